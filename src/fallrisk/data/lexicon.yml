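# Fall-detection lexicon (English).
# Triggers carry their inflection variants explicitly; matching is
# case-insensitive on word boundaries, so no stemming is applied.
triggers:
  - fall
  - falls
  - fell
  - fallen
  - falling
  - stumble
  - stumbles
  - stumbled
  - stumbling
  - trip
  - tripped
  - tripping
  - slipped
  - slipping
  - tumble
  - tumbled
negations:
  - "no"
  - "not"
  - without
  - never
  - denies
  - denied
traffic:
  - traffic
  - car
  - bike
  - bicycle
  - moped
  - scooter
  - vehicle
  - collision
  - crash
homonyms:
  - season
  - autumn
  - semester
  - asleep
  - vacation
  - holiday
  - prices
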