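# Note templates used by the synthetic cohort generator, keyed by gold label.
# Every template is a full sentence; templates under "fall" contain exactly one
# unambiguous trigger mention, "negated"/"traffic"/"homonym" templates contain a
# trigger in the corresponding excluding context, and "unrelated" templates
# contain no trigger at all. The default English lexicon classifies each
# template to its own key (regression-tested).
fall:
  - "patient fell off a chair at home yesterday"
  - "she stumbled over the doorstep and landed on her hip"
  - "found on the floor after a fall in the bathroom"
  - "tripped on the stairs last week, bruising on left arm"
  - "reports having fallen in the garden this morning"
  - "slipped on wet tiles and hurt her wrist"
negated:
  - "no fall reported this visit"
  - "denies falling in the past year"
  - "no recent falls, gait stable"
  - "patient has not fallen since the last checkup"
  - "never stumbled according to the daughter"
traffic:
  - "fell during a traffic accident on the bike"
  - "came off his bicycle in a collision and fell onto the road"
  - "fall after being hit by a car at the crossing"
homonym:
  - "fall season vaccination campaign discussed"
  - "flu shots planned for the fall season"
  - "worried about falling asleep during the day"
unrelated:
  - "blood pressure measured at 140 over 85, medication unchanged"
  - "routine diabetes review, hba1c stable"
  - "repeat prescription issued for statin"
  - "complains of mild headache, advised paracetamol"
  - "annual flu vaccination administered"
  - "ear wax removed, hearing improved"
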