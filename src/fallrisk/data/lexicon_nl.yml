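# Parallel Dutch example lexicon. This is an analogue for demonstration and
# format documentation, not the supplementary regex list used on the original
# registry; substitute the authentic lists via --lexicon to reproduce those.
triggers:
  - val
  - valt
  - viel
  - gevallen
  - vallen
  - struikelt
  - struikelde
  - gestruikeld
  - uitgegleden
  - gleed
negations:
  - geen
  - niet
  - nooit
  - zonder
  - ontkent
traffic:
  - verkeer
  - auto
  - fiets
  - scooter
  - aanrijding
  - botsing
homonyms:
  - najaar
  - herfst
  - prijzen
  - slaap
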