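# Search-term dictionary for first-line smoking-cessation pharmacotherapies.
# Terms are matched case-insensitively against the verbatim drugname and
# prod_ai fields; short or ambiguous terms carry word_boundary: true so that
# e.g. "gum" does not capture "gummy".  Wellbutrin (a bupropion brand
# prescribed mainly for depression) is excluded to reduce confounding by
# non-cessation indications.
classes:
  NRT:
    - nicotine
    - nicoderm cq
    - nicorette
    - habitrol
    - nicotrol
    - {term: thrive, word_boundary: true}
    - nicorelief
    - nicotine patch
    - {term: gum, word_boundary: true}
    - {term: lozenge, word_boundary: true}
    - {term: inhaler, word_boundary: true}
    - {term: nasal spray, word_boundary: true}
    - polacrilex
  Varenicline:
    - varenicline
    - chantix
    - champix
  Bupropion:
    - bupropion
    - zyban
    - bupropion sr
exclusions:
  - wellbutrin
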