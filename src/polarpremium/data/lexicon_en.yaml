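# Default English lexicon: concepts (word lists) and axes (antonym pairs,
# positive pole first).  The beauty/ugliness lists and the success/failure
# pairs follow the established vocabulary for embedding-bias studies; the
# remaining axes use standard antonym sets and are the intended extension
# point for richer, sourced vocabularies.
languages:
  en:
    concepts:
      beauty:
        words: [beautiful, attractive, handsome, pretty, lovely, cute]
      ugliness:
        words: [ugly, unattractive, hideous, unsightly, repulsive, grotesque]
    axes:
      success_failure:
        positive_label: Success
        negative_label: Failure
        pairs:
          - [successful, unsuccessful]
          - [victorious, failed]
          - [winning, losing]
      affluence_poverty:
        positive_label: Affluence
        negative_label: Poverty
        pairs:
          - [rich, poor]
          - [wealthy, impoverished]
          - [affluent, destitute]
      good_bad:
        positive_label: Good
        negative_label: Bad
        pairs:
          - [good, bad]
          - [virtuous, wicked]
          - [right, wrong]
      pleasant_unpleasant:
        positive_label: Pleasant
        negative_label: Unpleasant
        pairs:
          - [pleasant, unpleasant]
          - [agreeable, disagreeable]
          - [enjoyable, annoying]
      competence_incompetence:
        positive_label: Competence
        negative_label: Incompetence
        pairs:
          - [competent, incompetent]
          - [capable, incapable]
          - [skilled, unskilled]
      trust_distrust:
        positive_label: Trust
        negative_label: Distrust
        pairs:
          - [trustworthy, untrustworthy]
          - [honest, dishonest]
          - [reliable, unreliable]
      confident_doubtful:
        positive_label: Confident
        negative_label: Doubtful
        pairs:
          - [confident, doubtful]
          - [assured, hesitant]
          - [certain, uncertain]
      # Control axes unrelated to evaluation, for specificity checks.
      fast_slow:
        positive_label: Fast
        negative_label: Slow
        pairs:
          - [fast, slow]
          - [quick, sluggish]
          - [rapid, gradual]
      far_near:
        positive_label: Far
        negative_label: Near
        pairs:
          - [far, near]
          - [distant, close]
          - [remote, nearby]
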