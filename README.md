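# polarpremium

Measure how strongly a language associates one concept with another —
for example Beauty with Success — directly from pre-trained word
embeddings, and compare the association across languages and countries.

The motivating application is the **linguistic beauty premium**: the
well-documented tendency for physically attractive people to receive
better social and economic outcomes is also *encoded in language use*,
and because word embeddings are available for dozens of languages, the
strength of that encoding can be compared across cultures without
running a survey in each one.

## The measurement

A word embedding maps each vocabulary word `w` to a vector `v(w)` whose
geometry reflects semantic relatedness. A two-poled semantic axis such
as *Success–Failure* is spanned by antonym pairs; each pair contributes
a unit **direction vector**

```
d_i = (v(pos_i) − v(neg_i)) / ‖v(pos_i) − v(neg_i)‖ ,
```

e.g. (successful, unsuccessful), (victorious, failed), (winning,
losing). Stacking the `d_i` gives the axis's direction matrix. A word's
association with the axis is its scalar projection onto each direction,
averaged over pairs:

```
score(w) = (1/P) Σ_i ⟨v(w), d_i⟩ ,
```

and a concept (Beauty, represented by a curated word list to capture its
shades of meaning) is scored by averaging once more over its words, so
list length does not weight the result. Positive scores mean association
with the declared positive pole. Treating each word as one independent
observation yields a Student-t confidence interval per concept, and the
**premium** on an axis is the difference of concept means,

```
premium = mean(Beauty scores) − mean(Ugliness scores) ,
```

tested with a two-sided Welch t-test on the two word-mean samples and
labelled `positive_significant` / `negative_significant` /
`not_significant` at level α.

Everything is organised as model + results objects:
`AxisAssociationModel(table, beauty, ugliness, axis).fit()` returns an
`AxisAssociationResults` with the estimates, intervals, test and a
`summary()` table. A pipeline layer runs many languages from one config
file and joins premia onto countries via a primary-language table, and a
synthetic-embedding generator plants a known axis and known concept
effects so the whole chain is testable without downloading embeddings.

## Worked example

Generate a synthetic embedding whose ground truth is known — Beauty
words planted at projection +0.3 on the latent axis, Ugliness words at
−0.3, isotropic noise σ = 0.05 — then score it:

```
$ premium synth --dim 50 --pairs 3 --words 20 --delta-beauty 0.3 \
    --delta-ugliness -0.3 --sigma 0.05 --seed 7 --out demo.vec
$ premium compute --embeddings demo.vec --lang syn \
    --lexicon demo.vec.lexicon.yaml --axis planted
Axis association (semantic-axis projection)
============================================================
language: syn    axis: planted (Positive vs Negative)
pairs used: 3
------------------------------------------------------------
concept             mean    ci_low   ci_high    n
beauty            0.2952    0.2728    0.3177   20
ugliness         -0.2985   -0.3233   -0.2738   20
------------------------------------------------------------
difference (beauty - ugliness): 0.5938 [0.5615, 0.6261]
Welch t = 37.235, df = 37.6, p = 2.61e-31
label (alpha = 0.05): positive_significant
```

The concept means recover the planted ±0.3 (each with its 95% interval
over the 20 word scores), the difference 0.5938 estimates the planted
premium of 0.6 (slightly shrunk because noise tilts the empirical pair
directions off the latent axis; see `docs/methods.md`), and the Welch
test is decisive.

For real data, point `premium compute` at a word2vec-format `.vec` file
(e.g. the published fastText vectors for a language) together with the
shipped English lexicon or your own translated lexicon, use
`premium validate` to check lexicon coverage first, `premium crosslang`
to run many languages from a YAML config, and `premium countries` to
join the per-language premia onto countries.

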