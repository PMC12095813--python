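# Methods

## The association model

Let `v(w) ∈ R^D` be a word's embedding vector. A semantic axis `A` is a
set of `P` antonym pairs `(pos_i, neg_i)`; its direction matrix has unit
rows `d_i = (v(pos_i) − v(neg_i)) / ‖·‖`. A word's axis score is the
mean scalar projection `(1/P) Σ_i ⟨v(w), d_i⟩`; a concept's score is the
unweighted mean of its words' scores. Two opposed concepts (Beauty and
Ugliness by default) on the same axis give the premium — the difference
of concept means — tested with a two-sided Welch t-test over the two
sets of word means and labelled significant at level α.

Assumptions worth stating explicitly:

- **Projection, not change of basis.** Each pair direction is used
  independently and the per-pair values averaged. The alternative
  interpretable-basis construction (inverting the stacked direction
  matrix) answers a different question and is not implemented.
- **Words are the units of inference.** Concept CIs and the Welch test
  treat each word's mean score as one independent observation; pairs
  and pair×word cells are never pooled as if independent. Word scores
  on one axis share the same directions, so they are positively
  correlated in truth; the CI is over word selection, which is the
  sensitivity the word-list design is meant to expose.
- **Raw projections by default.** Word vectors are not unit-normalised
  before projection (`normalize_words=True` switches this on). Raw
  projections make concept scores scale-equivariant: multiplying all
  vectors by c > 0 multiplies all scores by exactly c, because the
  directions renormalise. Normalised projections are scale-free; both
  behaviours are exposed because published analyses rarely state which
  was used.
- **Per-word CIs** are the Student-t interval over the P per-pair
  projections (each antonym pair one observation of the word's
  association). The leave-one-pair-out construction is a plausible
  alternative reading of "varying the word–antonym-pair combination";
  per-pair dispersion was chosen because it is the direct dispersion of
  the quantities actually averaged, and it is undefined (NaN) for a
  single-pair axis rather than silently zero.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level for the premium label |
| `ci_level` | 0.95 | confidence level of all t-intervals |
| `normalize_words` | off | unit-normalise word vectors before projection |
| `min_coverage` | 0.5 | below this fraction of lexicon terms found, a concept/axis is flagged and the language excluded from cross-language runs |
| `phrase_policy` | `average` | multi-token lexicon terms: average token vectors when all tokens are in-vocabulary, else treat the term as missing (`skip`: always missing) |
| `max_words` | none | read only the first N vocabulary rows (published tables are frequency-sorted) |

Case handling looks up the surface form first, then the lower-cased
form. Direction rows must be unit within 1e-9; zero-difference pairs
(identical pole vectors) are dropped with a recorded reason, while
duplicated but distinct pairs are kept as distinct observations. A
single in-vocabulary word or a single pair yields an undefined (NaN)
interval, never a fabricated zero-width one. Welch's test with both
sample variances zero is defined as t = 0, p = 1 when the means agree
(and p = 0 otherwise). The Holm-adjusted p-value column emitted by the
pipeline is an extension for readers who want family-wise control
across languages; the per-language labels are deliberately unadjusted,
matching the per-language presentation of the measurement.

## The lexicon

The shipped English lexicon (`data/lexicon_en.yaml`) contains the
Beauty words *beautiful, attractive, handsome, pretty, lovely, cute*,
an Ugliness list of standard antonyms, and nine axes: Success–Failure
(successful/unsuccessful, victorious/failed, winning/losing),
Affluence–Poverty, Good–Bad, Pleasant–Unpleasant,
Competence–Incompetence, Trust–Distrust, Confident–Doubtful, plus two
control axes (Fast–Slow, Far–Near) whose associations with evaluation
should be weak — a specificity check. Apart from the Beauty list and
the Success–Failure pairs, which follow established embedding-bias
vocabulary, the antonym sets are this package's own choices and the
intended extension point: supply a richer, sourced lexicon file for
serious use. Translated lexica are user inputs; translation quality and
coverage gate which languages can be analysed (the `min_coverage`
exclusion rule).

## The synthetic generator

`SyntheticConfig` plants a latent unit direction `u`: pole words at
`±a·u`, Beauty words at `δ_b·u`, Ugliness words at `δ_u·u`, fillers at
the origin, all plus isotropic Gaussian noise `N(0, σ²I)`. Each role
(direction, poles, beauty, ugliness, fillers) draws from its own
deterministic random stream derived from the seed, so enlarging one
group never perturbs another — changing the filler count provably
leaves every concept score bitwise unchanged.

What it emulates: the geometric contract the analysis relies on —
concept words displaced along a pole-to-pole direction plus noise.
What it does not: real embeddings are anisotropic, have heavy-tailed
norms that correlate with word frequency, and their antonym-pair
directions are far noisier and only partially aligned. Passing tests
therefore demonstrate that the estimator is correct and calibrated
*for data satisfying its own geometric model*, not that any particular
natural-language finding is right.

### Expected premium under noise

With noise the empirical pair direction is `(2a·u + ε)/‖2a·u + ε‖`,
`ε ~ N(0, 2σ²I)`, and its component along `u` simplifies exactly to
`(1 + r²/(1+t)²)^{-1/2}` with `t ~ N(0, q)`, `r² ~ q·χ²_{D−1}`,
`q = σ²/(2a²)`. Expanding to fourth order,

```
k = 1 − q(D−1)/2 · (1 + 3q) + (3/8) q² (D−1)(D+1) ,
```

so the expected estimated premium is `(δ_b − δ_u)·k` — exact at σ = 0.
At the reference configuration (D = 50, a = 1, σ = 0.05: q = 1.25e-3)
k = 0.9707 and the expected premium is 0.5824; the residual of the
expansion is about 6e-5 there (checked against large-sample numerical
integration of the exact expression). This is the shrinkage visible in
the README example: the estimator is unbiased for the generative
expectation, which sits slightly below the planted `δ_b − δ_u` because
noisy pole placements tilt the empirical directions off the latent
axis.

The noise variance of a word's score is `σ²‖d̄‖²` with `d̄` the mean
direction; since the P directions are nearly collinear,
`E‖d̄‖² = 1/P + (P−1)/P·k²` is close to 1 and the concept mean has
variance ≈ `σ²·E‖d̄‖²/n_words` — the variance oracle used in the tests.

## Problem sizes and numerical choices

Validation runs use D = 50, 3 pairs, 20 words per concept, σ = 0.05,
with 1000 replicates for bias/coverage/type-I calibration and 10 seeds
for the five-language ranking experiment — sizes at which Monte-Carlo
error is comfortably inside the asserted bands (the premium estimator's
replicate SD is ≈ 0.016, so 1000 replicates pin its mean to ≈ 0.0005).
Exact symmetries (pole swap, permutations) are asserted at 1e-12 or
exactly; orthogonal invariance at 1e-8 (QR-based rotations introduce
rounding at the 1e-15 level per coordinate, amplified by D). Derived
per-replicate seeds come from `numpy.random.SeedSequence` and stay
below 2^31. TSV output formats floats with 12 significant digits, which
makes re-reads faithful to that precision and repeated runs
byte-identical.

## Known limitations

- Whole-word lookups only: no subword composition, so out-of-vocabulary
  terms are simply missing (the published `.vec` tables, not subword
  models, are the intended input).
- The country join uses one primary language per country; countries
  with several widely spoken languages inherit only the primary one,
  and within-language cultural variation is invisible by construction.
- The shipped country→language table is an illustrative synthetic
  fixture, not an authoritative source.
- No multiple-testing adjustment in the headline labels (by design;
  Holm column provided).
- The synthetic generator's isotropic noise understates the difficulty
  of real embeddings; calibration results transfer only to the extent
  the geometric model holds.
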