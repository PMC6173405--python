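# Methods

## Model

For one drug, the data are a feature matrix `X` (n samples × M genomic
features: continuous expression, binary 0/1 mutation status, continuous copy
number) and a continuous response `y` (activity area).  The estimand is the
conditional law of the response given the features, summarised by its quantile
function; no distributional form is assumed for the response or the noise.

The estimator is a quantile regression forest: `T` un-pruned CART regression
trees grown on bootstrap resamples, each split chosen among `m` randomly drawn
candidate features to maximise variance reduction, with nodes of fewer than
`min_node` samples left unsplit.  The trees define leaf-co-membership weights
`ω_i(x)` (uniform over the bootstrap members of the leaf containing `x`,
averaged over trees), a weighted empirical CDF `F̂(y|x) = Σ ω_i(x) I(Y_i ≤ y)`,
quantiles via the inf definition, and the conditional mean `Σ ω_i(x) Y_i`.

Dimension reduction happens in two stages before the QRF: a marginal Pearson
screen (two-sided t-test, raw `p < alpha_screen`; point-biserial for binary
features; features with fewer than two distinct values get `p = 1`), then OOB
permutation importance from a selection forest with the `mean + c·SD`
importance cutoff (sample SD, n−1 denominator).  No multiple-testing
correction is applied at the screen — it is a permissive pre-filter whose
type-I rate per null feature is `alpha_screen` by construction, and the
importance stage is expected to discard the surviving false positives.

Reliability is compared across subjects by inverse-transform sampling: `k`
draws `τ_j ~ U(0,1)` mapped through a subject's estimated quantile function
give pseudo-responses whose dispersion is compared by the Levene test
(statistic `W` from absolute deviations about group means, referred to
`F(g−1, N−g)`).  The pseudo-responses are draws from the *estimated* discrete
conditional law, not the true one; the plug-in's operating characteristics are
therefore themselves checked by simulation (calibration near the nominal 5%
level on identical-distribution pairs, power ≈ 1 at a 3-fold scale ratio with
`k = 500`), since no analytic correction exists.

## Parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `alpha_screen` | 0.05 | marginal screen threshold (raw p) |
| `trees_select` | 25 000 | trees in the selection forest |
| `trees_qrf` | 15 000 | trees in the QRF |
| `min_node` | 10 | do not split nodes with fewer samples |
| `mtry` | ⌊M/3⌋, min 1 | candidate features per split |
| `importance_c` | 2.0 | SD multiplier of the importance cutoff |
| `taus` | {0.025, 0.1, 0.25, 0.5, 0.75, 0.9, 0.975} | reported quantile grid |
| `alpha_pi` | 0.05 | central interval, `[q_{α/2}, q_{1−α/2}]` |
| `k_levene` | 500 | pseudo-responses per subject |

The tree counts are compute budgets, not algorithmic constants: results
stabilise once every sample is OOB in many trees, and the test suite and
acceptance studies use 100–1000 trees on panels of n ≤ 500, where forests are
seed-deterministic and far cheaper.  All randomness (bootstraps, split
candidate draws, permutation shuffles, τ draws) derives from a single seed via
`numpy.random.SeedSequence` spawning, so any run is bit-reproducible and
parallel/serial order cannot change results.

## Implementation notes and numerical choices

- Trees are grown by scikit-learn's `DecisionTreeRegressor`
  (`criterion="squared_error"`, `min_samples_split = min_node`,
  `max_features = mtry`, fixed per-tree `random_state`); thresholds are
  midpoints between consecutive sorted values and ties route left (`≤`).  The
  package keeps its own bootstrap multiset, OOB index set and per-draw leaf
  assignment, which the weight formulas need and a plain regressor discards.
- Leaf weights count bootstrap multiplicity: a sample drawn twice into a
  tree's bootstrap carries twice the weight in that leaf.  This is the
  bootstrap-multiset convention; weights are uniform over draws, not over
  distinct samples.
- Quantiles are read off the cumulative sorted weighted responses with a
  `1e-12` tolerance on the `≥ τ` comparison to absorb floating-point drift;
  with tied responses the CDF is evaluated at the last tied position, so the
  inf definition is exact on discrete support.
- OOB prediction averages weights over the trees in which a sample was
  out-of-bag, dividing by the number of such trees (not T).  Samples in-bag
  everywhere receive NaN sentinels and a warning; downstream metrics drop
  NaN pairs.
- Coverage is closed-interval (`lower ≤ y ≤ upper`), the conservative reading.
- Degenerate cases: constant features get `(r, p) = (0, 1)` at the screen;
  a constant response yields single-leaf trees and zero-length intervals;
  Levene returns `(W, p) = (0, 1)` when all absolute deviations are identical
  and `p = 0` when groups' mean deviations differ with zero within-group
  variability.
- The Levene statistic is computed directly from the textbook formula (the
  degenerate conventions and reported group variances/df are not available
  from library routines); `scipy.stats.levene` serves as an oracle in tests.
- Each subject in a reliability comparison gets independent τ draws; sharing
  one τ grid across subjects would couple the groups artificially.  Pairwise
  p-values are reported unadjusted with a Bonferroni column alongside.
- The CLI's `fit`/`predict` retrain the deterministic forest from the seed
  rather than serialising models.

## Synthetic data generator

`generate(GeneratorSpec(...))` emulates a pharmacogenomic panel: continuous
features i.i.d. N(0,1), a `mutation_fraction` of binary features i.i.d.
Bernoulli(0.1), and `y = f(x) + σ(x)·ε` with `f` linear in the first `s`
continuous features (optional interaction term), `σ(x) = 0.5 + |x₁|` by
default (heteroscedastic, so interval length genuinely varies), and `ε`
standardised to mean 0, variance 1 from a gaussian, shifted-lognormal
(default; drug responses are right-skewed) or Student-t family.  Every
conditional quantile has a closed form (`GroundTruth.conditional_quantile`),
making the generator an oracle for quantile error, interval coverage and
reliability power studies.

What it does not emulate: gene–gene correlation, batch structure,
non-additive biology beyond one interaction term, and missingness.  Passing
tests demonstrate recovery of a known conditional law under these idealised
conditions, not performance on correlated genomic panels.

## Known limitations

- **The `mean + 2·SD` selection rule needs a small informative fraction.**
  At most a fraction `1/(1+c²)` of any importance vector can exceed
  `mean + c·SD` (one-sided Chebyshev), i.e. at most 20% for `c = 2`.  On
  small screened sets where the truly informative features are more than
  ~20% of survivors, the rule cannot retain them all and may select nothing
  (the error message suggests lowering `c`).  The rule behaves as intended
  when thousands of features are screened and a handful are informative.
- **Intervals are mildly conservative.**  With `min_node = 10` at n ≈ 500 the
  80% OOB intervals overcover by a few points (e.g. CP ≈ 0.88–0.90 on
  heteroscedastic skewed panels whose forests contain noise features), and
  interval length tracks the true conditional scale only loosely when noise
  features dilute the splits.  An independent reference implementation
  (R `ranger`, `quantreg=TRUE`) reproduces these numbers to within half a
  coverage point on shared data, so this is a property of the method at this
  scale, not of the implementation.
- OOB quantile estimates need enough trees that every sample has many
  OOB-eligible trees; with very small `T` some samples get sentinels.
- The Levene comparison treats estimated quantiles as genuine response draws;
  with poorly estimated conditional laws (tiny n or T) its nominal level can
  drift from α.
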