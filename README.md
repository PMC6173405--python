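# qrfdrug

Quantile-regression-forest prediction of drug response from cell-line genomics,
with prediction intervals and a statistical assessment of prediction
reliability.

## The problem

Most drug-response predictors output a single number per (cell line, drug) pair
— the conditional mean of a sensitivity measure such as the activity area — and
say nothing about how much the response could fluctuate around it.  In
precision-medicine settings the *reliability* of a prediction matters as much
as its value: when two drugs (or two patients) have near-identical point
predictions, the one whose predicted response distribution is tighter is the
safer choice.  Because drug-response distributions are typically skewed,
normal-theory prediction intervals are not trustworthy; this package instead
estimates the full conditional distribution nonparametrically.

`qrfdrug` is aimed at computational biologists working with panels like a
cell-line pharmacogenomic screen: a high-dimensional feature matrix (gene
expression, binary mutation status, copy-number variation) and one continuous
response per sample per drug.

## The method

A three-step workflow per drug:

1. **Screening.** Every feature is tested for marginal association with the
   response via the two-sided t-test on the Pearson correlation,
   `t = r·sqrt((n−2)/(1−r²)) ~ t(n−2)`; features with raw `p < 0.05` survive.
2. **Selection.** A bagged regression forest (default 25 000 trees, `mtry =
   M/3`, nodes with < 10 samples unsplit) is fitted on the screened features;
   out-of-bag (OOB) permutation importance is computed per feature, and
   features with importance above `mean + 2·SD` of all importances are kept.
3. **Quantile regression forest.** A forest (default 15 000 trees) on the
   selected features defines, for any sample x, weights over training samples

       ω_i(x, Ψ) = I(X_i ∈ leaf(x, Ψ)) / #{j : X_j ∈ leaf(x, Ψ)},
       ω_i(x) = (1/T) Σ_t ω_i(x, Ψ_t),

   from which the conditional CDF `F̂(y|x) = Σ_i ω_i(x)·I(Y_i ≤ y)`, quantiles
   `q̂_τ(x) = inf{y : F̂(y|x) ≥ τ}`, the conditional mean `Σ_i ω_i(x)·Y_i`, and
   central prediction intervals `[q̂_{α/2}, q̂_{1−α/2}]` follow.  Point and
   quantile predictions are evaluated out-of-bag (Pearson accuracy; check loss
   `ρ_τ(r) = τr − r·I(r<0)`; interval average length AveL and coverage CP).

**Reliability comparison.** For subjects with near-equal point predictions, k
(default 500) pseudo-responses per subject are drawn by inverse-transform
sampling from each subject's estimated quantile function, and the Levene
homogeneity-of-variances test (mean-centred; Brown–Forsythe optional) compares
their spread.  A rejecting test plus a shorter prediction interval identifies
the more stable, hence preferable, prediction.

## Worked example

```python
import numpy as np
from qrfdrug import (GeneratorSpec, PipelineConfig, ThreeStepQRF,
                     compare_reliability, generate)

# a synthetic 500-cell-line panel: 400 genomic features, 2 truly predictive
data, truth = generate(GeneratorSpec(n=500, M=400, s=2, seed=1))
config = PipelineConfig(trees_select=500, trees_qrf=300, seed=1)
results = ThreeStepQRF(data, config, drug_id="synthetic_drug").fit()
print(results.summary())
```

```
Three-step QRF results for drug 'synthetic_drug'
========================================================
Samples:                      500
Features (input):             400
Features after screening:     32
Features after selection:     2
--------------------------------------------------------
oob_accuracy_mean            0.6940
oob_accuracy_median          0.6988
pi95_average_length          4.2920
pi95_coverage                0.9340
pi80_average_length          2.5804
pi80_coverage                0.7580
--------------------------------------------------------
Selected features (importance-ranked):
  expr:G0002
  expr:G0001
========================================================
```

The screen kept 32 of 400 features, the importance rule narrowed these to
exactly the two truly predictive genes, OOB point predictions correlate ~0.69
with the observed responses, and the nominal 95%/80% intervals cover 93.4%/75.8%
of held-out (OOB) responses.

Comparing two cell lines whose point predictions are nearly equal:

```python
pred = results.predictions.set_index("sample_id")
sel = results.dataset.subset_features(results.selected_features)
report = compare_reliability(
    results.qrf.forest,
    [(sel.X[162], "S0163"), (sel.X[350], "S0351")],
    k=500, seed=1,
)
print(report.summary())
```

```
label    mean  median  pi_lower  pi_upper  pi_length
S0163 -0.3496 -0.6277   -0.8129    0.5930     1.4060
S0351 -0.2414 -0.8212   -2.6639    5.8497     8.5136

Joint Levene test: W = 246.1108, p = 9.635e-50, df = (1, 998), reject H0

S0163 vs S0351: variances differ (p=9.64e-50); near-equal point predictions;
S0163 has the shorter 95% PI (1.406 vs 8.514) and offers the more stable response
```

Both cell lines are predicted to respond at about the same level, but S0351's
predicted response distribution is six times wider; the Levene test on the
inverse-transform samples confirms the difference, so S0163's prediction is the
reliable one.

The same workflow is available from the shell:

```bash
qrfdrug simulate --n 500 --num-features 400 --informative 2 --seed 1 --outdir panel/
qrfdrug run --expression panel/expression.tsv --mutation panel/mutation.tsv \
    --response panel/response.tsv --drug-id synthetic_drug \
    --trees-select 500 --trees-qrf 300 --seed 1 --outdir out/
```

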