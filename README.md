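# brainage

A tested, reusable pipeline for **brain-age-gap analysis**: predict a
"healthy" brain age from 3D structural MRI-like volumes with a small residual
CNN, remove the regression-to-the-mean age bias, attribute the prediction to
atlas regions by cross-subject permutation importance, scan many phenotypes
for association with the brain-age difference (a PheWAS), and probe causality
with two-sample Mendelian randomisation.

Real analyses of this kind run on access-controlled biobank imaging. This
package therefore ships a first-class **synthetic-cohort simulator** that
generates every input with known ground truth — volumes with a planted
regional age signal, trait tables linked to a planted brain-age gap, and GWAS
summary statistics with a planted causal effect — so that every stage is
verifiable by parameter recovery at desk scale.

## The quantities being estimated

* **Brain-age difference.** A CNN regressor f maps a volume x to a raw age
  prediction ŷ_raw = f(x), trained by minimising mean squared error with
  Adam. Raw predictions show a linear age bias (old subjects predicted young
  and vice versa), so an ordinary-least-squares fit ŷ_raw ≈ α + β·y on the
  *training* split is inverted to give ŷ = (ŷ_raw − α)/β, and the brain-age
  difference is δ = ŷ − y. Positive δ means an "older-looking" brain.
* **Region importance.** For each atlas region, the region's voxels are
  exchanged between subjects by a random bijection (at fixed template
  coordinates), inference is re-run, and the increase in mean absolute error
  ΔMAE over the unpermuted baseline — averaged over repeats — measures how
  much subject-specific information that region contributes.
* **PheWAS.** Each trait is regressed on δ/sd(δ) with adjustment for age,
  sex and assessment centre: linear for continuous traits, logistic for
  binary, cumulative-logit for ordinal. Multiplicity is controlled by
  Bonferroni (α/m) and Benjamini–Hochberg FDR.
* **Mendelian randomisation.** From harmonised, LD-clumped exposure/outcome
  summary statistics: the inverse-variance-weighted estimate
  Σ(β̂xjβ̂yj/σ²yj)/Σ(β̂²xj/σ²yj), MR-Egger regression (whose intercept tests
  directional pleiotropy), the weighted median of the Wald ratios, and
  Cochran's Q for heterogeneity.

The CNN is implemented in NumPy (3D convolutions via sliding-window views,
batch normalisation, residual blocks, hand-written reverse-mode gradients,
Adam), validated against finite differences in the test suite. It accepts
any grid compatible with its downsampling factor, from the 32³ desk-scale
cohorts used in the tests up to full 182×218×182 scans.

## Worked example

```python
import numpy as np
from brainage import generate_atlas, generate_volumes, stack_volumes
from brainage.model import (ModelConfig, build_model, train, predict,
                            fit_bias_correction, apply_bias_correction, evaluate)
from brainage.importance import region_importance_scan, rank_regions

atlas = generate_atlas((32, 32, 32), n_regions=20, seed=1)
samples, truth = generate_volumes(atlas, 400, signal_regions=(3, 11),
                                  effect_size=1.0, noise_sd=1.0, seed=2)
ids, X, ages = stack_volumes(samples)

cfg = ModelConfig(input_shape=(32, 32, 32), seed=1)
model, _ = train(build_model(cfg), (X[:280], ages[:280]),
                 (X[280:340], ages[280:340]), cfg)

bc = fit_bias_correction(predict(model, X[:280]), ages[:280])
records = apply_bias_correction(bc, predict(model, X[340:]), ages[340:])
mae, r = evaluate(records)
print(f"held-out MAE {mae:.2f} y, Pearson r {r:.2f}")

imps = region_importance_scan(model, X[340:], ages[340:], atlas,
                              n_repeats=5, seed=3)
print(rank_regions(imps).head(3))
```

This prints (exact values vary slightly with BLAS):

```
held-out MAE 2.95 y, Pearson r 0.94
   region_id  delta_mae        sd  n_repeats  most_informative
0          3      2.881  0.402...          5              True
1         11      0.9...  0.2...           5              True
2         ...     0.019  ...              5             False
```

Held-out MAE of ~3 years against a constant-mean-age baseline of ~9 years:
the network has learned the planted age signal, and the residual error is
dominated by the planted subject-level gap (sd 3.72 years) — exactly as
intended, since that gap is what the downstream association scan consumes.
The two planted signal regions (3 and 11) top the importance ranking and are
the only regions whose ΔMAE exceeds the 0.10-year reporting threshold.

A shell-level interface wraps the same stages:

```sh
brainage simulate --config sim.yaml --out data/ --seed 1
brainage train --cohort data/volumes --out model.npz --seed 1
brainage predict --model model.npz --cohort data/volumes --out preds.tsv
brainage phewas --predictions preds.tsv --traits data/traits.tsv --out phewas.tsv
brainage mr --exposure data/exposure.tsv --outcome data/outcome.tsv --out mr.tsv
```

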