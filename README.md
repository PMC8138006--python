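# specell

Multispectral autofluorescence analysis of single cells, built for the
non-invasive assessment of kidney health from urinary exfoliated proximal
tubule cells — and for any study that classifies cells from their intrinsic
fluorescence spectra.

Living cells fluoresce without any added dye: NAD(P)H, flavins, lipofuscin
and other native fluorophores each respond in characteristic
excitation/emission bands.  A multispectral microscope images the same field
in 34 such spectral channels (excitation 340–510 nm, emission 420–650 nm),
producing a *data block*: one image per channel, a brightfield image, and
per-channel reference images (dark, water, and a calibration fluid of 30 µM
NADH + 18 µM FAD).  Channel 2 intensity is dominated by NAD(P)H and channels
15/32 by flavins, so the ch2/ch32 intensity ratio tracks the cellular redox
ratio — a metabolic signal that shifts with kidney dysfunction.

`specell` implements the full analysis chain:

1. **I/O** — lossless TIFF data blocks with JSON metadata sidecars,
   label-image cell masks, canonical CSV feature tables
   (`specell.io`).
2. **Synthetic cohorts** — a generator that emulates the acquisition
   (linear spectral mixing, vignetting, Poisson shot noise, dark offset,
   hot/dead pixels, reference images) with hierarchical patient/cell
   variation and a *designed* group effect on the NAD(P)H:flavins
   log-ratio whose Bayes-optimal AUC is known in closed form
   (`specell.synthetic`).
3. **Preprocessing** — bad-pixel repair, water-reference subtraction,
   calibration-fluid flat-fielding, exposure equalization
   (`specell.preprocess`).
4. **Features** — per-cell channel means, top-10%-pixel means, channel
   ratios, and (in the extended policy) per-channel SD, skewness and excess
   kurtosis (`specell.features`).
5. **Discriminant model** — features ranked by *minimum attainable
   classification error* (the best single-threshold misclassification
   fraction), the best n < N selected, and a Fisher canonical projection
   fitted: w₁ maximizes between-group over within-group scatter,
   w₂ repeats the construction in the orthogonal complement
   (`specell.discriminant`, `specell.model`).
6. **Validation** — ROC/AUC (midrank ties, so AUC = U/(n₁n₂)), nested
   cross-validation with patient-grouped folds and all selection re-run
   inside each training fold, a label-permutation leakage guard, and the
   two-tailed Mann–Whitney U test with */**/*** tiers
   (`specell.validation`).

## Worked example

Fit the discriminant model on a synthetic cohort at the reference scale
(41 + 84 cells, two groups, designed Bayes AUC 0.9):

```python
from specell import (
    CanonicalDiscriminantModel, CohortConfig, CVConfig,
    effect_for_auc, generate_feature_cohort,
)
from specell.synthetic import default_spectra

cfg = CohortConfig(seed=7, effect=effect_for_auc(0.9),
                   n_patients_per_group=8, cells_per_group=(41, 84))
table, truth = generate_feature_cohort(cfg, default_spectra(seed=1))

results = CanonicalDiscriminantModel(table).fit(n_features=6)
print(results.summary())
```

```
Canonical discriminant analysis (binary groups)
========================================================
cells: 125  (group 1: n = 41, group 2: n = 84)
candidate features: 40   selected: 6
shrinkage gamma: 0.50   Fisher criterion: 5.163
training AUC: 0.907   training error: 0.128
Mann-Whitney U = 3124.0, p = 1.71e-13 [***]
--------------------------------------------------------
feature                min_error        w1        w2
ratio_ch02_ch15            0.128     0.427     0.300
ratio_ch15_ch02            0.128    -0.841     0.371
mean_ch02                  0.232     0.218     0.769
mean_ch08                  0.288     0.126    -0.331
mean_ch13                  0.304    -0.199    -0.250
mean_ch19                  0.312    -0.082    -0.095
```

The ranking recovers the interpretable redox channels (ratios of channels
2 and 15, the channel-2 mean) without being told where the effect was
planted; min_error 0.128 means the best single threshold on that feature
misclassifies 12.8% of cells.  Honest held-out performance comes from
nested CV:

```python
report = results.cross_validate(CVConfig(seed=0, n_grid=(2, 4, 6, 8)))
print(report.pooled_auc)          # 0.884  (designed Bayes AUC: 0.9)
print(report.group_test.tier)     # ***
```

The pooled held-out AUC (0.884) sits near the designed 0.9, and the
projection scores separate the groups at p < 0.001 — the same shape of
result the method produces on real cohorts (conservative six-feature
models around AUC 0.75–0.85, extended models up to 0.99).

The whole chain, from image rendering to the four-panel report (canonical
scatter, ROC, projection histograms, boxplots), runs as one command:

```bash
specell run --out results/run1 --seed 11
specell verify results/run1          # checksums of every artifact
```

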