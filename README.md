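# ehgkit

Electrohysterography (EHG) — surface recording of uterine myoelectrical
activity — is a promising basis for predicting preterm labor, but clinical
uptake favors simple, interpretable classifiers over black-box models.
`ehgkit` implements a complete, reusable version of that analysis for
researchers in biomedical signal processing: it characterizes 3-channel,
20-Hz EHG recordings with temporal, spectral and non-linear descriptors in
four bandwidths, balances the rare preterm class, selects a compact feature
subset with a genetic-algorithm (GA) wrapper, and evaluates k-nearest
neighbours (KNN), linear discriminant analysis (LDA) and logistic
regression (LR) plus their majority-vote ensemble under a repeated
stratified holdout protocol. A synthetic cohort generator with planted,
configurable term/preterm effects makes every stage testable without
clinical data.

## The method

Each recording (three bipolar channels S1–S3, 20 Hz, expert-marked usable
segments) is band-pass filtered (zero-phase Butterworth) into 0.1–4,
0.34–4, 0.2–0.34 and 0.34–1 Hz, cut into 120-s windows with 50 % overlap,
and summarized per window by 66 descriptors per channel: peak-to-peak
amplitude per band; Teager energy, mean frequency, dominant frequencies,
spectral deciles D1–D9, normalized band energies, H/L energy ratio and the
spectral moment ratio M(−1)/M(5); and, in every band, sample entropy,
fuzzy entropy, spectral entropy, binary and 6-state Lempel-Ziv complexity,
time reversibility, Katz fractal dimension and the Poincaré descriptors
SD1/SD2/SDRR/SD1:SD2. Window values collapse to per-recording medians;
with five obstetric covariates the feature vector has
3 × 66 + 5 = 203 entries.

After SMOTE oversampling (k = 5) to class parity, the table is split into
30 stratified train/validation/test thirds. For each base classifier a GA
(binary masks, tournament 2, elite 2, arithmetic crossover 0.8, uniform
mutation 0.01) maximizes

    fitness = F1̄_val · (NFeat − NCFeat)

the mean validation F1 times the number of discarded features, so compact
subsets that keep performance win and selecting everything scores zero.
Each classifier's optimized mask is then evaluated on the untouched test
thirds; the ensemble takes the per-row majority label. Classifiers are
compared with a Friedman test and Nemenyi post-hoc decisions, and
between-partition variability is reported as coefficients of variation.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from ehgkit.pipeline import run_pipeline, scaled_study_config

result = run_pipeline(scaled_study_config(seed=11))
print(result.mean_metrics("test")[["f1", "auc"]].round(3))
print({k: int(m.sum()) for k, m in result.masks.items()})
```

prints (roughly ten minutes on one core):

```
               f1    auc
classifier
ensemble    0.819  0.911
knn         0.774  0.837
lda         0.763  0.717
lr          0.846  0.829
{'knn': 61, 'lda': 68, 'lr': 65}
```

i.e. the per-classifier mean test F1 and AUC over the partitions, and the
number of features each classifier's GA kept out of 203. The ensemble's
mean F1 sits at or above the weakest base classifier and its
between-partition variability at or below the most variable one — the
qualitative pattern this pipeline is designed to exhibit; absolute values
describe the synthetic cohort only.

The same pipeline is scriptable from a shell:

```bash
ehgkit all --seed 1 --outdir out/          # every stage, all artifacts
ehgkit simulate --seed 1 --outdir cohort/  # or stage by stage
ehgkit extract --cohort-dir cohort/ --out features.tsv
```

Artifacts (feature table, screening report, balanced table, per-classifier
masks and GA histories, metrics, comparison and CV tables) are plain
delimited text.

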