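# mipam

Mutual-information-based feature selection for high-dimensional spectral
data, with a downstream case/control classification harness.

ATR-FTIR spectra of biofluids carry hundreds of highly redundant
wavenumber intensities: neighbouring bands move together because they
report on the same molecular vibrations, and the relationships are not
always linear. `mipam` selects a small, interpretable set of
representative wavenumbers by

1. estimating the pairwise **mutual information** I(X_j, X_j') between all
   wavenumbers with the Kraskov–Stögbauer–Grassberger (KSG) k-nearest-
   neighbour estimator (nats; k = 3 by default),
2. mapping it to a normalized similarity
   `I_norm = sqrt(1 − exp(−2 I))` — which equals |ρ| for bivariate
   Gaussian data — and to the dissimilarity `d = 1 − I_norm ∈ [0, 1]`
   (d = 1 exactly under independence),
3. clustering the *wavenumbers* (not the subjects) with **Partitioning
   Around Medoids** (deterministic Kaufman–Rousseeuw build + best-improvement
   swap) on that dissimilarity, choosing the cluster count G by the
   maximum **average silhouette width**, and
4. keeping each cluster's **medoid** — an actual observed wavenumber — as
   a covariate for Mann–Whitney screening (with Benjamini–Hochberg
   adjustment), logistic-regression / LDA / random-forest classification,
   and repeated stratified k-fold cross-validation.

Because MI detects any kind of dependence, the pipeline keeps working when
wavenumbers are related non-monotonically — the regime where a Pearson
correlation matrix (provided as the `1 − |r|` comparator) falls apart.

The intended users are biostatisticians and spectroscopists who want
variable *selection* (interpretable wavenumbers) rather than variable
*projection* (PCA/PLS components).

## Worked example

Real patient spectra are rarely shareable, so the package ships a
generator of block-structured synthetic spectra (latent factor per block,
amide I/II mean-spectrum bands near 1650 and 1545 cm⁻¹, optional
non-monotone dependence, group mean shifts in chosen blocks):

```python
import numpy as np
from mipam import generate_block_spectra, select_features, evaluate_medoids
from mipam.synthetic import separable_preset

cfg = separable_preset(seed=1)        # 85 subjects, 120 wavenumbers, 8 blocks
ds, blocks = generate_block_spectra(cfg)

fs = select_features(ds, g_range=(2, 12), seed=1)   # KSG MI -> d -> PAM -> silhouette
print("chosen G:", fs.selection.chosen_g)
print("medoid wavenumbers:", np.round(fs.medoid_wavenumbers, 1))

res = evaluate_medoids(ds, fs.medoid_indices, seed=1)
for m in ("logit", "lda", "rf"):
    s = res["cv"]["summary"][m]["auc"]
    print(m, "CV AUC median %.3f mean %.3f" % (s["median"], s["mean"]))
```

Output:

```
chosen G: 8
medoid wavenumbers: [1626.1 1580.7 1361.3 1293.3 1149.6 1119.3 1028.6  937.8]
logit CV AUC median 0.972 mean 0.954
lda   CV AUC median 0.986 mean 0.974
rf    CV AUC median 0.958 mean 0.955
```

The silhouette sweep recovers the 8 planted dependence blocks and returns
one medoid per block; the three medoids drawn from the group-shifted
blocks drive the discrimination, and all three classifiers separate the
groups with median cross-validated AUC well above 0.9 (the preset plants
a shift whose Bayes-optimal AUC is ≈ 0.95). `res["screening"]` holds the
per-medoid Mann–Whitney table (medians per group, U statistic, raw and
BH-adjusted p-values).

The same pipeline is scriptable from the shell:

```bash
mipam --seed 1 --out-dir run simulate --preset compact
mipam --seed 1 --out-dir run mi --input run/spectra.csv --label-column group
mipam --out-dir run select-g --matrix run/dissimilarity.csv --g-min 2 --g-max 12
mipam --seed 1 --out-dir run evaluate --input run/spectra.csv \
      --label-column group --partition run/partition.json
```

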