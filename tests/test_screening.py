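import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from mipam import (
    LabelError,
    SpectralDataset,
    fit_classifiers,
    mann_whitney_screen,
    repeated_cv,
)
from mipam.screening import summarize_metric
from mipam.synthetic import SyntheticSpectraConfig, generate_block_spectra


def labeled_ds(n_per_group=20, p=3, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2 * n_per_group, p))
    x[:n_per_group] += shift
    labels = ["MS"] * n_per_group + ["HC"] * n_per_group
    return SpectralDataset(x, np.arange(p, dtype=float) + 1000, [str(i) for i in range(2 * n_per_group)], labels)


class TestMannWhitney:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal((10, 2))
        x = np.vstack([half, half])  # the case group duplicates the controls
        ds = SpectralDataset(x, [1.0, 2.0], [str(i) for i in range(20)], ["MS"] * 10 + ["HC"] * 10)
        rows = mann_whitney_screen(ds)
        for row in rows:
            assert row.W == 10 * 10 / 2
            assert row.p_value > 0.9

    def test_complete_separation_extreme_w(self):
        ds = labeled_ds(n_per_group=15, p=2, shift=20.0, seed=1)
        rows = mann_whitney_screen(ds)
        for row in rows:
            assert row.W == 15 * 15  # all case values above all controls
            assert row.p_value < 1e-6
            assert row.min <= row.median_control <= row.max
            assert row.min <= row.median_case <= row.max

    def test_bh_adjustment_hand_check(self):
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_monotone_and_bounded(self):
        ds = labeled_ds(n_per_group=20, p=6, shift=0.4, seed=2)
        rows = mann_whitney_screen(ds)
        ps = [r.p_value for r in rows]
        padj = [r.p_adjusted for r in rows]
        assert all(a >= p for a, p in zip(padj, ps))
        assert all(a <= 1.0 for a in padj)
        # adjustment preserves the p-value ordering
        assert np.array_equal(np.argsort(ps), np.argsort(padj))

    def test_requires_labels(self):
        ds = labeled_ds()
        ds.labels = None
        with pytest.raises(LabelError):
            mann_whitney_screen(ds)


class TestClassifiers:
    def test_perfect_separation_all_models(self):
        ds = labeled_ds(n_per_group=20, p=3, shift=8.0, seed=3)
        _, report = fit_classifiers(ds, seed=0)
        for name, ev in report.per_model.items():
            assert ev.accuracy == 1.0, name
            assert ev.auc == 1.0
            assert ev.sensitivity == 1.0 and ev.specificity == 1.0
            tp, fp = ev.confusion[0]
            fn, tn = ev.confusion[1]
            assert tp + fp + fn + tn == ds.n_subjects
            assert (tp + tn) / ds.n_subjects == ev.accuracy

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for s in range(25):
            ds = labeled_ds(n_per_group=25, p=3, shift=0.0, seed=100 + s)
            _, report = fit_classifiers(ds, models=("lda",), seed=s)
            aucs.append(report.per_model["lda"].auc)
        # training-set AUC is optimistic, but centred above/around 0.5 without signal
        assert 0.45 < np.mean(aucs) < 0.75

    def test_trapezoid_auc_equals_rank_statistic(self):
        from scipy.stats import mannwhitneyu

        ds = labeled_ds(n_per_group=30, p=4, shift=0.7, seed=5)
        _, report = fit_classifiers(ds, models=("logit",), seed=0)
        # recompute AUC as the normalized Mann-Whitney U of the scores
        fitted, _ = fit_classifiers(ds, models=("logit",), seed=0)
        prob = fitted["logit"].case_probability(ds.intensities)
        y, _ = ds.binary_labels()
        u = mannwhitneyu(prob[y == 1], prob[y == 0], alternative="two-sided").statistic
        assert report.per_model["logit"].auc == pytest.approx(u / (30 * 30), abs=1e-9)

    def test_importance_single_informative_covariate(self):
        rng = np.random.default_rng(6)
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        x = rng.standard_normal((n, 4))
        x[:, 2] += 3.0 * y  # only column 2 carries signal
        ds = SpectralDataset(x, [1.0, 2.0, 3.0, 4.0], list(map(str, range(n))),
                             ["MS" if v else "HC" for v in y])
        _, report = fit_classifiers(ds, seed=0)
        for name, imp in report.importances.items():
            assert np.argmax(imp) == 2, name
            assert imp[2] == 100.0
            assert np.all(imp <= 100.0) and np.all(imp >= 0.0)


class TestRepeatedCV:
    def test_counts_determinism_and_summary_ordering(self):
        ds = labeled_ds(n_per_group=20, p=3, shift=1.0, seed=7)
        cv1 = repeated_cv(ds, models=("lda",), k_folds=5, repeats=10, seed=3)
        cv2 = repeated_cv(ds, models=("lda",), k_folds=5, repeats=10, seed=3)
        assert len(cv1["values"]["lda"]["auc"]) == 50
        assert np.array_equal(cv1["values"]["lda"]["auc"], cv2["values"]["lda"]["auc"])
        s = cv1["summary"]["lda"]["auc"]
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]

    def test_separable_data_reaches_auc_one(self):
        ds = labeled_ds(n_per_group=20, p=3, shift=8.0, seed=8)
        cv = repeated_cv(ds, models=("logit", "lda"), seed=0)
        for m in ("logit", "lda"):
            assert cv["summary"][m]["auc"]["median"] == 1.0

    def test_small_class_rejected(self):
        ds = labeled_ds(n_per_group=3, p=2, seed=9)
        with pytest.raises(ValueError):
            repeated_cv(ds, k_folds=5)

    def test_type7_quantiles(self):
        s = summarize_metric([1.0, 2.0, 3.0, 4.0])
        assert s["q1"] == 1.75 and s["q3"] == 3.25  # linear interpolation
        assert s["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))


def test_pipeline_importance_on_synthetic_blocks():
    """Affected-block medoids should carry the importance signal."""
    from mipam import evaluate_medoids, select_features

    cfg = SyntheticSpectraConfig(
        n_subjects=85, block_sizes=(5, 5, 5), noise_sd=0.1,
        affected_blocks=(1,), effect_size=2.0, seed=23,
    )
    ds, blocks = generate_block_spectra(cfg)
    fs = select_features(ds, g=3, seed=0)
    result = evaluate_medoids(ds, fs.medoid_indices, models=("logit", "rf"), seed=0)
    medoid_blocks = blocks[fs.medoid_indices]
    informative = int(np.flatnonzero(medoid_blocks == 1)[0])
    for name, imp in result["training"].importances.items():
        assert np.argmax(imp) == informative, name
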