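"""Screening and classification of medoid wavenumbers.

After feature selection the medoids become the covariates of a binary
case/control problem.  This module provides:

* univariate screening: a two-sided Mann–Whitney U test per medoid with
  Benjamini–Hochberg adjustment across the selected set;
* three classifiers — unpenalized logistic regression (IRLS binomial GLM),
  linear discriminant analysis, and a seeded random forest — with
  confusion-matrix metrics at the 0.5 probability threshold, ROC curves
  and trapezoidal AUC;
* repeated stratified k-fold cross-validation with Table-style summaries
  (min, Q1, median, mean, SD, Q3, max; quantiles by linear interpolation);
* caret-style variable importances rescaled to [0, 100].

Cases (the lexicographically larger label code by default, e.g. "MS") are
the positive class throughout: sensitivity is case detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .data_io import DataError, LabelError, SpectralDataset

__all__ = [
    "ScreeningRow",
    "ModelEvaluation",
    "EvaluationReport",
    "MODEL_NAMES",
    "mann_whitney_screen",
    "fit_classifiers",
    "variable_importance",
    "repeated_cv",
    "summarize_metric",
]

MODEL_NAMES = ("logit", "lda", "rf")

RF_N_TREES = 500


@dataclass
class ScreeningRow:
    """One medoid's univariate case/control comparison."""

    wavenumber: float
    median_case: float
    median_control: float
    min: float
    max: float
    W: float
    p_value: float
    p_adjusted: float


@dataclass
class ModelEvaluation:
    """Training-set diagnostics of one classifier."""

    confusion: np.ndarray  # rows: predicted case/control; cols: observed
    sensitivity: float
    specificity: float
    accuracy: float
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    auc: float
    converged: bool = True


@dataclass
class EvaluationReport:
    per_model: dict[str, ModelEvaluation]
    importances: dict[str, np.ndarray] = field(default_factory=dict)
    positive_class: object = None


def mann_whitney_screen(
    ds: SpectralDataset, positive=None, alpha: float = 0.05
) -> list[ScreeningRow]:
    """Two-sided Mann–Whitney U test per column with BH adjustment.

    The reported W is the U statistic of the case sample.  Small samples
    without ties use the exact null distribution; otherwise the normal
    approximation with tie and continuity corrections is used.  Rows keep
    the column order of ``ds`` (the medoid list order).
    """
    if ds.labels is None:
        raise LabelError("screening requires group labels")
    y, pos = ds.binary_labels(positive)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise LabelError("each group needs at least 2 subjects")
    rows = []
    pvals = []
    for j in range(ds.n_wavenumbers):
        col = ds.intensities[:, j]
        case, ctrl = col[y == 1], col[y == 0]
        pooled = np.concatenate([case, ctrl])
        small = min(case.size, ctrl.size) < 20
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
        rows.append(
            ScreeningRow(
                wavenumber=float(ds.wavenumbers[j]),
                median_case=float(np.median(case)),
                median_control=float(np.median(ctrl)),
                min=float(pooled.min()),
                max=float(pooled.max()),
                W=float(res.statistic),
                p_value=float(res.pvalue),
                p_adjusted=np.nan,
            )
        )
        pvals.append(res.pvalue)
    adjusted = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    for row, padj in zip(rows, adjusted):
        row.p_adjusted = float(padj)
    return rows


class _LogitModel:
    """Unpenalized binomial GLM fitted by IRLS."""

    name = "logit"

    def fit(self, X, y, seed=None):
        self.converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                self.result = sm.GLM(
                    y, sm.add_constant(X, has_constant="add"), family=sm.families.Binomial()
                ).fit(maxiter=100)
            except Exception:
                # quasi-separated fits can fail outright; retry with few
                # IRLS steps, which bounds the coefficients
                self.result = sm.GLM(
                    y, sm.add_constant(X, has_constant="add"), family=sm.families.Binomial()
                ).fit(maxiter=10)
                self.converged = False
        if any("erfect" in str(w.message) for w in caught):
            self.converged = False
            warnings.warn(
                "logit fit is (quasi-)separated; coefficients are unstable "
                "but predicted classes are reported anyway",
                stacklevel=2,
            )
        return self

    def case_probability(self, X):
        return np.asarray(self.result.predict(sm.add_constant(X, has_constant="add")))

    def importance(self):
        # |z| of each slope; intercept excluded
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(np.asarray(self.result.tvalues)[1:])
        return np.nan_to_num(z)


class _LDAModel:
    name = "lda"

    def fit(self, X, y, seed=None):
        self.model = LinearDiscriminantAnalysis()
        self.model.fit(X, y)
        self.converged = True
        # pooled within-class sd, used for standardized coefficients
        resid = np.vstack([X[y == c] - X[y == c].mean(axis=0) for c in (0, 1)])
        self._pooled_sd = np.sqrt((resid**2).sum(axis=0) / (len(y) - 2))
        return self

    def case_probability(self, X):
        col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, col]

    def importance(self):
        return np.abs(self.model.coef_[0] * self._pooled_sd)


class _RFModel:
    name = "rf"

    def fit(self, X, y, seed=0):
        self.model = RandomForestClassifier(
            n_estimators=RF_N_TREES,
            max_features="sqrt",
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
        self.model.fit(X, y)
        self.converged = True
        return self

    def case_probability(self, X):
        col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, col]

    def importance(self):
        return self.model.feature_importances_


_MODEL_TYPES = {"logit": _LogitModel, "lda": _LDAModel, "rf": _RFModel}


def _confusion_metrics(y: np.ndarray, prob: np.ndarray, threshold: float = 0.5):
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    confusion = np.array([[tp, fp], [fn, tn]])
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    acc = (tp + tn) / y.size
    return confusion, sens, spec, acc


def _check_columns(ds: SpectralDataset) -> None:
    sds = ds.intensities.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DataError(
            f"zero-variance covariate(s) at wavenumber(s) {ds.wavenumbers[bad].tolist()}"
        )


def fit_classifiers(
    ds: SpectralDataset,
    models=MODEL_NAMES,
    seed: int = 0,
    positive=None,
) -> tuple[dict, EvaluationReport]:
    """Fit the requested classifiers on all rows and evaluate on them.

    Training-set performance (the analogue of an apparent error rate):
    confusion matrix and sensitivity/specificity/accuracy at the 0.5
    probability threshold, plus ROC and trapezoidal AUC from the
    continuous scores.  Use :func:`repeated_cv` for an out-of-sample view.
    """
    if ds.labels is None:
        raise LabelError("classification requires group labels")
    _check_columns(ds)
    y, pos = ds.binary_labels(positive)
    X = ds.intensities
    fitted = {}
    per_model = {}
    for name in models:
        model = _MODEL_TYPES[name]().fit(X, y, seed=seed)
        prob = model.case_probability(X)
        confusion, sens, spec, acc = _confusion_metrics(y, prob)
        fpr, tpr, _ = roc_curve(y, prob)
        per_model[name] = ModelEvaluation(
            confusion=confusion,
            sensitivity=sens,
            specificity=spec,
            accuracy=acc,
            roc=(fpr, tpr),
            auc=float(trapezoid_auc(fpr, tpr)),
            converged=model.converged,
        )
        fitted[name] = model
    report = EvaluationReport(
        per_model=per_model,
        importances=variable_importance(fitted),
        positive_class=pos,
    )
    return fitted, report


def variable_importance(fitted: dict) -> dict[str, np.ndarray]:
    """Caret-style importances: each model's scores min-max scaled to [0, 100]."""
    out = {}
    for name, model in fitted.items():
        v = np.abs(np.asarray(model.importance(), dtype=float))
        span = v.max() - v.min()
        out[name] = np.full_like(v, 100.0) if span == 0 else (v - v.min()) / span * 100.0
    return out


def summarize_metric(values) -> dict[str, float]:
    """min/Q1/median/mean/SD/Q3/max with type-7 (linear) quantiles."""
    v = np.asarray(values, dtype=float)
    return {
        "min": float(v.min()),
        "q1": float(np.quantile(v, 0.25)),
        "median": float(np.median(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "q3": float(np.quantile(v, 0.75)),
        "max": float(v.max()),
    }


def repeated_cv(
    ds: SpectralDataset,
    models=MODEL_NAMES,
    k_folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    positive=None,
) -> dict:
    """Repeated stratified k-fold cross-validation of the classifiers.

    Each repeat draws a fresh stratified split; every held-out fold yields
    AUC, sensitivity and specificity per model, giving
    ``k_folds * repeats`` values per metric, summarized as in
    :func:`summarize_metric`.  Deterministic given ``seed``.
    """
    if ds.labels is None:
        raise LabelError("cross-validation requires group labels")
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    _check_columns(ds)
    y, pos = ds.binary_labels(positive)
    if min((y == 1).sum(), (y == 0).sum()) < k_folds:
        raise ValueError("each class needs at least k_folds members for stratification")
    X = ds.intensities

    values = {name: {"auc": [], "sensitivity": [], "specificity": []} for name in models}
    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats)
    for r, rs in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(rs) % (2**31))
        for f, (train, test) in enumerate(skf.split(X, y)):
            fold_seed = int(np.random.SeedSequence([seed, r, f]).generate_state(1)[0])
            for name in models:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = _MODEL_TYPES[name]().fit(X[train], y[train], seed=fold_seed)
                prob = model.case_probability(X[test])
                _, sens, spec, _ = _confusion_metrics(y[test], prob)
                values[name]["auc"].append(float(roc_auc_score(y[test], prob)))
                values[name]["sensitivity"].append(float(sens))
                values[name]["specificity"].append(float(spec))

    return {
        "positive_class": pos,
        "k_folds": k_folds,
        "repeats": repeats,
        "seed": seed,
        "values": {m: {k: np.asarray(v) for k, v in d.items()} for m, d in values.items()},
        "summary": {
            m: {k: summarize_metric(v) for k, v in d.items()} for m, d in values.items()
        },
    }
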