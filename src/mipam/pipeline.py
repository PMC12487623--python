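"""End-to-end convenience wrappers: spectra -> medoids -> evaluation.

The canonical workflow is

1. estimate the pairwise KSG MI matrix of the wavenumbers,
2. transform it to the normalized-MI dissimilarity,
3. cluster the wavenumbers with PAM (either at a fixed G or with the
   silhouette sweep),
4. keep the medoid wavenumbers as covariates,
5. screen them univariately and evaluate classifiers by repeated
   stratified cross-validation.

Setting ``matrix="pearson"`` swaps step 1-2 for the 1 - |r| comparator,
everything else unchanged — the comparison that isolates what the MI
measure itself buys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import PairwiseMatrix, SpectralDataset
from .dissimilarity import mi_to_dissimilarity, pearson_dissimilarity
from .mi import KSGSettings, mi_matrix
from .model_selection import SelectionReport, select_g
from .pam import Partition, pam
from .screening import EvaluationReport, fit_classifiers, mann_whitney_screen, repeated_cv

__all__ = ["FeatureSelectionResult", "select_features", "evaluate_medoids"]


@dataclass
class FeatureSelectionResult:
    dissimilarity: PairwiseMatrix
    partition: Partition
    medoid_indices: list[int]
    medoid_wavenumbers: np.ndarray
    selection: SelectionReport | None = None


def select_features(
    ds: SpectralDataset,
    matrix: str = "mi",
    k: int = 3,
    g: int | None = None,
    g_range: tuple[int, int] = (2, 40),
    seed: int = 0,
) -> FeatureSelectionResult:
    """Run MI (or Pearson) dissimilarity + PAM and return the medoids.

    ``g=None`` selects the cluster count by the silhouette sweep over
    ``g_range``; otherwise PAM runs at the given G.
    """
    if matrix == "mi":
        D = mi_to_dissimilarity(mi_matrix(ds, KSGSettings(k=k, seed=seed)))
    elif matrix == "pearson":
        D = pearson_dissimilarity(ds)
    else:
        raise ValueError(f"matrix must be 'mi' or 'pearson', got {matrix!r}")
    selection = None
    if g is None:
        selection = select_g(D, *g_range)
        part = selection.partition
    else:
        part = pam(D, g)
    return FeatureSelectionResult(
        dissimilarity=D,
        partition=part,
        medoid_indices=list(part.medoids),
        medoid_wavenumbers=ds.wavenumbers[part.medoids],
        selection=selection,
    )


def evaluate_medoids(
    ds: SpectralDataset,
    medoid_indices,
    models=("logit", "lda", "rf"),
    k_folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    positive=None,
) -> dict:
    """Screen the medoid covariates and evaluate classifiers on them.

    Returns the screening rows, the training-set :class:`EvaluationReport`
    and the repeated-CV summary, all computed on the dataset restricted to
    the medoid columns.
    """
    sub = ds.select_wavenumbers(medoid_indices)
    screening = mann_whitney_screen(sub, positive=positive)
    fitted, report = fit_classifiers(sub, models=models, seed=seed, positive=positive)
    cv = repeated_cv(
        sub, models=models, k_folds=k_folds, repeats=repeats, seed=seed, positive=positive
    )
    return {"screening": screening, "training": report, "cv": cv, "models": fitted}
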