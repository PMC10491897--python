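"""Feature selection and patient-held-out SVM classification.

Features are the per-wavenumber SNV intensities on the common 1 cm^-1
grid, minus the 1060-1100 cm^-1 interval (possible surface-blood
phosphate contamination). Feature selection uses an L1-regularized
linear SVM path: features are ranked by the penalty level at which their
weight first becomes nonzero (earlier entry = stronger feature). The
final classifier is a plain hinge-loss linear SVM with soft-margin
parameter C, validated with leave-one-patient-out (LOPO) cross
validation — all spectra of one patient form the held-out fold, and
feature selection is (by default) redone inside each fold using training
patients only, so no patient-level information leaks. Hyperparameters
(C, number of features k) are chosen by grid search on the LOPO AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVC, l1_min_c

from .preprocess import ProcessedSpectrum
from .synthetic_cohort import CANCER_NECROSIS, NORMAL_BENIGN

__all__ = [
    "DEFAULT_EXCLUDE_INTERVAL",
    "DEFAULT_C_GRID",
    "DEFAULT_K_GRID",
    "FeatureMatrix",
    "Hyperparams",
    "CVPredictions",
    "LinearDecisionModel",
    "GridSearchResult",
    "build_feature_matrix",
    "l1_feature_ranking",
    "group_selected_bands",
    "train_svm",
    "lopo_cv",
    "grid_search",
]

#: Blood-band exclusion window (closed interval, cm^-1).
DEFAULT_EXCLUDE_INTERVAL = (1060.0, 1100.0)
#: Soft-margin grid spanning 0.01..5 and feature counts 5..20.
DEFAULT_C_GRID = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0)
DEFAULT_K_GRID = tuple(range(5, 21))

_LABEL_CODE = {NORMAL_BENIGN: 0, CANCER_NECROSIS: 1}


@dataclass(frozen=True)
class FeatureMatrix:
    """Spectra-by-wavenumber design matrix with patient bookkeeping."""

    X: np.ndarray  # (n_spectra, n_features)
    wavenumbers: np.ndarray  # (n_features,) cm^-1, ascending
    y: np.ndarray  # (n_spectra,) 0 = normal/benign, 1 = cancer/necrosis
    patient_ids: np.ndarray  # (n_spectra,)

    def __post_init__(self) -> None:
        if self.X.shape != (self.y.size, self.wavenumbers.size):
            raise ValueError("inconsistent feature-matrix shapes")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass(frozen=True)
class Hyperparams:
    """Soft-margin parameter C and number of selected features k."""

    C: float
    k: int

    def __post_init__(self) -> None:
        if not 0.01 <= self.C <= 5.0:
            raise ValueError("C must lie in [0.01, 5]")
        if not 5 <= self.k <= 20:
            raise ValueError("k must lie in [5, 20]")


@dataclass(frozen=True)
class LinearDecisionModel:
    """Linear decision function f(x) = w . x + b over selected features."""

    weights: np.ndarray
    intercept: float
    feature_indices: np.ndarray  # columns of the FeatureMatrix used

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.feature_indices] @ self.weights + self.intercept


@dataclass
class CVPredictions:
    """Per-spectrum LOPO decision scores and per-fold selections."""

    scores: np.ndarray  # NaN where the fold was skipped
    fold_ids: np.ndarray  # held-out patient id per spectrum
    y: np.ndarray
    selected_wavenumbers: dict[str, np.ndarray]  # per held-out patient
    skipped_folds: list[str]

    def valid(self) -> np.ndarray:
        return ~np.isnan(self.scores)


@dataclass
class GridSearchResult:
    best: Hyperparams
    table: pd.DataFrame  # columns C, k, auc
    best_predictions: CVPredictions
    fold_rankings: dict[str, np.ndarray] | None = None  # per held-out patient


def build_feature_matrix(
    dataset: Sequence[ProcessedSpectrum],
    exclude_interval: tuple[float, float] | None = DEFAULT_EXCLUDE_INTERVAL,
) -> FeatureMatrix:
    """Stack SNV spectra into a design matrix, dropping the excluded band.

    The exclusion interval is closed: grid points at both ends are
    removed. Pass ``None`` to keep the full axis.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    axis = dataset[0].axis
    for spec in dataset:
        if spec.axis.shape != axis.shape or not np.allclose(spec.axis, axis):
            raise ValueError("all spectra must share the common wavenumber axis")
    keep = np.ones(axis.size, dtype=bool)
    if exclude_interval is not None:
        lo, hi = exclude_interval
        keep &= ~((axis >= lo) & (axis <= hi))
    X = np.stack([s.snv_intensity for s in dataset])[:, keep]
    y = np.array([_LABEL_CODE[s.label] for s in dataset])
    patients = np.array([s.patient_id for s in dataset])
    return FeatureMatrix(X=X, wavenumbers=axis[keep].copy(), y=y, patient_ids=patients)


def l1_feature_ranking(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    n_path: int = 50,
    n_top: int | None = None,
    tol: float = 1e-4,
) -> np.ndarray:
    """Rank features by an L1-penalized linear-SVM regularization path.

    Fits squared-hinge L1 linear SVMs over ``n_path`` log-spaced penalty
    levels starting just above the smallest C producing any nonzero
    weight, and records for each feature the level at which its weight
    first becomes nonzero. Earlier entry ranks higher; ties are broken by
    |weight| at the last fitted path point (descending), then by
    wavenumber (ascending). Features that never enter rank last under the
    same tie rules. If ``n_top`` is given, the path stops as soon as that
    many features have entered (the tail ordering is still deterministic).

    Returns the feature indices in rank order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("feature ranking requires both classes")
    d = X.shape[1]
    if wavenumbers is None:
        wavenumbers = np.arange(d, dtype=float)
    cs = l1_min_c(X, y, loss="squared_hinge") * np.logspace(0.02, 3.0, n_path)
    entry = np.full(d, np.inf)
    final_w = np.zeros(d)
    for step, C in enumerate(cs):
        clf = LinearSVC(
            C=C,
            penalty="l1",
            loss="squared_hinge",
            dual=False,
            tol=tol,
            max_iter=20000,
            random_state=0,
        )
        clf.fit(X, y)
        w = clf.coef_.ravel()
        active = np.abs(w) > 1e-9
        entry[active & np.isinf(entry)] = step
        final_w = w
        if n_top is not None and np.isfinite(entry).sum() >= n_top:
            break
    order = np.lexsort((wavenumbers, -np.abs(final_w), entry))
    return order


def group_selected_bands(
    ranked_wavenumbers: Sequence[float], max_gap: float = 10.0
) -> list[list[float]]:
    """Group ranked wavenumber features into contiguous bands.

    Individual selected wavenumbers within ``max_gap`` cm^-1 of an
    earlier-ranked feature belong to the same band (correlated columns of
    one vibrational band enter the L1 path together). Bands are returned
    in rank order of their first member; this is a reporting convention —
    models always operate on individual wavenumber features.
    """
    bands: list[list[float]] = []
    for w in ranked_wavenumbers:
        for band in bands:
            if min(abs(w - x) for x in band) <= max_gap:
                band.append(float(w))
                break
        else:
            bands.append([float(w)])
    return bands


def train_svm(X: np.ndarray, y: np.ndarray, C: float) -> LinearDecisionModel:
    """Train the final hinge-loss linear SVM on the selected features.

    ``X`` must already be restricted to the selected columns. The
    decision function is positive for the cancer/necrosis class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training fold contains a single class")
    if C <= 0:
        raise ValueError("C must be > 0")
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(X, y)
    return LinearDecisionModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_indices=np.arange(X.shape[1]),
    )


def _fold_rankings(fm: FeatureMatrix, n_top: int) -> dict[str, np.ndarray]:
    """Inside-fold L1 rankings, one per held-out patient."""
    rankings: dict[str, np.ndarray] = {}
    for patient in sorted(set(fm.patient_ids)):
        train = fm.patient_ids != patient
        if np.unique(fm.y[train]).size < 2:
            continue
        rankings[patient] = l1_feature_ranking(
            fm.X[train], fm.y[train], fm.wavenumbers, n_top=n_top
        )
    return rankings


def lopo_cv(
    fm: FeatureMatrix,
    hp: Hyperparams,
    rankings: dict[str, np.ndarray] | None = None,
) -> CVPredictions:
    """Leave-one-patient-out cross validation.

    One fold per patient; feature selection runs inside each fold on the
    training patients only (precomputed fold rankings may be passed to
    avoid refitting the L1 path when sweeping C and k). Folds whose
    training partition lacks a class are skipped and flagged.
    """
    patients = sorted(set(fm.patient_ids))
    if len(patients) < 2:
        raise ValueError("LOPO CV requires at least two patients")
    if rankings is None:
        rankings = _fold_rankings(fm, n_top=hp.k)
    scores = np.full(fm.y.size, np.nan)
    selected: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for patient in patients:
        test = fm.patient_ids == patient
        train = ~test
        if np.unique(fm.y[train]).size < 2 or patient not in rankings:
            skipped.append(patient)
            continue
        top = rankings[patient][: hp.k]
        try:
            model = train_svm(fm.X[train][:, top], fm.y[train], hp.C)
        except ValueError:
            skipped.append(patient)
            continue
        scores[test] = fm.X[test][:, top] @ model.weights + model.intercept
        selected[patient] = fm.wavenumbers[np.sort(top)]
    return CVPredictions(
        scores=scores,
        fold_ids=fm.patient_ids.copy(),
        y=fm.y.copy(),
        selected_wavenumbers=selected,
        skipped_folds=skipped,
    )


def grid_search(
    fm: FeatureMatrix,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> GridSearchResult:
    """Exhaustive (C, k) search scored by pooled LOPO AUC.

    The L1 ranking per fold is computed once at the largest k and reused
    across the grid (the path ordering does not depend on C or k). Ties
    on AUC are broken by smaller k, then smaller C.
    """
    C_grid = list(C_grid)
    k_grid = list(k_grid)
    if not C_grid or not k_grid:
        raise ValueError("empty hyperparameter grid")
    rankings = _fold_rankings(fm, n_top=max(k_grid))
    rows = []
    best_key = None
    best_cell: tuple[Hyperparams, CVPredictions] | None = None
    for k in sorted(k_grid):
        for C in sorted(C_grid):
            hp = Hyperparams(C=C, k=k)
            preds = lopo_cv(fm, hp, rankings=rankings)
            ok = preds.valid()
            auc = (
                roc_auc_score(preds.y[ok], preds.scores[ok])
                if ok.any() and np.unique(preds.y[ok]).size == 2
                else np.nan
            )
            rows.append({"C": C, "k": k, "auc": auc})
            key = (-auc if np.isfinite(auc) else np.inf, k, C)
            if best_key is None or key < best_key:
                best_key = key
                best_cell = (hp, preds)
    assert best_cell is not None
    return GridSearchResult(
        best=best_cell[0],
        table=pd.DataFrame(rows),
        best_predictions=best_cell[1],
        fold_rankings=rankings,
    )
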