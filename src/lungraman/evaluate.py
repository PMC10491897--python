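"""Model evaluation: ROC analysis, permutation control, band statistics,
and cohort bookkeeping.

AUC is the empirical ROC area, identical to the normalized Mann-Whitney
pair count with ties counted one half. The reported operating point
maximizes Youden's J (sensitivity + specificity - 1); alternative rules
(fixed specificity, closest-to-corner) are selectable. The permutation
control retrains the full patient-held-out pipeline N times with labels
randomly reassigned, which should drive the AUC to chance if the real
model's performance is not an artifact of overfitting. Univariate band
statistics compare class intensity distributions at each canonical band
with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .classify import FeatureMatrix, Hyperparams, lopo_cv
from .preprocess import ProcessedSpectrum
from .synthetic_cohort import BAND_CENTERS, CANCER_NECROSIS, CATEGORY_CLASS, NORMAL_BENIGN

__all__ = [
    "RocResult",
    "PermutationSummary",
    "BandStat",
    "CohortTally",
    "roc_auc",
    "permutation_null",
    "band_statistics",
    "tally_cohort",
]


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_point: dict  # {"threshold", "sensitivity", "specificity"}


@dataclass(frozen=True)
class PermutationSummary:
    n_repeats: int
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    seed: int
    n_failed: int


@dataclass(frozen=True)
class BandStat:
    center: float
    n_cancer: int
    n_normal: int
    statistic: float
    p_value: float
    stars: str  # "**" for p<0.01, "****" for p<0.0001
    p_holm: float  # Holm-adjusted across the tested bands (reported separately)


@dataclass(frozen=True)
class CohortTally:
    """Pure-arithmetic cohort bookkeeping (acquired vs retained)."""

    acquired_normal_benign: int
    acquired_cancer_necrosis: int
    acquired_total: int
    retained_normal_benign: int | None
    retained_cancer_necrosis: int | None
    retained_total: int | None
    class_ratio_before: float  # cancer/necrosis : normal/benign, 2 decimals
    class_ratio_after: float | None
    rejected_percent: int | None  # nearest integer percent


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    return ""


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    operating_rule: str = "youden",
    min_specificity: float = 0.9,
) -> RocResult:
    """Empirical ROC curve, AUC, and a single operating point.

    The AUC equals the Mann-Whitney statistic over all positive/negative
    pairs with ties counted 1/2. Operating rules: ``youden`` (maximal
    sensitivity + specificity - 1; ties resolved toward higher
    sensitivity), ``fixed_specificity`` (most sensitive point with
    specificity >= ``min_specificity``), ``closest_corner`` (nearest to
    the (0, 1) corner).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC analysis requires both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    auc = float(roc_auc_score(labels, scores))
    if operating_rule == "youden":
        j = sens + spec - 1.0
        candidates = np.flatnonzero(j >= j.max() - 1e-12)
        best = candidates[np.argmax(sens[candidates])]
    elif operating_rule == "fixed_specificity":
        ok = np.flatnonzero(spec >= min_specificity)
        best = ok[np.argmax(sens[ok])] if ok.size else int(np.argmax(spec))
    elif operating_rule == "closest_corner":
        best = int(np.argmin((1.0 - sens) ** 2 + (1.0 - spec) ** 2))
    else:
        raise ValueError(f"unknown operating rule {operating_rule!r}")
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        operating_point={
            "threshold": float(thresholds[best]),
            "sensitivity": float(sens[best]),
            "specificity": float(spec[best]),
        },
    )


def permutation_null(
    fm: FeatureMatrix,
    hp: Hyperparams,
    n_repeats: int = 100,
    seed: int = 0,
    patient_level: bool = False,
) -> PermutationSummary:
    """Random-label control: rerun the LOPO pipeline on shuffled labels.

    Labels are shuffled across spectra (patient ids untouched); with
    ``patient_level=True`` whole patient-class blocks are shuffled
    instead. Feature selection is redone inside each fold on the shuffled
    labels, so the control probes the entire modeling chain. Repeats that
    fail (e.g. a fold left with one class) are excluded and counted.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = substream(seed, "permutation")
    aucs = []
    n_failed = 0
    for _ in range(n_repeats):
        if patient_level:
            y_perm = np.empty_like(fm.y)
            patients = sorted(set(fm.patient_ids))
            labels = [fm.y[fm.patient_ids == p] for p in patients]
            order = rng.permutation(len(patients))
            for p, k in zip(patients, order):
                block = fm.patient_ids == p
                src = labels[k]
                idx = rng.integers(0, src.size, size=int(block.sum()))
                y_perm[block] = src[idx]
        else:
            y_perm = rng.permutation(fm.y)
        shuffled = FeatureMatrix(
            X=fm.X, wavenumbers=fm.wavenumbers, y=y_perm, patient_ids=fm.patient_ids
        )
        try:
            preds = lopo_cv(shuffled, hp)
            ok = preds.valid()
            if not ok.any() or np.unique(preds.y[ok]).size < 2:
                raise ValueError("no scorable folds")
            aucs.append(float(roc_auc_score(preds.y[ok], preds.scores[ok])))
        except ValueError:
            n_failed += 1
    aucs = np.asarray(aucs)
    return PermutationSummary(
        n_repeats=n_repeats,
        aucs=aucs,
        mean_auc=float(aucs.mean()) if aucs.size else float("nan"),
        sd_auc=float(aucs.std(ddof=1)) if aucs.size > 1 else float("nan"),
        seed=seed,
        n_failed=n_failed,
    )


def band_statistics(
    dataset: Sequence[ProcessedSpectrum],
    band_centers: Sequence[float] = BAND_CENTERS,
) -> list[BandStat]:
    """Two-sided rank-sum class comparison of SNV intensity per band.

    Each band is evaluated at the nearest grid point of the common axis.
    Raises if a band falls off the axis or either class has fewer than
    two spectra. Raw p-values drive the star annotation; a Holm-adjusted
    column is reported alongside, clearly separated from the raw one.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    axis = dataset[0].axis
    cancer = np.stack([s.snv_intensity for s in dataset if s.label == CANCER_NECROSIS]) if any(
        s.label == CANCER_NECROSIS for s in dataset
    ) else np.empty((0, axis.size))
    normal = np.stack([s.snv_intensity for s in dataset if s.label == NORMAL_BENIGN]) if any(
        s.label == NORMAL_BENIGN for s in dataset
    ) else np.empty((0, axis.size))
    if cancer.shape[0] < 2 or normal.shape[0] < 2:
        raise ValueError("band statistics require at least two spectra per class")
    stats, pvals, ns = [], [], []
    for center in band_centers:
        if not axis[0] <= center <= axis[-1]:
            raise ValueError(f"band {center} cm^-1 lies outside the spectral axis")
        col = int(np.argmin(np.abs(axis - center)))
        res = mannwhitneyu(cancer[:, col], normal[:, col], alternative="two-sided")
        stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
        ns.append((cancer.shape[0], normal.shape[0]))
    holm = multipletests(pvals, method="holm")[1]
    return [
        BandStat(
            center=float(c),
            n_cancer=n[0],
            n_normal=n[1],
            statistic=s,
            p_value=p,
            stars=_stars(p),
            p_holm=float(ph),
        )
        for c, n, s, p, ph in zip(band_centers, ns, stats, pvals, holm)
    ]


def tally_cohort(
    acquired: dict[str, int],
    retained: dict[str, int] | None = None,
    class_map: dict[str, str] | None = None,
) -> CohortTally:
    """Cohort tally: per-class totals, ratios, and rejection percentage.

    ``acquired``/``retained`` map histology category to sample count;
    ``class_map`` maps category to binary class (defaults to the built-in
    histology taxonomy). Ratios are rounded to two decimals and the
    rejection fraction to the nearest integer percent, matching the usual
    reporting convention.
    """
    if class_map is None:
        class_map = CATEGORY_CLASS

    def class_totals(counts: dict[str, int]) -> tuple[int, int]:
        pos = neg = 0
        for category, count in counts.items():
            if count < 0:
                raise ValueError(f"negative count for category {category!r}")
            if class_map[category] == CANCER_NECROSIS:
                pos += count
            else:
                neg += count
        return neg, pos

    neg_a, pos_a = class_totals(acquired)
    total_a = neg_a + pos_a
    if total_a == 0:
        raise ValueError("empty cohort: all acquired counts are zero")
    ratio_before = round(pos_a / neg_a, 2) if neg_a else float("nan")
    if retained is None:
        return CohortTally(
            acquired_normal_benign=neg_a,
            acquired_cancer_necrosis=pos_a,
            acquired_total=total_a,
            retained_normal_benign=None,
            retained_cancer_necrosis=None,
            retained_total=None,
            class_ratio_before=ratio_before,
            class_ratio_after=None,
            rejected_percent=None,
        )
    neg_r, pos_r = class_totals(retained)
    total_r = neg_r + pos_r
    if total_r > total_a:
        raise ValueError("retained counts exceed acquired counts")
    return CohortTally(
        acquired_normal_benign=neg_a,
        acquired_cancer_necrosis=pos_a,
        acquired_total=total_a,
        retained_normal_benign=neg_r,
        retained_cancer_necrosis=pos_r,
        retained_total=total_r,
        class_ratio_before=ratio_before,
        class_ratio_after=round(pos_r / neg_r, 2) if neg_r else float("nan"),
        rejected_percent=round(100 * (total_a - total_r) / total_a),
    )
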