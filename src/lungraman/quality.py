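"""Spectral quality factor (QF) and dataset filtering.

The QF scores how much of an SNV-normalized spectrum's energy lives at
spectral scales wider than a smoothing window — i.e. how Raman-peak-like
rather than noise-like the spectrum is. Because an SNV spectrum has unit
variance, the variance of its smoothed version is exactly that energy
fraction: close to 1 for clean tissue spectra (bands are much wider than
the window) and close to the smoother's noise-variance factor for pure
white noise. Spectra with QF at or below a threshold (0.4 by default,
strict inequality for retention) are rejected before modeling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .preprocess import ProcessedSpectrum
from .synthetic_cohort import CANCER_NECROSIS, NORMAL_BENIGN

__all__ = ["QualitySummary", "SplitResult", "quality_factor", "split_by_qf"]


@dataclass(frozen=True)
class QualitySummary:
    """Bookkeeping of a QF-threshold split."""

    n_total: int
    n_retained: int
    n_rejected: int
    rejected_fraction: float
    retained_per_category: dict[str, int]
    total_per_category: dict[str, int]
    class_ratio_before: float  # cancer/necrosis : normal/benign, 2 decimals
    class_ratio_after: float


@dataclass(frozen=True)
class SplitResult:
    retained: list[ProcessedSpectrum]
    rejected: list[ProcessedSpectrum]
    summary: QualitySummary


def quality_factor(
    snv_spectrum: np.ndarray,
    smooth_window: float = 13.0,
    polyorder: int = 3,
    axis_step: float = 1.0,
) -> float:
    """Quality factor of an SNV-normalized spectrum, in [0, 1].

    QF = variance of the Savitzky-Golay-smoothed spectrum (window
    ``smooth_window`` in cm^-1, cubic by default), clipped to [0, 1].
    Since the input has unit variance this is the fraction of spectral
    energy at scales the smoother preserves. White noise scores the
    smoother's noise factor (~0.17 for the defaults); spectra dominated
    by real vibrational bands score close to 1.

    The input must already be SNV-normalized (mean ~0, sd ~1); anything
    else is rejected, because the energy-fraction interpretation relies
    on unit total variance.
    """
    x = np.asarray(snv_spectrum, dtype=float)
    if abs(float(x.mean())) > 0.01 or abs(float(x.std()) - 1.0) > 0.01:
        raise ValueError("quality_factor requires an SNV-normalized spectrum (mean 0, sd 1)")
    window = max(int(round(smooth_window / axis_step)) | 1, polyorder + 2 | 1)
    window = min(window, x.size | 1)
    smoothed = savgol_filter(x, window, polyorder)
    return float(np.clip(np.var(smoothed), 0.0, 1.0))


def split_by_qf(dataset: Sequence[ProcessedSpectrum], threshold: float = 0.4) -> SplitResult:
    """Partition spectra into retained (QF strictly above threshold) and
    rejected, with cohort bookkeeping.

    Class ratios (cancer/necrosis over normal/benign) before and after
    the cut are rounded to two decimals for reporting.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    for spec in dataset:
        if spec.qf is None:
            raise ValueError("every spectrum must have a QF before splitting")
    retained = [s for s in dataset if s.qf > threshold]
    rejected = [s for s in dataset if s.qf <= threshold]

    def ratio(group: Sequence[ProcessedSpectrum]) -> float:
        pos = sum(1 for s in group if s.label == CANCER_NECROSIS)
        neg = sum(1 for s in group if s.label == NORMAL_BENIGN)
        return round(pos / neg, 2) if neg else float("nan")

    summary = QualitySummary(
        n_total=len(dataset),
        n_retained=len(retained),
        n_rejected=len(rejected),
        rejected_fraction=len(rejected) / len(dataset),
        retained_per_category=dict(Counter(s.category for s in retained)),
        total_per_category=dict(Counter(s.category for s in dataset)),
        class_ratio_before=ratio(dataset),
        class_ratio_after=ratio(retained),
    )
    return SplitResult(retained=retained, rejected=rejected, summary=summary)
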