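"""Optional diagnostic plots (requires the ``plot`` extra)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .evaluate import RocResult
from .preprocess import ProcessedSpectrum


def plot_roc(roc: RocResult, path: str | Path) -> None:
    """Write a ROC curve with the operating point marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1.0 - roc.specificity, roc.sensitivity, lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    op = roc.operating_point
    ax.plot(1.0 - op["specificity"], op["sensitivity"], "ro", ms=5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_qf_trace(spectra: Sequence[ProcessedSpectrum], threshold: float, path: str | Path) -> None:
    """QF per measurement in acquisition order, with the cutoff line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    qfs = [s.qf for s in spectra]
    colors = ["tab:red" if s.label == "cancer_necrosis" else "tab:blue" for s in spectra]
    ax.scatter(range(len(qfs)), qfs, c=colors, s=10)
    ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("measurement (acquisition order)")
    ax.set_ylabel("quality factor")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
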