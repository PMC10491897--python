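"""Spectral preprocessing chain.

Raw repeat frames are turned into an analysis-ready spectrum by, in
order: repeat averaging, dark-count subtraction (scaled by the
integration-time ratio), instrument-response correction, wavenumber
calibration and resampling onto a common 1 cm^-1 grid from 800 to
1700 cm^-1, fluorescence-baseline removal with the bubble-envelope
("BubbleFill") algorithm, and standard normal variate (SNV)
normalization. The stage order matters and is regression-tested; it is
configurable but flagged, since swapping e.g. SNV ahead of baseline
removal changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .synthetic_cohort import SimulatedMeasurement

__all__ = [
    "COMMON_AXIS",
    "CalibrationFit",
    "ResponseCurve",
    "ProcessedSpectrum",
    "PreprocessParams",
    "PipelineStageError",
    "BubbleFillResult",
    "average_repeats",
    "subtract_dark",
    "detect_calibration_peaks",
    "fit_calibration",
    "identity_calibration",
    "estimate_response",
    "flat_response",
    "correct_response",
    "resample_to_axis",
    "bubblefill",
    "snv",
    "preprocess_measurement",
]

#: Common fingerprint axis: 1 cm^-1 steps, 800..1700 inclusive (901 points).
COMMON_AXIS = np.arange(800.0, 1701.0, 1.0)


class PipelineStageError(RuntimeError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class CalibrationFit:
    """Polynomial pixel -> wavenumber calibration."""

    coefficients: tuple[float, ...]  # ascending powers
    order: int
    residuals: np.ndarray  # per-peak, cm^-1
    rms_residual: float

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(pixels, dtype=float), self.coefficients)


@dataclass(frozen=True)
class ResponseCurve:
    """Per-pixel multiplicative instrument-sensitivity correction."""

    factors: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or not np.all(f > 0):
            raise ValueError("response factors must be finite and strictly positive")


@dataclass
class ProcessedSpectrum:
    """SNV-normalized fingerprint spectrum with its intermediates.

    ``baseline + raman_before_snv`` reconstructs the response-corrected,
    resampled spectrum exactly; ``snv_intensity`` has mean 0 and unit
    population standard deviation. ``qf`` is filled by the quality module.
    """

    axis: np.ndarray
    snv_intensity: np.ndarray
    raman_before_snv: np.ndarray
    baseline: np.ndarray
    patient_id: str
    label: str
    category: str
    qf: float | None = None
    provenance: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables for the preprocessing chain."""

    min_bubble_width: float = 100.0  # cm^-1; wider than any tissue band
    axis: np.ndarray = field(default_factory=lambda: COMMON_AXIS.copy())
    snv_before_baseline: bool = False  # non-standard order; for regression tests only


def average_repeats(frames: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of the repeat frames."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    n = frames[0].shape
    if any(f.shape != n for f in frames):
        raise ValueError("ragged frames: all repeat frames must have equal length")
    return np.mean(frames, axis=0)


def subtract_dark(
    frame: np.ndarray, dark_frame: np.ndarray, frame_time: float, dark_time: float
) -> np.ndarray:
    """Subtract the dark counts, scaled by the integration-time ratio.

    Counts are time-proportional, so a dark frame acquired over
    ``dark_time`` is rescaled by ``frame_time / dark_time`` before
    subtraction. The result is not clipped: slightly negative values are
    legitimate and clipping them would bias the subsequent baseline fit.
    """
    frame = np.asarray(frame, dtype=float)
    dark_frame = np.asarray(dark_frame, dtype=float)
    if frame.shape != dark_frame.shape:
        raise ValueError("frame and dark_frame must have equal length")
    if frame_time <= 0 or dark_time <= 0:
        raise ValueError("integration times must be > 0")
    return frame - dark_frame * (frame_time / dark_time)


def detect_calibration_peaks(frame: np.ndarray, min_rel_height: float = 0.2) -> np.ndarray:
    """Locate calibration peaks with sub-pixel (parabolic) refinement."""
    frame = np.asarray(frame, dtype=float)
    idx, _ = find_peaks(frame, height=min_rel_height * frame.max(), distance=5)
    refined = []
    for i in idx:
        if 0 < i < frame.size - 1:
            denom = frame[i - 1] - 2 * frame[i] + frame[i + 1]
            delta = 0.5 * (frame[i - 1] - frame[i + 1]) / denom if denom != 0 else 0.0
            refined.append(i + np.clip(delta, -0.5, 0.5))
        else:
            refined.append(float(i))
    return np.asarray(refined)


def fit_calibration(
    peak_pixels: Sequence[float],
    reference_wavenumbers: Sequence[float],
    order: int = 2,
    pixel_range: tuple[float, float] | None = None,
) -> CalibrationFit:
    """Least-squares polynomial pixel -> wavenumber fit.

    Requires at least ``order + 1`` peaks; raises if the fitted map is
    not strictly increasing over ``pixel_range`` (default: the span of
    the peak pixels).
    """
    px = np.asarray(peak_pixels, dtype=float)
    ref = np.asarray(reference_wavenumbers, dtype=float)
    if px.size != ref.size:
        raise ValueError("peak_pixels and reference_wavenumbers must have equal length")
    if px.size < order + 1:
        raise ValueError(f"need at least {order + 1} peaks for an order-{order} fit")
    if not (np.all(np.diff(px) > 0) and np.all(np.diff(ref) > 0)):
        raise ValueError("peak lists must be sorted ascending")
    coeffs = np.polynomial.polynomial.polyfit(px, ref, order)
    fitted = np.polynomial.polynomial.polyval(px, coeffs)
    residuals = ref - fitted
    if pixel_range is None:
        pixel_range = (float(px[0]), float(px[-1]))
    grid = np.linspace(pixel_range[0], pixel_range[1], 512)
    if not np.all(np.diff(np.polynomial.polynomial.polyval(grid, coeffs)) > 0):
        raise ValueError("fitted calibration is not strictly increasing over the pixel range")
    return CalibrationFit(
        coefficients=tuple(float(c) for c in coeffs),
        order=order,
        residuals=residuals,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
    )


def identity_calibration(wavenumbers: np.ndarray) -> CalibrationFit:
    """Calibration for data already on a known wavenumber axis.

    Fits an exact linear map when the axis is uniform; used for tests and
    for simulated instruments with a known axis.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    step = float(np.mean(np.diff(nu)))
    return CalibrationFit(
        coefficients=(float(nu[0]), step),
        order=1,
        residuals=np.zeros(2),
        rms_residual=0.0,
    )


def estimate_response(
    measured_reference: np.ndarray,
    certified_shape: np.ndarray,
    smooth_window: int = 31,
) -> ResponseCurve:
    """Instrument response = measured reference / certified shape, smoothed.

    ``smooth_window`` is the Savitzky-Golay window in pixels (odd,
    quadratic); the true response varies slowly across the detector, so
    smoothing suppresses photon noise in the reference measurement.
    """
    measured = np.asarray(measured_reference, dtype=float)
    certified = np.asarray(certified_shape, dtype=float)
    if measured.shape != certified.shape:
        raise ValueError("measured and certified shapes must have equal length")
    if not np.all(certified > 0):
        raise ValueError("certified shape must be strictly positive everywhere")
    factors = measured / certified
    if smooth_window and smooth_window >= 5:
        window = min(smooth_window | 1, factors.size | 1)
        factors = savgol_filter(factors, window, polyorder=2)
    if not np.all(factors > 0):
        raise ValueError("nonpositive response factors after smoothing")
    return ResponseCurve(factors=factors, source="estimated")


def flat_response(n_pixels: int) -> ResponseCurve:
    """Unit response (no correction)."""
    return ResponseCurve(factors=np.ones(n_pixels), source="flat")


def correct_response(spectrum: np.ndarray, response: ResponseCurve) -> np.ndarray:
    """Divide out the per-pixel instrument sensitivity."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != np.asarray(response.factors).shape:
        raise ValueError("spectrum and response curve must have equal length")
    return spectrum / response.factors


def resample_to_axis(
    spectrum: np.ndarray, pixel_wavenumbers: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Linear interpolation onto the common wavenumber grid."""
    return np.interp(axis, pixel_wavenumbers, spectrum)


class BubbleFillResult(NamedTuple):
    baseline: np.ndarray
    raman: np.ndarray


def bubblefill(
    spectrum: np.ndarray,
    axis: np.ndarray | None = None,
    min_bubble_width: float = 100.0,
) -> BubbleFillResult:
    """Bubble-envelope baseline removal.

    The fluorescence baseline is built as the upper envelope of circular
    arcs ("bubbles") grown from below until they touch the spectrum. The
    spectrum is first rescaled so its intensity range matches the index
    range (making the arcs genuinely circular), then a bubble spanning
    the full axis is grown; each touch point splits its interval in two
    and the procedure recurses, stopping when an interval is narrower
    than ``min_bubble_width``. Intervals touching the axis ends use
    half-bubbles of doubled radius so the baseline can hug the edges.

    Guarantees: ``baseline <= spectrum`` everywhere (to rounding),
    ``raman = spectrum - baseline`` so the decomposition is exact, the
    baseline carries no structure narrower than the bubble geometry
    allows, and the whole construction is deterministic. If
    ``min_bubble_width`` is at least the axis span, the result is the
    single largest bubble envelope (degenerate but valid).
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum must be finite")
    n = y.size
    if axis is None:
        step = 1.0
    else:
        axis = np.asarray(axis, dtype=float)
        if axis.size != n:
            raise ValueError("axis and spectrum must have equal length")
        step = float(np.median(np.diff(axis)))
    if min_bubble_width <= step:
        raise ValueError("min_bubble_width must exceed the axis spacing")
    min_pts = max(int(round(min_bubble_width / step)), 2)

    ymin = float(y.min())
    yrange = float(y.max()) - ymin
    if yrange == 0.0:
        return BubbleFillResult(baseline=y.copy(), raman=np.zeros(n))
    scale = yrange / (n - 1)
    Y = (y - ymin) / scale  # intensity now spans [0, n-1]: bubbles are circular

    baseline = np.full(n, -np.inf)
    stack: list[tuple[int, int]] = [(0, n - 1)]
    first = True
    while stack:
        lo, hi = stack.pop()
        width = hi - lo
        if width < 1:
            continue
        if not first and width < min_pts:
            continue
        first = False
        xs = np.arange(width + 1, dtype=float)
        if lo == 0 and hi == n - 1:
            radius, center = width / 2.0, width / 2.0
        elif lo == 0:  # left-edge half bubble, apex at the edge
            radius, center = float(width), 0.0
        elif hi == n - 1:  # right-edge half bubble
            radius, center = float(width), float(width)
        else:
            radius, center = width / 2.0, width / 2.0
        arc = np.sqrt(np.maximum(radius**2 - (xs - center) ** 2, 0.0)) - radius
        gap = Y[lo : hi + 1] - arc
        t = int(np.argmin(gap))
        arc += gap[t]  # lift the bubble until it touches the spectrum
        np.maximum(baseline[lo : hi + 1], arc, out=baseline[lo : hi + 1])
        # split at the touch point; a touch at an interval endpoint shaves
        # that point off instead, so every child strictly shrinks
        if t == 0:
            stack.append((lo + 1, hi))
        elif t == width:
            stack.append((lo, hi - 1))
        else:
            stack.append((lo, lo + t))
            stack.append((lo + t, hi))

    baseline = baseline * scale + ymin
    return BubbleFillResult(baseline=baseline, raman=y - baseline)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sd with the population sd.

    The output has mean 0 and unit standard deviation, making spectra
    invariant to affine intensity transforms (laser power, collection
    efficiency). A constant spectrum cannot be normalized and raises.
    """
    x = np.asarray(spectrum, dtype=float)
    sd = float(np.std(x))  # population (1/N) convention
    if sd == 0.0:
        raise ValueError("constant spectrum cannot be SNV-normalized (sd = 0)")
    return (x - x.mean()) / sd


def preprocess_measurement(
    measurement: SimulatedMeasurement,
    calibration: CalibrationFit,
    response: ResponseCurve,
    params: PreprocessParams | None = None,
) -> ProcessedSpectrum:
    """Run the full chain on one measurement.

    Order: average repeats -> subtract dark -> correct response ->
    calibrate/resample onto the common axis -> bubble baseline removal ->
    SNV. Stage failures are re-raised with the stage name attached.
    """
    if params is None:
        params = PreprocessParams()
    provenance: list[str] = []

    def run(stage: str, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise PipelineStageError(stage, exc) from exc
        provenance.append(stage)
        return out

    mean_frame = run("average_repeats", average_repeats, measurement.repeat_frames)
    dark_sub = run(
        "subtract_dark",
        subtract_dark,
        mean_frame,
        measurement.dark_frame,
        measurement.integration_time_s,
        measurement.dark_integration_time_s,
    )
    corrected = run("correct_response", correct_response, dark_sub, response)
    pixel_nu = calibration(np.arange(corrected.size))
    resampled = run("resample", resample_to_axis, corrected, pixel_nu, params.axis)

    if params.snv_before_baseline:
        # Non-standard order kept for regression comparison only. Note
        # that bubblefill is exactly affine-equivariant, so re-applying
        # SNV afterwards would reproduce the standard chain; the swapped
        # order therefore ends at the (un-normalized) raman component.
        normalized = run("snv", snv, resampled)
        baseline, raman = run(
            "bubblefill", bubblefill, normalized, params.axis, params.min_bubble_width
        )
        final = raman
    else:
        baseline, raman = run(
            "bubblefill", bubblefill, resampled, params.axis, params.min_bubble_width
        )
        final = run("snv", snv, raman)

    return ProcessedSpectrum(
        axis=params.axis.copy(),
        snv_intensity=final,
        raman_before_snv=raman,
        baseline=baseline,
        patient_id=measurement.patient_id,
        label=measurement.label,
        category=measurement.category,
        provenance=provenance,
    )
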