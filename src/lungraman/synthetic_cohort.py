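"""Synthetic single-point Raman cohort generator.

Emulates the acquisition protocol of a handheld fingerprint-region
(800-1700 cm^-1) Raman probe measuring fresh lung tissue: for each
interrogation point a dark frame (laser off) is recorded, followed by a
series of short repeat frames. The forward model per pixel is

    counts = response x (raman + fluorescence) x t + dark_rate x t + noise

with Poisson shot noise plus Gaussian read noise. Tissue spectra are sums
of Lorentzian (or Gaussian) vibrational bands at the canonical lung-tissue
band positions (852, 1037, 1080, 1156, 1449, 1549, 1657 cm^-1) riding on a
smooth fluorescence background that dominates the Raman signal. The
cancer/necrosis class carries a higher amide I (1657 cm^-1) amplitude and
a more subtle tyrosine (852 cm^-1) elevation relative to normal/benign
tissue. A configurable fraction of measurements is "degraded" (low SNR),
emulating poor probe contact or insufficient photon counts.

The generator also produces pseudo-calibration frames (narrow peaks at
known reference wavenumbers, standing in for an acetaminophen standard)
and a broadband reference frame (instrument response times a certified
smooth shape, standing in for a NIST fluorescence standard) so the full
calibration/response-correction chain is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "BandSpec",
    "TissueProfile",
    "InstrumentModel",
    "CohortConfig",
    "SimulatedMeasurement",
    "CANCER_NECROSIS",
    "NORMAL_BENIGN",
    "CATEGORY_CLASS",
    "BAND_CENTERS",
    "default_profiles",
    "default_instrument",
    "default_reference_peaks",
    "certified_reference_shape",
    "synth_pure_spectrum",
    "synth_background",
    "simulate_measurement",
    "generate_cohort",
    "synth_reference_frames",
]

FINGERPRINT_LO = 800.0
FINGERPRINT_HI = 1700.0

NORMAL_BENIGN = "normal_benign"
CANCER_NECROSIS = "cancer_necrosis"

#: Fine-grained histology categories and their binary class.
CATEGORY_CLASS = {
    "normal_lung": NORMAL_BENIGN,
    "emphysema_bronchiolitis": NORMAL_BENIGN,
    "adenocarcinoma": CANCER_NECROSIS,
    "squamous_cell_carcinoma": CANCER_NECROSIS,
    "nsclc_not_otherwise_specified": CANCER_NECROSIS,
    "small_cell_carcinoma": CANCER_NECROSIS,
    "necrosis": CANCER_NECROSIS,
}

#: Within-class category sampling weights, mirroring a realistic cohort
#: composition (normal lung vs benign inflammatory conditions; carcinoma
#: subtypes and necrosis).
CATEGORY_WEIGHTS = {
    NORMAL_BENIGN: {"normal_lung": 24, "emphysema_bronchiolitis": 76},
    CANCER_NECROSIS: {
        "adenocarcinoma": 32,
        "squamous_cell_carcinoma": 17,
        "nsclc_not_otherwise_specified": 20,
        "small_cell_carcinoma": 10,
        "necrosis": 18,
    },
}

#: Canonical lung-tissue band centers (cm^-1): tyrosine ring breathing,
#: phenylalanine C-H bend, phosphate (blood), carotenoids, CH2/CH3
#: deformation, tryptophan, amide I.
BAND_CENTERS = (852.0, 1037.0, 1080.0, 1156.0, 1449.0, 1549.0, 1657.0)

# (fwhm cm^-1, relative amplitude) for each discrete marker band.
_BASE_BANDS = {
    852.0: (14.0, 0.60),
    1037.0: (12.0, 0.45),
    1080.0: (12.0, 0.40),
    1156.0: (14.0, 0.35),
    1449.0: (22.0, 1.00),
    1549.0: (16.0, 0.30),
    1657.0: (20.0, 0.80),
}

# Broad, class-shared band congestion underlying the discrete markers:
# tryptophan/C-C skeletal region, phenylalanine ring breathing, amide III,
# CH2 twist/wag envelope, and the aromatic 1580-1620 cm^-1 region. Real
# fingerprint tissue spectra are congested; without this matrix a single
# band boost would dominate the per-spectrum variance and SNV would smear
# it into every other band. Matrix bands carry half the biological CV of
# the discrete markers (cv_scale 0.5).
_MATRIX_BANDS = {
    880.0: (70.0, 0.70),
    1004.0: (18.0, 1.00),
    1260.0: (60.0, 1.20),
    1310.0: (55.0, 1.10),
    1340.0: (50.0, 0.80),
    1587.0: (45.0, 0.60),
    1618.0: (35.0, 0.50),
}
_MATRIX_CV_SCALE = 0.5

#: Multiplicative class effect for cancer/necrosis tissue: amide I up 50%,
#: tyrosine up 45% (a subtler absolute change). All other bands are shared between
#: classes.
CANCER_BAND_BOOST = {1657.0: 1.50, 852.0: 1.45}


@dataclass(frozen=True)
class BandSpec:
    """A single vibrational band.

    center, fwhm in cm^-1; amplitude in arbitrary intensity units;
    lineshape Lorentzian (physical default for Raman) or Gaussian.
    """

    center: float
    fwhm: float
    amplitude: float
    lineshape: Literal["lorentzian", "gaussian"] = "lorentzian"
    #: Per-band scaling of the biological coefficient of variation: broad
    #: matrix congestion (a bulk compositional average) fluctuates less
    #: between patients and measurements than discrete marker bands.
    cv_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} cm^-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} cm^-1: amplitude must be >= 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        if self.cv_scale < 0:
            raise ValueError(f"band at {self.center} cm^-1: cv_scale must be >= 0")


@dataclass(frozen=True)
class TissueProfile:
    """Noiseless spectral profile of one histology category."""

    label: str
    category: str
    bands: tuple[BandSpec, ...]
    band_cv: float = 0.05  # per-measurement band-amplitude coefficient of variation

    def __post_init__(self) -> None:
        if self.label not in (NORMAL_BENIGN, CANCER_NECROSIS):
            raise ValueError(f"unknown class label {self.label!r}")
        if self.band_cv < 0:
            raise ValueError("band_cv must be >= 0")


@dataclass(frozen=True)
class InstrumentModel:
    """Forward model of the probe + spectrometer.

    ``true_pixel_to_wavenumber`` holds polynomial coefficients in
    ascending powers (numpy polynomial convention) mapping pixel index to
    Raman shift; it must be strictly increasing over the pixel range.
    ``response_curve`` is the per-pixel multiplicative sensitivity.
    ``raman_rate`` sets the photon budget: counts/s at the detector for a
    band of unit amplitude (before the response curve). ``background_scale``
    is the fluorescence-to-Raman amplitude ratio.
    """

    n_pixels: int
    true_pixel_to_wavenumber: tuple[float, ...]
    response_curve: np.ndarray
    dark_rate: float = 300.0
    read_noise_sd: float = 4.0
    background_scale: float = 5.0
    raman_rate: float = 16000.0

    def __post_init__(self) -> None:
        resp = np.asarray(self.response_curve, dtype=float)
        if resp.shape != (self.n_pixels,):
            raise ValueError("response_curve length must equal n_pixels")
        if not np.all(resp > 0):
            raise ValueError("response_curve must be strictly positive")
        nu = self.pixel_wavenumbers()
        if not np.all(np.diff(nu) > 0):
            raise ValueError("pixel-to-wavenumber map must be strictly increasing")

    def pixel_wavenumbers(self) -> np.ndarray:
        """True Raman-shift axis (cm^-1) for each pixel."""
        pixels = np.arange(self.n_pixels, dtype=float)
        return np.polynomial.polynomial.polyval(pixels, self.true_pixel_to_wavenumber)


@dataclass(frozen=True)
class CohortConfig:
    """Acquisition-protocol parameters for a synthetic cohort."""

    n_patients: int = 10
    max_measurements_per_class_per_patient: int = 10
    n_repeats: int = 10
    integration_time_s: float = 0.075
    dark_integration_time_s: float = 0.050
    low_quality_fraction: float = 0.33
    low_quality_noise_multiplier: float = 35.0
    patient_band_cv: float = 0.15
    noise_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "max_measurements_per_class_per_patient", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise ValueError("low_quality_fraction must be in [0, 1]")
        if self.low_quality_noise_multiplier <= 1.0:
            raise ValueError("low_quality_noise_multiplier must be > 1")
        if self.integration_time_s <= 0 or self.dark_integration_time_s <= 0:
            raise ValueError("integration times must be > 0")
        if self.patient_band_cv < 0:
            raise ValueError("patient_band_cv must be >= 0")


@dataclass
class SimulatedMeasurement:
    """One interrogation point: repeat frames, a dark frame, and truth."""

    repeat_frames: np.ndarray  # (n_repeats, n_pixels) counts
    dark_frame: np.ndarray  # (n_pixels,) counts
    patient_id: str
    label: str
    category: str
    quality: str  # "normal" | "degraded"
    integration_time_s: float
    dark_integration_time_s: float
    truth: dict = field(default_factory=dict)


def default_profiles(
    amide_boost: float | None = None,
    tyrosine_boost: float | None = None,
    band_cv: float = 0.05,
    lineshape: Literal["lorentzian", "gaussian"] = "lorentzian",
) -> dict[str, TissueProfile]:
    """Build the per-category tissue profiles.

    Returns a mapping category -> TissueProfile for all histology
    categories. Cancer/necrosis categories share the elevated amide I and
    tyrosine amplitudes; everything else is common to both classes.
    """
    boosts = dict(CANCER_BAND_BOOST)
    if amide_boost is not None:
        boosts[1657.0] = amide_boost
    if tyrosine_boost is not None:
        boosts[852.0] = tyrosine_boost
    profiles: dict[str, TissueProfile] = {}
    for category, label in CATEGORY_CLASS.items():
        bands = []
        for center, (fwhm, amp) in _BASE_BANDS.items():
            if label == CANCER_NECROSIS:
                amp = amp * boosts.get(center, 1.0)
            bands.append(BandSpec(center, fwhm, amp, lineshape))
        for center, (fwhm, amp) in _MATRIX_BANDS.items():
            bands.append(BandSpec(center, fwhm, amp, lineshape, cv_scale=_MATRIX_CV_SCALE))
        profiles[category] = TissueProfile(label, category, tuple(bands), band_cv)
    return profiles


def default_instrument(
    n_pixels: int = 2048,
    dark_rate: float = 300.0,
    read_noise_sd: float = 4.0,
    background_scale: float = 12.0,
    raman_rate: float = 16000.0,
) -> InstrumentModel:
    """Instrument with a gently quadratic pixel->wavenumber map over
    800-1700 cm^-1 and a smooth bell-shaped response curve."""
    a2 = 2.0e-5 * (1024.0 / n_pixels) ** 2
    last = n_pixels - 1
    a1 = (FINGERPRINT_HI - FINGERPRINT_LO - a2 * last**2) / last
    pixels = np.arange(n_pixels, dtype=float)
    response = 0.75 + 0.4 * np.exp(-(((pixels - 0.45 * n_pixels) / (0.35 * n_pixels)) ** 2))
    return InstrumentModel(
        n_pixels=n_pixels,
        true_pixel_to_wavenumber=(FINGERPRINT_LO, a1, a2),
        response_curve=response,
        dark_rate=dark_rate,
        read_noise_sd=read_noise_sd,
        background_scale=background_scale,
        raman_rate=raman_rate,
    )


def default_reference_peaks() -> list[float]:
    """Calibration peak table (cm^-1) for the pseudo-acetaminophen
    standard, shipped as package data."""
    text = resources.files("lungraman").joinpath("data/pseudo_acetaminophen_peaks.json").read_text()
    return list(json.loads(text)["wavenumbers_cm1"])


def certified_reference_shape(wavenumbers: np.ndarray) -> np.ndarray:
    """Synthetic certified broadband fluorescence shape.

    A smooth, strictly positive curve over the fingerprint region playing
    the role of a certified reference emission profile used for
    instrument-response characterization. Synthetic: defined by this
    package, not traceable to any real certificate.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    return 0.25 + np.exp(-(((nu - 1250.0) / 500.0) ** 2))


def _lineshape(axis: np.ndarray, band: BandSpec) -> np.ndarray:
    if band.lineshape == "lorentzian":
        g = band.fwhm / 2.0
        return g * g / ((axis - band.center) ** 2 + g * g)
    sigma = band.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((axis - band.center) ** 2) / (2.0 * sigma**2))


def synth_pure_spectrum(profile: TissueProfile, axis: np.ndarray) -> np.ndarray:
    """Sum of band lineshapes evaluated on ``axis`` (unit: band amplitude).

    Each band contributes ``amplitude`` at its center. Raises if a band
    center falls outside the axis range (the band would be truncated).
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be a 1-D strictly ascending wavenumber vector")
    out = np.zeros_like(axis)
    for band in profile.bands:
        if not axis[0] <= band.center <= axis[-1]:
            raise ValueError(
                f"band center {band.center} cm^-1 outside axis range "
                f"[{axis[0]}, {axis[-1]}] cm^-1"
            )
        out += band.amplitude * _lineshape(axis, band)
    return out


def synth_background(
    axis: np.ndarray,
    amplitude: float,
    decay_scale: float | None = 1500.0,
    bumps: Sequence[tuple[float, float, float]] = ((1150.0, 400.0, 0.25), (1500.0, 450.0, 0.15)),
) -> np.ndarray:
    """Smooth fluorescence-like background envelope.

    A monotone-decaying exponential (scale ``decay_scale`` cm^-1; ``None``
    for a flat envelope) plus broad Gaussian bumps (center, fwhm, relative
    amplitude). All structure is far wider than any Raman band, so a
    baseline-removal step can separate the two.
    """
    if amplitude < 0:
        raise ValueError("background amplitude must be >= 0")
    axis = np.asarray(axis, dtype=float)
    if decay_scale is None:
        env = np.ones_like(axis)
    else:
        env = np.exp(-(axis - axis[0]) / float(decay_scale))
    for center, fwhm, rel in bumps:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        env = env + rel * np.exp(-((axis - center) ** 2) / (2.0 * sigma**2))
    if decay_scale is None and not bumps:
        return amplitude * np.ones_like(axis)
    return amplitude * env / env.max()


def _sample_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    noise_multiplier: float,
    read_noise_sd: float,
) -> np.ndarray:
    """Sample detector counts around ``mean``.

    Shot noise is exact Poisson where the mean is <= 20 counts and a
    Gaussian with variance = mean above that (CCD regime); read noise is
    additive Gaussian. ``noise_multiplier`` scales the deviation from the
    mean (1 = nominal). Counts are clipped at zero.
    """
    mean = np.asarray(mean, dtype=float)
    draw = np.empty_like(mean)
    small = mean <= 20.0
    draw[small] = rng.poisson(mean[small])
    big = ~small
    draw[big] = rng.normal(mean[big], np.sqrt(mean[big]))
    read = rng.normal(0.0, read_noise_sd, size=mean.shape)
    counts = mean + noise_multiplier * (draw - mean) + noise_multiplier * read
    return np.maximum(counts, 0.0)


def simulate_measurement(
    profile: TissueProfile,
    instrument: InstrumentModel,
    config: CohortConfig,
    quality: str = "normal",
    rng: np.random.Generator | None = None,
) -> SimulatedMeasurement:
    """Simulate one interrogation point under the acquisition protocol.

    Generates ``config.n_repeats`` laser-on frames at the measurement
    integration time plus one laser-off dark frame at the (shorter) dark
    integration time. ``quality="degraded"`` multiplies the noise of the
    laser-on frames by ``config.low_quality_noise_multiplier``; the dark
    frame noise is detector-level and unaffected.
    """
    if quality not in ("normal", "degraded"):
        raise ValueError("quality must be 'normal' or 'degraded'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nu = instrument.pixel_wavenumbers()
    pure_rate = instrument.raman_rate * synth_pure_spectrum(profile, nu)
    max_amp = max((b.amplitude for b in profile.bands), default=0.0)
    bg_rate = synth_background(nu, instrument.background_scale * instrument.raman_rate * max_amp)
    t = config.integration_time_s
    td = config.dark_integration_time_s
    frame_mean = instrument.response_curve * (pure_rate + bg_rate) * t + instrument.dark_rate * t
    dark_mean = np.full(instrument.n_pixels, instrument.dark_rate * td)

    mult = config.low_quality_noise_multiplier if quality == "degraded" else 1.0
    if config.noise_enabled:
        frames = np.stack(
            [
                _sample_counts(rng, frame_mean, mult, instrument.read_noise_sd)
                for _ in range(config.n_repeats)
            ]
        )
        dark = _sample_counts(rng, dark_mean, 1.0, instrument.read_noise_sd)
    else:
        frames = np.tile(frame_mean, (config.n_repeats, 1))
        dark = dark_mean.copy()

    return SimulatedMeasurement(
        repeat_frames=frames,
        dark_frame=dark,
        patient_id="",
        label=profile.label,
        category=profile.category,
        quality=quality,
        integration_time_s=t,
        dark_integration_time_s=td,
        truth={
            "pure_raman": pure_rate * t,
            "background": bg_rate * t,
            "applied_response": instrument.response_curve.copy(),
            "noise_level": mult,
        },
    )


def _patient_adjusted(
    profile: TissueProfile, patient_factors: dict[float, float], rng: np.random.Generator
) -> TissueProfile:
    """Apply per-patient and per-measurement band-amplitude variability."""
    bands = []
    for band in profile.bands:
        factor = patient_factors.get(band.center, 1.0)
        cv = profile.band_cv * band.cv_scale
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            factor *= rng.lognormal(-0.5 * sigma**2, sigma)
        bands.append(replace(band, amplitude=band.amplitude * factor))
    return replace(profile, bands=tuple(bands))


def generate_cohort(
    config: CohortConfig,
    class_profiles: dict[str, TissueProfile] | None = None,
    instrument: InstrumentModel | None = None,
) -> list[SimulatedMeasurement]:
    """Generate a full patient cohort.

    For each patient, up to ``max_measurements_per_class_per_patient``
    measurements are simulated per class; histology categories are sampled
    within each class with realistic composition weights. Between-patient
    variability is a per-patient multiplicative log-normal factor per band
    (CV ``config.patient_band_cv``), shared by both classes of the same
    patient — both tissue types are sampled from the same subject. A
    fraction ``low_quality_fraction`` of measurements (i.i.d. Bernoulli)
    is degraded to low SNR.
    """
    if class_profiles is None:
        class_profiles = default_profiles()
    if instrument is None:
        instrument = default_instrument()
    rng = substream(config.seed, "cohort")

    by_class: dict[str, list[str]] = {NORMAL_BENIGN: [], CANCER_NECROSIS: []}
    for category, prof in class_profiles.items():
        by_class[prof.label].append(category)
    for label, cats in by_class.items():
        if not cats:
            raise ValueError(f"class_profiles contains no category for class {label!r}")

    center_cv_scale: dict[float, float] = {}
    for prof in class_profiles.values():
        for band in prof.bands:
            center_cv_scale[band.center] = band.cv_scale
    all_centers = sorted(center_cv_scale)

    def _patient_sigma(center: float) -> float:
        cv = config.patient_band_cv * center_cv_scale[center]
        return np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    cohort: list[SimulatedMeasurement] = []
    for p in range(config.n_patients):
        patient_id = f"P{p + 1:03d}"
        patient_factors = {}
        for c in all_centers:
            sig = _patient_sigma(c)
            patient_factors[c] = rng.lognormal(-0.5 * sig**2, sig) if sig > 0 else 1.0
        for label in (NORMAL_BENIGN, CANCER_NECROSIS):
            cats = sorted(by_class[label])
            weights = np.array([CATEGORY_WEIGHTS[label].get(c, 1) for c in cats], dtype=float)
            weights /= weights.sum()
            for _ in range(config.max_measurements_per_class_per_patient):
                category = cats[rng.choice(len(cats), p=weights)]
                quality = "degraded" if rng.random() < config.low_quality_fraction else "normal"
                prof = _patient_adjusted(class_profiles[category], patient_factors, rng)
                meas = simulate_measurement(prof, instrument, config, quality, rng)
                meas.patient_id = patient_id
                cohort.append(meas)
    return cohort


def synth_reference_frames(
    instrument: InstrumentModel,
    reference_peak_table: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    peak_fwhm: float = 6.0,
    peak_amplitude: float = 1000.0,
    noise_sd: float = 0.0,
) -> dict[str, np.ndarray]:
    """Pseudo-calibration and broadband-reference frames.

    ``calibration_frame``: narrow Gaussian peaks at the reference
    wavenumbers, placed through the instrument's true pixel->wavenumber
    map (so a calibration fit can recover that map). ``broadband_reference_frame``:
    the instrument response times the certified reference shape. Optional
    additive Gaussian noise of ``noise_sd`` counts on both.
    """
    if reference_peak_table is None:
        reference_peak_table = default_reference_peaks()
    peaks = list(reference_peak_table)
    if not peaks:
        raise ValueError("reference_peak_table must be nonempty")
    if sorted(peaks) != peaks:
        raise ValueError("reference_peak_table must be sorted ascending")
    nu = instrument.pixel_wavenumbers()
    calib = np.zeros(instrument.n_pixels)
    sigma = peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for center in peaks:
        calib += peak_amplitude * np.exp(-((nu - center) ** 2) / (2.0 * sigma**2))
    broadband = instrument.response_curve * certified_reference_shape(nu)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        calib = calib + rng.normal(0.0, noise_sd, calib.shape)
        broadband = broadband + rng.normal(0.0, noise_sd, broadband.shape)
    return {"calibration_frame": calib, "broadband_reference_frame": broadband}
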