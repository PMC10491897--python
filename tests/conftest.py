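"""Shared fixtures: a default instrument with its calibration/response
chain, and a fully preprocessed default cohort (expensive, session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from lungraman import classify, preprocess as pp, quality, synthetic_cohort as sc


@pytest.fixture(scope="session")
def instrument() -> sc.InstrumentModel:
    return sc.default_instrument()


@pytest.fixture(scope="session")
def calibration_and_response(instrument):
    """Calibration fit and response curve recovered from the synthetic
    reference frames, as the pipeline itself would."""
    refs = sc.synth_reference_frames(instrument)
    peak_px = pp.detect_calibration_peaks(refs["calibration_frame"])
    calibration = pp.fit_calibration(
        peak_px,
        sc.default_reference_peaks(),
        order=2,
        pixel_range=(0.0, float(instrument.n_pixels - 1)),
    )
    certified = sc.certified_reference_shape(calibration(np.arange(instrument.n_pixels)))
    response = pp.estimate_response(refs["broadband_reference_frame"], certified)
    return calibration, response


@pytest.fixture(scope="session")
def default_cohort(instrument):
    """One default cohort: 10 patients, 10 measurements per class each."""
    return sc.generate_cohort(sc.CohortConfig(seed=1), instrument=instrument)


@pytest.fixture(scope="session")
def processed_dataset(default_cohort, calibration_and_response):
    """Preprocessed default cohort with QF values attached."""
    calibration, response = calibration_and_response
    out = []
    for meas in default_cohort:
        spec = pp.preprocess_measurement(meas, calibration, response)
        spec.qf = quality.quality_factor(spec.snv_intensity)
        out.append(spec)
    return out


@pytest.fixture(scope="session")
def retained_feature_matrix(processed_dataset):
    split = quality.split_by_qf(processed_dataset, 0.4)
    return classify.build_feature_matrix(split.retained)
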