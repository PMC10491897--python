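"""On-disk formats and the end-to-end pipeline runner.

Cohorts are stored as plain delimited text — one TSV per measurement
(pixel index, one column per repeat frame, one dark column) plus a
JSON-lines metadata sidecar — so fixtures stay diffable. Processed
spectra are a single TSV (wavenumber, snv_intensity, baseline,
raman_before_snv per spectrum) with their own sidecar. All run artifacts
embed the master seed and a hash of the resolved configuration, and a
rerun with the same configuration reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import classify, evaluate, preprocess, quality, synthetic_cohort as sc

__all__ = [
    "RunConfig",
    "StageFailure",
    "SpectraParseError",
    "write_cohort",
    "read_spectra_table",
    "write_processed",
    "run_pipeline",
]


class SpectraParseError(ValueError):
    """A spectra table could not be parsed; message names the location."""


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_patients: int = Field(default=10, ge=1)
    max_measurements_per_class_per_patient: int = Field(default=10, ge=1)
    n_repeats: int = Field(default=10, ge=1)
    integration_time_s: float = Field(default=0.075, gt=0)
    dark_integration_time_s: float = Field(default=0.050, gt=0)
    low_quality_fraction: float = Field(default=0.33, ge=0, le=1)
    low_quality_noise_multiplier: float = Field(default=35.0, gt=1)
    patient_band_cv: float = Field(default=0.15, ge=0)
    noise_enabled: bool = True


class InstrumentSection(_Strict):
    n_pixels: int = Field(default=2048, ge=16)
    dark_rate: float = Field(default=300.0, ge=0)
    read_noise_sd: float = Field(default=4.0, ge=0)
    background_scale: float = Field(default=12.0, ge=0)
    raman_rate: float = Field(default=16000.0, gt=0)


class PreprocessSection(_Strict):
    min_bubble_width: float = Field(default=100.0, gt=0)
    response_smooth_window: int = Field(default=31, ge=0)
    calibration_order: int = Field(default=2, ge=1)
    qf_smooth_window: float = Field(default=13.0, gt=0)
    qf_polyorder: int = Field(default=3, ge=1)


class GridSection(_Strict):
    c_grid: list[float] = Field(default_factory=lambda: list(classify.DEFAULT_C_GRID))
    k_min: int = Field(default=5, ge=5)
    k_max: int = Field(default=20, le=20)


class EvaluationSection(_Strict):
    n_permutations: int = Field(default=100, ge=2)
    operating_rule: str = "youden"
    permute_patient_level: bool = False


class RunConfig(_Strict):
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    qf_threshold: float = Field(default=0.4, ge=0, le=1)
    exclude_interval: tuple[float, float] | None = classify.DEFAULT_EXCLUDE_INTERVAL
    outdir: str = "results"
    cohort: CohortSection = Field(default_factory=CohortSection)
    instrument: InstrumentSection = Field(default_factory=InstrumentSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    grids: GridSection = Field(default_factory=GridSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.model_dump(mode="json")
        payload.pop("outdir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def cohort_config(self) -> sc.CohortConfig:
        return sc.CohortConfig(seed=self.seed, **self.cohort.model_dump())


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_cohort(cohort: Sequence[sc.SimulatedMeasurement], directory: str | Path) -> Path:
    """Write a cohort as per-measurement TSVs plus metadata.jsonl."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, meas in enumerate(cohort):
        fname = f"measurement_{i:04d}.tsv"
        n_repeats, n_pixels = meas.repeat_frames.shape
        header = ["pixel"] + [f"repeat_{r}" for r in range(n_repeats)] + ["dark"]
        rows = [header]
        for px in range(n_pixels):
            rows.append(
                [str(px)]
                + [repr(float(v)) for v in meas.repeat_frames[:, px]]
                + [repr(float(meas.dark_frame[px]))]
            )
        (directory / fname).write_text("\n".join("\t".join(r) for r in rows) + "\n")
        lines.append(
            json.dumps(
                {
                    "file": fname,
                    "patient_id": meas.patient_id,
                    "label": meas.label,
                    "category": meas.category,
                    "quality": meas.quality,
                    "integration_time_s": meas.integration_time_s,
                    "dark_integration_time_s": meas.dark_integration_time_s,
                    "noise_level": meas.truth.get("noise_level"),
                },
                sort_keys=True,
            )
        )
    (directory / "metadata.jsonl").write_text("\n".join(lines) + "\n")
    return directory


def read_spectra_table(directory: str | Path) -> list[sc.SimulatedMeasurement]:
    """Read a cohort directory written by :func:`write_cohort`.

    Raises :class:`SpectraParseError` with the file and line number on
    ragged rows or non-numeric cells, and on a missing or empty sidecar.
    """
    directory = Path(directory)
    sidecar = directory / "metadata.jsonl"
    if not sidecar.exists():
        raise SpectraParseError(f"missing metadata sidecar {sidecar}")
    records = [json.loads(line) for line in sidecar.read_text().splitlines() if line.strip()]
    if not records:
        raise SpectraParseError("no measurements: metadata sidecar is empty")
    cohort = []
    for rec in records:
        path = directory / rec["file"]
        lines = path.read_text().splitlines()
        if not lines or len(lines) < 2:
            raise SpectraParseError(f"{path.name}: no measurements (empty table)")
        header = lines[0].split("\t")
        ncol = len(header)
        repeat_cols = [i for i, h in enumerate(header) if h.startswith("repeat_")]
        dark_col = header.index("dark")
        frames = []
        for lineno, line in enumerate(lines[1:], start=2):
            cells = line.split("\t")
            if len(cells) != ncol:
                raise SpectraParseError(
                    f"{path.name}: ragged row at line {lineno} "
                    f"({len(cells)} cells, expected {ncol})"
                )
            try:
                frames.append([float(c) for c in cells])
            except ValueError as exc:
                raise SpectraParseError(f"{path.name}: non-numeric cell at line {lineno}") from exc
        table = np.asarray(frames)
        cohort.append(
            sc.SimulatedMeasurement(
                repeat_frames=table[:, repeat_cols].T.copy(),
                dark_frame=table[:, dark_col].copy(),
                patient_id=rec["patient_id"],
                label=rec["label"],
                category=rec["category"],
                quality=rec["quality"],
                integration_time_s=rec["integration_time_s"],
                dark_integration_time_s=rec["dark_integration_time_s"],
                truth={"noise_level": rec.get("noise_level")},
            )
        )
    return cohort


def write_processed(spectra: Sequence[preprocess.ProcessedSpectrum], directory: str | Path) -> Path:
    """Write processed spectra as one wide TSV plus metadata.jsonl."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, spec in enumerate(spectra):
        fname = f"spectrum_{i:04d}.tsv"
        rows = ["wavenumber\tsnv_intensity\tbaseline\traman_before_snv"]
        for j in range(spec.axis.size):
            rows.append(
                f"{spec.axis[j]!r}\t{spec.snv_intensity[j]!r}"
                f"\t{spec.baseline[j]!r}\t{spec.raman_before_snv[j]!r}"
            )
        (directory / fname).write_text("\n".join(rows) + "\n")
        lines.append(
            json.dumps(
                {
                    "file": fname,
                    "patient_id": spec.patient_id,
                    "label": spec.label,
                    "category": spec.category,
                    "qf": spec.qf,
                },
                sort_keys=True,
            )
        )
    (directory / "metadata.jsonl").write_text("\n".join(lines) + "\n")
    return directory


@dataclass
class PipelineResult:
    """In-memory summary of a full run (artifacts are also on disk)."""

    qc_summary: quality.QualitySummary
    best: classify.Hyperparams
    roc: evaluate.RocResult
    permutation: evaluate.PermutationSummary
    band_stats: list[evaluate.BandStat]
    tally: evaluate.CohortTally
    outdir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow: simulate -> preprocess -> QF filter ->
    grid search -> evaluation, writing every artifact under
    ``config.outdir``. Deterministic given the configuration."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}

    # --- simulate ---------------------------------------------------------
    instrument = sc.default_instrument(**config.instrument.model_dump())
    cohort_cfg = config.cohort_config()
    try:
        cohort = sc.generate_cohort(cohort_cfg, instrument=instrument)
        write_cohort(cohort, outdir / "cohort")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("simulate", str(exc)) from exc

    # --- calibration + response ------------------------------------------
    try:
        refs = sc.synth_reference_frames(instrument)
        peak_px = preprocess.detect_calibration_peaks(refs["calibration_frame"])
        calibration = preprocess.fit_calibration(
            peak_px,
            sc.default_reference_peaks(),
            order=config.preprocess.calibration_order,
            pixel_range=(0.0, float(instrument.n_pixels - 1)),
        )
        certified = sc.certified_reference_shape(calibration(np.arange(instrument.n_pixels)))
        response = preprocess.estimate_response(
            refs["broadband_reference_frame"],
            certified,
            smooth_window=config.preprocess.response_smooth_window,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("calibration", str(exc)) from exc

    # --- preprocess + QF --------------------------------------------------
    params = preprocess.PreprocessParams(min_bubble_width=config.preprocess.min_bubble_width)
    try:
        processed = []
        for meas in cohort:
            spec = preprocess.preprocess_measurement(meas, calibration, response, params)
            spec.qf = quality.quality_factor(
                spec.snv_intensity,
                smooth_window=config.preprocess.qf_smooth_window,
                polyorder=config.preprocess.qf_polyorder,
            )
            processed.append(spec)
        write_processed(processed, outdir / "processed")
        split = quality.split_by_qf(processed, config.qf_threshold)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("preprocess", str(exc)) from exc
    _dump_json(outdir / "qc_report.json", {**meta, "summary": _jsonable(asdict(split.summary))})

    # --- train ------------------------------------------------------------
    if not split.retained:
        raise StageFailure("train", "empty retained set after QF filtering")
    try:
        fm = classify.build_feature_matrix(split.retained, config.exclude_interval)
        k_grid = range(config.grids.k_min, config.grids.k_max + 1)
        search = classify.grid_search(fm, config.grids.c_grid, k_grid)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("train", str(exc)) from exc
    preds = search.best_predictions
    _dump_json(
        outdir / "model.json",
        {
            **meta,
            "hyperparameters": {"C": search.best.C, "k": search.best.k},
            "selected_wavenumbers": {
                p: [float(w) for w in ws] for p, ws in preds.selected_wavenumbers.items()
            },
            "skipped_folds": preds.skipped_folds,
            "grid": search.table.to_dict(orient="records"),
        },
    )

    # --- evaluate ---------------------------------------------------------
    try:
        ok = preds.valid()
        roc = evaluate.roc_auc(
            preds.scores[ok], preds.y[ok], operating_rule=config.evaluation.operating_rule
        )
        permutation = evaluate.permutation_null(
            fm,
            search.best,
            n_repeats=config.evaluation.n_permutations,
            seed=config.seed,
            patient_level=config.evaluation.permute_patient_level,
        )
        band_stats = evaluate.band_statistics(split.retained)
        tally = evaluate.tally_cohort(
            split.summary.total_per_category, split.summary.retained_per_category
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("evaluate", str(exc)) from exc
    _dump_json(
        outdir / "evaluation.json",
        {
            **meta,
            "parameters": {
                "qf_threshold": config.qf_threshold,
                "exclude_interval": config.exclude_interval,
                "c_grid": config.grids.c_grid,
                "k_range": [config.grids.k_min, config.grids.k_max],
                "n_permutations": config.evaluation.n_permutations,
            },
            "auc": roc.auc,
            "operating_point": roc.operating_point,
            "permutation": {
                "n_repeats": permutation.n_repeats,
                "mean_auc": permutation.mean_auc,
                "sd_auc": permutation.sd_auc,
                "n_failed": permutation.n_failed,
            },
            "band_statistics": [_jsonable(asdict(b)) for b in band_stats],
            "cohort_tally": _jsonable(asdict(tally)),
        },
    )
    return PipelineResult(
        qc_summary=split.summary,
        best=search.best,
        roc=roc,
        permutation=permutation,
        band_stats=band_stats,
        tally=tally,
        outdir=outdir,
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
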