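"""End-to-end one-class mapping pipeline.

Wires the stages together: edge training-set selection -> window-based
validation sampling -> simulated-annealing search for (C, s) -> SVDD
classification of the full raster -> confusion-matrix assessment against
the reference map. Offered both as an in-memory function
(:func:`run_oneclass_mapping`) and as a file-based run driven by a
:class:`RunConfig`, which writes every intermediate artifact plus a
manifest recording seeds and the chosen parameters.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .anneal import SAConfig, SATrace, evaluate_error, optimize
from .assess import AccuracyReport, ConfusionMatrix, confusion, metrics
from .raster import LabelRaster, MultibandRaster, read_labels, read_raster, write_labels
from .sampling import (
    SampleSet,
    build_random_validation_set,
    build_training_set,
    build_validation_set,
)
from .svdd import SVDDModel, classify_raster, fit_svdd

__all__ = ["RunConfig", "PipelineResult", "run_oneclass_mapping", "run_pipeline"]

ALLOWED_WINDOWS = (3, 5, 7, 9, 11)


@dataclass
class RunConfig:
    """File-based pipeline configuration (mirrors the CLI `run` command)."""

    image: str
    labels: str
    out_dir: str
    target_code: int
    n_mixed: int = 60
    n_corner: int = 60
    window: int = 3
    exclude_codes: tuple[int, ...] = ()
    sa: SAConfig | None = None
    aggregation_factors: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window not in ALLOWED_WINDOWS:
            raise ValueError(
                f"window must be one of {ALLOWED_WINDOWS}, got {self.window}"
            )


@dataclass
class PipelineResult:
    training: SampleSet
    validation: SampleSet
    best_C: float
    best_s: float
    trace: SATrace
    model: SVDDModel
    predicted: LabelRaster
    cm: ConfusionMatrix
    report: AccuracyReport
    timings: dict = field(default_factory=dict)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Named per-stage substreams derived from the single run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_oneclass_mapping(
    raster: MultibandRaster,
    labels: LabelRaster,
    target_code: int,
    *,
    n_mixed: int = 60,
    n_corner: int = 60,
    window: int = 3,
    exclude_codes: tuple[int, ...] = (),
    sa_config: SAConfig | None = None,
    seed: int = 0,
    validation_mode: str = "window",
    assess_labels: LabelRaster | None = None,
) -> PipelineResult:
    """Run the full one-class mapping chain in memory.

    ``validation_mode`` is "window" (the method's window-based informative
    sampling) or "random" (size-matched conventional comparator).
    Assessment uses ``assess_labels`` when given, else the same reference
    ``labels``. All randomness derives from ``seed`` via per-stage
    substreams.
    """
    seeds = _stage_seeds(seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    training = build_training_set(
        raster, labels, target_code, n_mixed, n_corner, seed=seeds[0]
    )
    validation = build_validation_set(
        training, raster, labels, target_code, w=window, exclude_codes=exclude_codes
    )
    if validation_mode == "random":
        validation = build_random_validation_set(
            validation,
            raster,
            labels,
            target_code,
            exclude_coords=training.coord_set(),
            exclude_codes=exclude_codes,
            seed=seeds[1],
        )
    elif validation_mode != "window":
        raise ValueError(f"unknown validation_mode {validation_mode!r}")
    timings["sampling"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cfg = sa_config or SAConfig()
    cfg = SAConfig(**{**cfg.__dict__, "seed": seeds[2]})
    best_C, best_s, trace = optimize(training, validation, cfg)
    timings["sa_search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = fit_svdd(training, best_C, best_s)
    predicted = classify_raster(model, raster)
    timings["classify"] = time.perf_counter() - t0

    ref = assess_labels if assess_labels is not None else labels
    cm = confusion(predicted, ref, target_code)
    report = metrics(cm)
    return PipelineResult(
        training=training,
        validation=validation,
        best_C=best_C,
        best_s=best_s,
        trace=trace,
        model=model,
        predicted=predicted,
        cm=cm,
        report=report,
        timings=timings,
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read inputs, run, write all artifacts.

    Writes the training/validation CSVs, model JSON, classified map, SA
    trace and accuracy report under ``out_dir``, plus ``manifest.json``
    recording the package version, seeds, stage timings and the chosen
    (C, s). Any stage failure is re-raised naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        raster = read_raster(config.image)
        labels = read_labels(config.labels)
        stage = "pipeline"
        result = run_oneclass_mapping(
            raster,
            labels,
            config.target_code,
            n_mixed=config.n_mixed,
            n_corner=config.n_corner,
            window=config.window,
            exclude_codes=config.exclude_codes,
            sa_config=config.sa,
            seed=config.seed,
        )
        stage = "write outputs"
        result.training.to_csv(out / "training.csv")
        result.validation.to_csv(out / "validation.csv")
        result.model.to_json(out / "model.json")
        result.trace.to_csv(out / "trace.csv")
        write_labels(result.predicted, out / "classified.tif")
        report = {
            "counts": {
                "tp": result.cm.tp, "fn": result.cm.fn,
                "fp": result.cm.fp, "tn": result.cm.tn,
            },
            **result.report.as_dict(),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        manifest = {
            "svddmap_version": __version__,
            "seed": config.seed,
            "target_code": config.target_code,
            "window": config.window,
            "exclude_codes": list(config.exclude_codes),
            "n_training": len(result.training),
            "n_validation_target": result.validation.n_target,
            "n_validation_outlier": result.validation.n_outlier,
            "sa_evaluations": result.trace.evaluations,
            "best_C": result.best_C,
            "best_s": result.best_s,
            "best_error": result.trace.best[2],
            "timings_s": result.timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return manifest
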