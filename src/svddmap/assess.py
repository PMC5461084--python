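"""Accuracy assessment and spatial aggregation.

Binary (target vs outlier) confusion-matrix metrics — producer's accuracy,
user's accuracy, overall accuracy and Cohen's kappa — plus the upscaling
tools used for multi-resolution experiments: block-mean spectral
aggregation, target-fraction maps from fine labels, and the strict
majority rule (fraction > 0.5) that turns fractions into a coarse
reference map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .raster import LabelRaster, MultibandRaster

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "FractionMap",
    "confusion",
    "metrics",
    "aggregate_raster",
    "fraction_map",
    "majority_labels",
]


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows = reference (target, outlier), columns = prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class AccuracyReport:
    """Derived accuracy metrics; undefined entries are NaN and listed in
    ``undefined`` rather than silently zeroed."""

    PA: float
    UA: float
    OA: float
    kappa: float
    undefined: tuple[str, ...] = ()

    @property
    def omission(self) -> float:
        return 1.0 - self.PA

    @property
    def commission(self) -> float:
        return 1.0 - self.UA

    def as_dict(self) -> dict:
        return {
            "PA": self.PA, "UA": self.UA, "OA": self.OA, "kappa": self.kappa,
            "omission": self.omission, "commission": self.commission,
            "undefined": list(self.undefined),
        }


@dataclass
class FractionMap:
    """Per-coarse-pixel target fraction in [0, 1] at aggregation ``factor``."""

    values: np.ndarray
    factor: int


def confusion(
    pred: LabelRaster,
    ref: LabelRaster,
    target_code: int,
    mask: np.ndarray | None = None,
    *,
    pred_target_code: int = 1,
) -> ConfusionMatrix:
    """Binary confusion matrix of a predicted map against a reference map.

    ``target_code`` selects the target class in the reference;
    ``pred_target_code`` in the prediction (default 1, the code written by
    ``classify_raster``). Unknown pixels in either map are excluded, as is
    anything outside ``mask``.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: pred {pred.shape} vs ref {ref.shape}")
    keep = (pred.labels != pred.unknown_code) & (ref.labels != ref.unknown_code)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    rt = ref.labels[keep] == target_code
    pt = pred.labels[keep] == pred_target_code
    return ConfusionMatrix(
        tp=int(np.sum(rt & pt)),
        fn=int(np.sum(rt & ~pt)),
        fp=int(np.sum(~rt & pt)),
        tn=int(np.sum(~rt & ~pt)),
    )


def metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """PA, UA, OA and kappa from a binary confusion matrix.

    PA = tp/(tp+fn) (1 - omission), UA = tp/(tp+fp) (1 - commission),
    OA = (tp+tn)/N, kappa = (OA - p_e)/(1 - p_e) with the chance agreement
    p_e = [(tp+fn)(tp+fp) + (fp+tn)(fn+tn)] / N^2.
    """
    N = cm.total
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    PA = ratio(cm.tp, cm.tp + cm.fn, "PA")
    UA = ratio(cm.tp, cm.tp + cm.fp, "UA")
    OA = (cm.tp + cm.tn) / N
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / N**2
    if p_e == 1.0:
        undefined.append("kappa")
        kappa = math.nan
    else:
        kappa = (OA - p_e) / (1.0 - p_e)
    return AccuracyReport(PA=PA, UA=UA, OA=OA, kappa=kappa, undefined=tuple(undefined))


def aggregate_raster(raster: MultibandRaster, factor: int) -> MultibandRaster:
    """Spectral upscaling: each coarse pixel is the per-band mean of a
    factor x factor block. Trailing rows/columns that do not fill a block
    are dropped; the resolution metadata is multiplied by ``factor``."""
    if factor < 2:
        raise ValueError("aggregation factor must be >= 2")
    p, h, w = raster.values.shape
    H, W = h // factor, w // factor
    if H == 0 or W == 0:
        raise ValueError(f"factor {factor} larger than grid {h}x{w}")
    v = raster.values[:, : H * factor, : W * factor]
    coarse = v.reshape(p, H, factor, W, factor).mean(axis=(2, 4))
    res = raster.resolution * factor if raster.resolution is not None else None
    return MultibandRaster(coarse, resolution=res, nodata=raster.nodata)


def fraction_map(fine_labels: LabelRaster, target_code: int, factor: int) -> FractionMap:
    """Target-class fraction of each factor x factor block of fine labels."""
    if factor < 2:
        raise ValueError("aggregation factor must be >= 2")
    h, w = fine_labels.shape
    H, W = h // factor, w // factor
    if H == 0 or W == 0:
        raise ValueError(f"factor {factor} larger than grid {h}x{w}")
    is_t = (fine_labels.labels[: H * factor, : W * factor] == target_code).astype(float)
    frac = is_t.reshape(H, factor, W, factor).mean(axis=(1, 3))
    return FractionMap(values=frac, factor=factor)


def majority_labels(fractions: FractionMap) -> LabelRaster:
    """Majority rule: target iff fraction strictly exceeds 0.5.

    A coarse pixel at exactly 0.5 is labeled outlier (strict inequality).
    """
    values = np.asarray(fractions.values)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")
    labels = (values > 0.5).astype(np.int64)
    return LabelRaster(labels, {1: "target", 0: "outlier"})
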