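"""Training- and validation-set construction for one-class mapping.

The training set is an *edge* set: mixed pixels along target parcel
boundaries plus "corner" pixels at the convex-hull vertices of the target
cloud in the MNF1-MNF2 plane. The validation set is window-based: every
pixel inside a w x w window around each training pixel, labeled
target/outlier from the reference map. Because mixed boundary pixels sit
between classes in feature space, their neighbours supply *informative*
outliers — spectra adjacent to the target class — which is what lets the
downstream parameter search tighten the SVDD hypersphere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError

from .raster import LabelRaster, MultibandRaster

__all__ = [
    "SampleSet",
    "MNFResult",
    "extract_boundary_pixels",
    "mnf_transform",
    "select_corner_pixels",
    "build_training_set",
    "build_validation_set",
    "build_random_validation_set",
]

TARGET = "target"
OUTLIER = "outlier"


@dataclass
class SampleSet:
    """Labeled pixel samples: coordinates, spectra and target/outlier tags.

    ``provenance`` is "training" or "validation"; ``window`` records the
    w used for window-based validation sets.
    """

    coords: np.ndarray  # (n, 2) int, (row, col)
    spectra: np.ndarray  # (n, p) float
    tags: np.ndarray  # (n,) str, TARGET or OUTLIER
    provenance: str = "training"
    window: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.tags = np.asarray(self.tags, dtype=object)
        n = len(self.coords)
        if self.spectra.shape[0] != n or self.tags.shape[0] != n:
            raise ValueError("coords, spectra and tags must have equal length")
        seen = {tuple(c) for c in self.coords}
        if len(seen) != n:
            raise ValueError("duplicate coordinates in sample set")
        if self.provenance == "training" and not np.all(self.tags == TARGET):
            raise ValueError("training sets may contain only target samples")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def is_target(self) -> np.ndarray:
        return self.tags == TARGET

    @property
    def n_target(self) -> int:
        return int(np.sum(self.is_target))

    @property
    def n_outlier(self) -> int:
        return int(len(self) - self.n_target)

    def coord_set(self) -> set[tuple[int, int]]:
        return {tuple(c) for c in self.coords}

    # -- CSV + JSON-sidecar serialization ----------------------------------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        p = self.spectra.shape[1]
        df = pd.DataFrame(
            {
                "row": self.coords[:, 0],
                "col": self.coords[:, 1],
                **{f"band_{b}": self.spectra[:, b] for b in range(p)},
                "tag": self.tags,
            }
        )
        df.to_csv(path, index=False)
        sidecar = {"provenance": self.provenance, "window": self.window, **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSet":
        path = Path(path)
        df = pd.read_csv(path)
        bands = [c for c in df.columns if c.startswith("band_")]
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            coords=df[["row", "col"]].to_numpy(),
            spectra=df[bands].to_numpy(),
            tags=df["tag"].to_numpy(dtype=object),
            provenance=meta.pop("provenance", "training"),
            window=meta.pop("window", None),
            meta=meta,
        )


@dataclass
class MNFResult:
    """Minimum-noise-fraction transform of a raster.

    ``components`` holds the transformed image (component, row, col) ordered
    by decreasing signal-to-noise ratio; ``transform`` has one column per
    component and whitens the estimated noise covariance to the identity.
    """

    components: MultibandRaster
    eigenvalues: np.ndarray  # SNR-like generalized eigenvalues, non-increasing
    noise_cov: np.ndarray
    transform: np.ndarray  # (p, p), columns = component loadings
    mean: np.ndarray


def extract_boundary_pixels(labels: LabelRaster, target_code: int) -> np.ndarray:
    """Coordinates of target pixels with >= 1 non-target 8-neighbour.

    The image border counts as non-target, so target pixels touching the
    edge of the grid are always boundary pixels. Returns an (n, 2) array in
    row-major scan order.
    """
    is_t = labels.labels == target_code
    if not is_t.any():
        raise ValueError(f"target code {target_code} absent from labels")
    padded = np.pad(is_t, 1, mode="constant", constant_values=False)
    all_neigh_target = np.ones_like(is_t)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            h, w = is_t.shape
            all_neigh_target &= padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    boundary = is_t & ~all_neigh_target
    return np.argwhere(boundary)


def mnf_transform(raster: MultibandRaster, *, reg: float = 1e-12) -> MNFResult:
    """Minimum noise fraction transform with shift-difference noise model.

    Noise covariance is estimated from horizontal first differences
    (each pixel minus its right neighbour; covariance halved), then the
    generalized eigenproblem ``Sigma_total v = lambda Sigma_noise v`` is
    solved. Components are ordered by decreasing eigenvalue (a
    signal-to-noise ratio), and the transform whitens the noise covariance
    to the identity. A singular noise covariance is ridge-regularized with
    a warning; a constant image raises ``ValueError``.
    """
    p = raster.n_bands
    if p < 2:
        raise ValueError("MNF requires at least 2 bands")
    valid = raster.valid_mask()
    X = raster.values.reshape(p, -1).T[valid.ravel()]
    if X.shape[0] < p + 1:
        raise ValueError("need at least p+1 valid pixels")
    if np.allclose(X, X[0]):
        raise ValueError("constant image: MNF undefined")

    # horizontal shift-difference noise estimate over valid pixel pairs
    pair_ok = valid[:, :-1] & valid[:, 1:]
    diffs = (raster.values[:, :, 1:] - raster.values[:, :, :-1]).reshape(p, -1).T
    diffs = diffs[pair_ok.ravel()]
    if diffs.shape[0] < p + 1:
        raise ValueError("too few valid pixel pairs for noise estimation")
    noise_cov = np.cov(diffs, rowvar=False) / 2.0
    total_cov = np.cov(X, rowvar=False)

    scale = np.trace(noise_cov) / p
    if scale <= 0 or np.linalg.cond(noise_cov) > 1e12:
        warnings.warn("singular noise covariance: applying ridge regularization")
        scale = max(scale, np.trace(total_cov) / p * 1e-12, 1e-300)
        noise_cov = noise_cov + reg * scale * np.eye(p) + 1e-10 * scale * np.eye(p)

    evals, evecs = eigh(total_cov, noise_cov)  # ascending; V^T Sigma_N V = I
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    W = evecs[:, order]

    mean = X.mean(axis=0)
    flat = raster.values.reshape(p, -1)
    comps = (W.T @ (flat - mean[:, None])).reshape(p, *raster.shape)
    return MNFResult(
        components=MultibandRaster(comps),
        eigenvalues=evals,
        noise_cov=noise_cov,
        transform=W,
        mean=mean,
    )


def _hull_vertices(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Indices (into the original candidate list) of hull vertices of the
    subset ``idx``; falls back to MNF1 extremes for degenerate clouds."""
    sub = points[idx]
    try:
        hull = ConvexHull(sub)
        return idx[hull.vertices]
    except (QhullError, ValueError):
        # collinear or too few points: take extremes along the first axis
        order = np.argsort(sub[:, 0], kind="stable")
        return idx[[order[0], order[-1]]] if len(idx) > 1 else idx


def select_corner_pixels(
    mnf: MNFResult, candidate_coords: np.ndarray, k: int
) -> np.ndarray:
    """Pick ``k`` candidates lying at convex-hull vertices in (MNF1, MNF2).

    The outermost hull's vertices are taken first; if fewer than ``k``, the
    hull is peeled (vertices removed, hull recomputed) until ``k`` are
    collected. When a hull overshoots, its vertices are ranked by distance
    from the centroid of all candidates (descending) and truncated.
    """
    coords = np.asarray(candidate_coords, dtype=int).reshape(-1, 2)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(coords) < k:
        raise ValueError(f"only {len(coords)} candidates for k={k} corner pixels")
    pts = mnf.components.values[:2, coords[:, 0], coords[:, 1]].T  # (n, 2)
    centroid = pts.mean(axis=0)

    chosen: list[int] = []
    remaining = np.arange(len(coords))
    while len(chosen) < k:
        if len(remaining) == 0:
            break
        verts = _hull_vertices(pts, remaining)
        need = k - len(chosen)
        if len(verts) > need:
            d = np.linalg.norm(pts[verts] - centroid, axis=1)
            verts = verts[np.argsort(-d, kind="stable")[:need]]
        chosen.extend(verts.tolist())
        remaining = np.setdiff1d(remaining, verts, assume_unique=True)
    return coords[np.asarray(chosen[:k], dtype=int)]


def build_training_set(
    raster: MultibandRaster,
    labels: LabelRaster,
    target_code: int,
    n_mixed: int = 60,
    n_corner: int = 60,
    *,
    seed: int = 0,
    mnf: MNFResult | None = None,
) -> SampleSet:
    """Edge training set: mixed boundary pixels + MNF corner pixels.

    ``n_mixed`` boundary pixels are subsampled in boundary-scan order with
    a seeded random phase (every k-th pixel, avoiding spatial clumping);
    ``n_corner`` corner pixels come from the convex hull of the remaining
    target pixels in the MNF1-MNF2 plane, so the two sources never overlap.
    A warning is issued when the total falls below the 30p rule of thumb.
    """
    p = raster.n_bands
    if n_mixed + n_corner < 30 * p:
        warnings.warn(
            f"training set of {n_mixed + n_corner} below the 30p rule ({30 * p})"
        )
    rng = np.random.default_rng(seed)

    full_boundary = boundary = extract_boundary_pixels(labels, target_code)
    # prefer true class-boundary pixels (a non-target *neighbour*, not just
    # the image border) for the mixed source; they carry mixed spectra
    is_t = labels.labels == target_code
    interior_edge = np.zeros_like(is_t)
    h_, w_ = is_t.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.zeros_like(is_t)
            rs = slice(max(dr, 0), h_ + min(dr, 0))
            rd = slice(max(-dr, 0), h_ + min(-dr, 0))
            cs = slice(max(dc, 0), w_ + min(dc, 0))
            cd = slice(max(-dc, 0), w_ + min(-dc, 0))
            shifted[rd, cd] = ~is_t[rs, cs]
            interior_edge |= is_t & shifted
    class_boundary = np.argwhere(interior_edge)
    if len(class_boundary) >= n_mixed:
        boundary = class_boundary
    if n_mixed > 0 and len(boundary) < n_mixed:
        raise ValueError(
            f"only {len(boundary)} boundary pixels available, need n_mixed={n_mixed}"
        )
    if n_mixed > 0:
        step = len(boundary) / n_mixed
        phase = rng.uniform(0, step)
        idx = np.minimum((phase + step * np.arange(n_mixed)).astype(int), len(boundary) - 1)
        mixed_coords = boundary[np.unique(idx)]
        # rounding collisions are rare; top up from unused boundary pixels
        if len(mixed_coords) < n_mixed:
            pool = np.setdiff1d(
                np.arange(len(boundary)), np.unique(idx), assume_unique=False
            )
            extra = rng.choice(pool, size=n_mixed - len(mixed_coords), replace=False)
            mixed_coords = np.vstack([mixed_coords, boundary[extra]])
    else:
        mixed_coords = np.empty((0, 2), dtype=int)

    if n_corner > 0:
        # corner candidates: target pixels off the boundary, so the two
        # training sources stay distinct (corner = the target cloud's own
        # spectral vertices, mixed = the boundary shell)
        target_coords = np.argwhere(labels.labels == target_code)
        taken = {tuple(c) for c in full_boundary}
        cand = np.array(
            [c for c in target_coords if tuple(c) not in taken], dtype=int
        ).reshape(-1, 2)
        if len(cand) < n_corner:  # tiny or all-boundary scenes: fall back
            taken = {tuple(c) for c in mixed_coords}
            cand = np.array(
                [c for c in target_coords if tuple(c) not in taken], dtype=int
            ).reshape(-1, 2)
        if len(cand) < n_corner:
            raise ValueError(
                f"only {len(cand)} corner candidates available, need n_corner={n_corner}"
            )
        if mnf is None:
            mnf = mnf_transform(raster)
        corner_coords = select_corner_pixels(mnf, cand, n_corner)
    else:
        corner_coords = np.empty((0, 2), dtype=int)

    coords = np.vstack([mixed_coords, corner_coords]).astype(int)
    return SampleSet(
        coords=coords,
        spectra=raster.spectra(coords),
        tags=np.array([TARGET] * len(coords), dtype=object),
        provenance="training",
        meta={"n_mixed": int(len(mixed_coords)), "n_corner": int(len(corner_coords)),
              "seed": seed, "target_code": int(target_code)},
    )


def build_validation_set(
    training: SampleSet,
    raster: MultibandRaster,
    labels: LabelRaster,
    target_code: int,
    w: int = 3,
    exclude_codes: tuple[int, ...] = (),
) -> SampleSet:
    """Window-based validation set.

    Union of the w x w windows centred on each training pixel, minus all
    training coordinates, deduplicated and clipped to the grid. Each pixel
    is tagged target iff its reference label equals ``target_code``;
    pixels whose label is in ``exclude_codes`` are dropped (the
    untrained-class experiment).
    """
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window size must be an odd integer >= 3, got {w}")
    if len(training) == 0:
        raise ValueError("training set is empty")
    half = w // 2
    h, wid = labels.shape
    train_coords = training.coord_set()
    excl = set(int(c) for c in exclude_codes)

    seen: set[tuple[int, int]] = set()
    for r, c in training.coords:
        for rr in range(max(0, r - half), min(h, r + half + 1)):
            for cc in range(max(0, c - half), min(wid, c + half + 1)):
                seen.add((rr, cc))
    coords = sorted(seen - train_coords)
    coords = [rc for rc in coords if int(labels.labels[rc]) not in excl]
    coords_arr = np.asarray(coords, dtype=int).reshape(-1, 2)
    tags = np.where(
        labels.labels[coords_arr[:, 0], coords_arr[:, 1]] == target_code, TARGET, OUTLIER
    ).astype(object)
    return SampleSet(
        coords=coords_arr,
        spectra=raster.spectra(coords_arr),
        tags=tags,
        provenance="validation",
        window=w,
        meta={"exclude_codes": sorted(excl), "target_code": int(target_code)},
    )


def build_random_validation_set(
    reference: SampleSet,
    raster: MultibandRaster,
    labels: LabelRaster,
    target_code: int,
    *,
    exclude_coords: set[tuple[int, int]] | None = None,
    exclude_codes: tuple[int, ...] = (),
    seed: int = 0,
) -> SampleSet:
    """Size-matched random validation set (the conventional comparator).

    Draws the same number of target and outlier pixels as ``reference``,
    uniformly at random over the whole labeled scene instead of from
    windows around the training set. Used to quantify the value of
    window-based (informative-outlier) sampling.
    """
    rng = np.random.default_rng(seed)
    excl_coords = exclude_coords or set()
    excl = set(int(c) for c in exclude_codes)
    is_t = labels.labels == target_code
    ok = np.ones(labels.shape, dtype=bool)
    for code in excl:
        ok &= labels.labels != code
    if excl_coords:
        rr, cc = zip(*excl_coords)
        ok[np.array(rr), np.array(cc)] = False

    def _draw(mask: np.ndarray, n: int) -> np.ndarray:
        pool = np.argwhere(mask)
        if len(pool) < n:
            raise ValueError(f"only {len(pool)} pixels available, need {n}")
        return pool[rng.choice(len(pool), size=n, replace=False)]

    t_coords = _draw(is_t & ok, reference.n_target)
    o_coords = _draw(~is_t & ok, reference.n_outlier)
    coords = np.vstack([t_coords, o_coords])
    tags = np.array([TARGET] * len(t_coords) + [OUTLIER] * len(o_coords), dtype=object)
    return SampleSet(
        coords=coords,
        spectra=raster.spectra(coords),
        tags=tags,
        provenance="validation",
        meta={"sampling": "random", "seed": seed, "target_code": int(target_code)},
    )
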