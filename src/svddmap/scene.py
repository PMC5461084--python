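"""Synthetic multispectral scene generation.

Produces fragmented-parcel landscapes with known per-pixel class fractions:
parcel interiors are drawn from a per-class multivariate Gaussian, and
pixels near parcel boundaries are linear spectral mixtures of the adjoining
classes — the mixed boundary pixels that edge-based training sets and
window-based validation sets rely on. Ground truth (hard labels + fraction
maps) is returned alongside the image, so classification accuracy can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import LabelRaster, MultibandRaster

__all__ = [
    "ClassSignature",
    "ParcelLayout",
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "canonical_scene_spec",
]


@dataclass
class ClassSignature:
    """Spectral model of one land-cover class: mean spectrum and covariance
    of the per-pixel Gaussian noise around it."""

    name: str
    mean: np.ndarray
    covariance: np.ndarray
    is_target: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = self.mean.shape[0]
        if not np.all(np.isfinite(self.mean)):
            raise ValueError(f"class {self.name}: non-finite mean")
        if self.covariance.shape != (p, p):
            raise ValueError(f"class {self.name}: covariance must be {p}x{p}")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError(f"class {self.name}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError(f"class {self.name}: covariance not PSD")


@dataclass
class ParcelLayout:
    """Rectangular parcel tessellation parameters.

    Parcels are axis-aligned cells whose edges pass through pixel centers;
    ``mean_size`` controls the average cell edge length in pixels. Explicit
    edge positions may be supplied instead (used for controlled geometries
    such as a two-class half-plane).
    """

    mean_size: int = 20
    row_edges: list[float] | None = None
    col_edges: list[float] | None = None


@dataclass
class SceneSpec:
    """Full recipe for one synthetic scene."""

    n_bands: int
    grid: tuple[int, int]
    classes: list[ClassSignature]
    parcel_layout: ParcelLayout = field(default_factory=ParcelLayout)
    mixing_width: int = 1
    class_weights: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        n_target = sum(c.is_target for c in self.classes)
        if n_target != 1:
            raise ValueError(f"exactly one target class required, got {n_target}")
        if self.mixing_width < 0:
            raise ValueError("mixing_width must be >= 0")
        h, w = self.grid
        if h < 1 or w < 1:
            raise ValueError(f"degenerate grid {self.grid}")
        for c in self.classes:
            if c.mean.shape[0] != self.n_bands:
                raise ValueError(f"class {c.name}: mean length != n_bands")

    @property
    def target_index(self) -> int:
        return next(i for i, c in enumerate(self.classes) if c.is_target)

    @property
    def class_table(self) -> dict[int, str]:
        return {i: c.name for i, c in enumerate(self.classes)}


@dataclass
class SceneTruth:
    """Ground truth for a generated scene: per-class sub-pixel fraction maps
    (shape ``(n_classes, h, w)``, summing to 1 per pixel) and the hard label
    map (class of largest fraction, ties to the lowest class code)."""

    labels: LabelRaster
    fractions: np.ndarray

    def target_fraction(self, target_code: int) -> np.ndarray:
        return self.fractions[target_code]


def _edge_positions(length: int, mean_size: int, min_size: int, rng) -> list[float]:
    """Random interior edge coordinates with block sizes ~ U[0.6m, 1.4m].

    Each edge gets a continuous sub-pixel offset in (-0.5, 0.5): a real
    parcel boundary falls at an arbitrary position within a pixel, so the
    mixed pixels straddling it are *dominated* by one of the two classes
    (fraction != 0.5 in general) rather than being exact half mixtures.
    """
    edges: list[float] = []
    pos = 0
    lo = max(min_size, int(round(0.6 * mean_size)))
    hi = max(lo + 1, int(round(1.4 * mean_size)))
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos >= length - min_size:
            break
        edges.append(pos + float(rng.uniform(-0.5, 0.5)))
    return edges


def _side_weights(n: int, edges: list[float], mixing_width: int) -> np.ndarray:
    """Per-coordinate weight of lying in each 1-D cell.

    For each interior edge ``b`` the transition from the left cell to the
    right is a linear ramp of total width ``mixing_width`` centred on the
    edge position, mimicking area-weighted mixing across a boundary: with
    ``mixing_width=1`` the pixel containing the edge gets the exact area
    overlap fraction (0.5 when the edge passes through its centre) and its
    neighbours stay pure. Returns an array of shape ``(n_cells, n)`` whose
    columns sum to 1.
    """
    x = np.arange(n, dtype=float)
    k = len(edges)
    right = np.empty((k + 2, n))
    right[0] = 1.0
    right[k + 1] = 0.0
    for j, b in enumerate(edges, start=1):
        if mixing_width == 0:
            right[j] = (x >= b).astype(float)
        else:
            right[j] = np.clip(0.5 + (x - b) / mixing_width, 0.0, 1.0)
    return right[:-1] - right[1:]


def _gaussian_field(sig: ClassSignature, shape: tuple[int, int], rng) -> np.ndarray:
    """Per-pixel draws from N(mean, cov), shape (p, h, w)."""
    p = sig.mean.shape[0]
    h, w = shape
    if np.allclose(sig.covariance, 0.0):
        return np.broadcast_to(sig.mean[:, None, None], (p, h, w)).copy()
    # symmetric PSD square root; robust to singular covariances
    vals, vecs = np.linalg.eigh(sig.covariance)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    z = rng.standard_normal((p, h * w))
    return (sig.mean[:, None] + root @ z).reshape(p, h, w)


def generate_scene(spec: SceneSpec) -> tuple[MultibandRaster, SceneTruth]:
    """Generate a scene and its ground truth from a :class:`SceneSpec`.

    The per-pixel spectrum is ``sum_c f_c * x_c`` where ``f_c`` are the
    recorded sub-pixel class fractions and ``x_c ~ N(mean_c, cov_c)`` —
    i.e. a linear mixture of per-class Gaussian draws at boundary pixels
    and a pure class draw in parcel interiors. Identical spec (including
    seed) yields a bit-identical scene.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.grid
    min_size = 2 * spec.mixing_width + 1
    layout = spec.parcel_layout
    row_edges = (
        list(layout.row_edges)
        if layout.row_edges is not None
        else _edge_positions(h, layout.mean_size, min_size, rng)
    )
    col_edges = (
        list(layout.col_edges)
        if layout.col_edges is not None
        else _edge_positions(w, layout.mean_size, min_size, rng)
    )

    row_w = _side_weights(h, row_edges, spec.mixing_width)
    col_w = _side_weights(w, col_edges, spec.mixing_width)
    n_rc, n_cc = row_w.shape[0], col_w.shape[0]

    weights = spec.class_weights
    if weights is None:
        weights = [1.0] * len(spec.classes)
    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    cell_class = rng.choice(len(spec.classes), size=(n_rc, n_cc), p=probs)

    n_classes = len(spec.classes)
    fractions = np.zeros((n_classes, h, w))
    for i in range(n_rc):
        for j in range(n_cc):
            fractions[cell_class[i, j]] += np.outer(row_w[i], col_w[j])
    # weights along each axis sum to 1, so fractions sum to 1 per pixel
    image = np.zeros((spec.n_bands, h, w))
    for c, sig in enumerate(spec.classes):
        if np.any(fractions[c] > 0):
            image += fractions[c] * _gaussian_field(sig, (h, w), rng)

    hard = np.argmax(fractions, axis=0).astype(np.int64)  # ties -> lowest code
    labels = LabelRaster(hard, spec.class_table)
    return MultibandRaster(image), SceneTruth(labels, fractions)


def canonical_scene_spec(seed: int = 0) -> SceneSpec:
    """Canonical 4-band, 4-class crop-mapping scene.

    Emulates a fragmented winter-wheat landscape observed with a 4-band
    (blue/green/red/NIR) high-resolution sensor: the target class "wheat"
    plus three outlier covers whose spectral distance to wheat increases
    from "bare_land" (adjacent in feature space) through "trees" to
    "water" (far away). Reflectance-scale means, isotropic per-class noise
    (SD 0.015), 200x200 grid, ~20-pixel parcels, 1-pixel mixing band.
    """
    p = 4
    sd = 0.015
    cov = (sd**2) * np.eye(p)
    classes = [
        ClassSignature("wheat", [0.100, 0.120, 0.100, 0.420], cov, is_target=True),
        ClassSignature("bare_land", [0.130, 0.145, 0.130, 0.400], cov),
        ClassSignature("trees", [0.060, 0.080, 0.050, 0.300], cov),
        ClassSignature("water", [0.030, 0.035, 0.020, 0.015], cov),
    ]
    return SceneSpec(
        n_bands=p,
        grid=(200, 200),
        classes=classes,
        parcel_layout=ParcelLayout(mean_size=20),
        mixing_width=1,
        class_weights=[0.40, 0.25, 0.20, 0.15],
        seed=seed,
    )
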