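"""Multiband raster and label-map containers with TIFF / ENVI-BSQ I/O.

Conventions shared by every module in the package:

* pixel coordinates are 0-based ``(row, col)``, row 0 at the top;
* image values are indexed ``(band, row, col)``;
* georeference, when present, is carried as opaque metadata — no
  reprojection or resampling is ever performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "MultibandRaster",
    "LabelRaster",
    "read_raster",
    "write_raster",
    "read_labels",
    "write_labels",
]


@dataclass
class MultibandRaster:
    """A p-band image grid of pixel spectra.

    Parameters
    ----------
    values
        Float array of shape ``(n_bands, height, width)``.
    resolution
        Ground meters per pixel, if known.
    nodata
        Sentinel marking invalid pixels (compared on band 0).
    """

    values: np.ndarray
    resolution: float | None = None
    nodata: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise ValueError(
                f"expected (band, row, col) array, got shape {self.values.shape}"
            )
        p, h, w = self.values.shape
        if p < 1 or h < 1 or w < 1:
            raise ValueError(f"degenerate raster shape {self.values.shape}")
        finite = np.isfinite(self.values)
        if self.nodata is not None:
            finite |= self.values == self.nodata
        if not finite.all():
            raise ValueError("raster contains non-finite values outside nodata")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def valid_mask(self) -> np.ndarray:
        """Boolean (row, col) mask of pixels that are not nodata."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return ~np.any(self.values == self.nodata, axis=0)

    def spectrum(self, row: int, col: int) -> np.ndarray:
        """The length-p spectrum at one pixel."""
        return self.values[:, row, col]

    def spectra(self, coords) -> np.ndarray:
        """Spectra at a sequence of (row, col) coordinates, shape (n, p)."""
        coords = np.asarray(coords, dtype=int)
        if coords.size == 0:
            return np.empty((0, self.n_bands))
        return self.values[:, coords[:, 0], coords[:, 1]].T


@dataclass
class LabelRaster:
    """Integer class codes on a (row, col) grid.

    ``class_table`` maps each code to a class name; ``unknown_code`` is
    reserved for unlabeled / nodata pixels and need not appear in the table.
    """

    labels: np.ndarray
    class_table: Mapping[int, str]
    unknown_code: int = -1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        self.class_table = dict(self.class_table)
        codes = set(np.unique(self.labels).tolist()) - {self.unknown_code}
        missing = codes - set(self.class_table)
        if missing:
            raise ValueError(f"label codes {sorted(missing)} absent from class_table")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# I/O: GeoTIFF via tifffile, plus an ENVI-style BSQ binary + text header
# fallback so tests and pipelines can run without any TIFF tooling.
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {
    "4": np.float32,
    "5": np.float64,
    "2": np.int16,
    "3": np.int32,
    "12": np.uint16,
    "13": np.uint32,
    "1": np.uint8,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def write_raster(
    raster: MultibandRaster, path: str | Path, *, overwrite: bool = True
) -> Path:
    """Write a raster to GeoTIFF (``.tif``) or ENVI BSQ (anything else).

    Round-trips losslessly through :func:`read_raster` for float32/float64
    imagery and for integer label bands.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    meta = {"resolution": raster.resolution, "nodata": raster.nodata}
    if _is_tiff(path):
        kwargs = {"planarconfig": "separate"} if raster.n_bands > 1 else {}
        tifffile.imwrite(
            path,
            raster.values if raster.n_bands > 1 else raster.values[0],
            photometric="minisblack",
            description=json.dumps(meta),
            **kwargs,
        )
    else:
        dtype = np.dtype(raster.values.dtype)
        if dtype not in _ENVI_CODES:
            dtype = np.dtype(np.float64)
        raster.values.astype(dtype).tofile(path)
        hdr_lines = [
            "ENVI",
            f"samples = {raster.width}",
            f"lines = {raster.height}",
            f"bands = {raster.n_bands}",
            f"data type = {_ENVI_CODES[dtype]}",
            "interleave = bsq",
            "byte order = 0",
        ]
        if raster.nodata is not None:
            hdr_lines.append(f"data ignore value = {raster.nodata}")
        if raster.resolution is not None:
            hdr_lines.append(f"pixel size = {raster.resolution}")
        path.with_suffix(path.suffix + ".hdr").write_text("\n".join(hdr_lines) + "\n")
    return path


def _read_envi(path: Path) -> MultibandRaster:
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise ValueError(f"no ENVI header found at {hdr_path}")
    fields: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        p = int(fields["bands"])
        dtype = _ENVI_DTYPES[fields["data type"]]
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} missing field {exc}") from exc
    if p < 1:
        raise ValueError(f"{path}: zero bands declared")
    values = np.fromfile(path, dtype=dtype)
    if values.size != p * h * w:
        raise ValueError(
            f"{path}: expected {p * h * w} values for {p}x{h}x{w}, got {values.size}"
        )
    nodata = fields.get("data ignore value")
    res = fields.get("pixel size")
    return MultibandRaster(
        values.reshape(p, h, w),
        resolution=float(res) if res is not None else None,
        nodata=float(nodata) if nodata is not None else None,
    )


def read_raster(path: str | Path) -> MultibandRaster:
    """Read a multiband raster written by :func:`write_raster`.

    Dialect is chosen by extension: ``.tif``/``.tiff`` → TIFF, anything
    else → ENVI BSQ with a ``.hdr`` text sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_tiff(path):
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description or ""
        if values.ndim == 2:
            values = values[np.newaxis]
        meta: dict = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        return MultibandRaster(
            values,
            resolution=meta.get("resolution"),
            nodata=meta.get("nodata"),
        )
    return _read_envi(path)


def write_labels(labels: LabelRaster, path: str | Path, *, overwrite: bool = True) -> Path:
    """Write a label raster as a single-band int32 file plus a JSON sidecar
    holding the class table and unknown code."""
    path = Path(path)
    raster = MultibandRaster(
        labels.labels.astype(np.int32)[np.newaxis],
        nodata=float(labels.unknown_code),
    )
    write_raster(raster, path, overwrite=overwrite)
    sidecar = {
        "class_table": {str(k): v for k, v in labels.class_table.items()},
        "unknown_code": labels.unknown_code,
    }
    path.with_suffix(path.suffix + ".classes.json").write_text(json.dumps(sidecar))
    return path


def read_labels(
    path: str | Path, class_table: Mapping[int, str] | None = None, unknown_code: int | None = None
) -> LabelRaster:
    """Read a single-band integer raster as a :class:`LabelRaster`.

    The class table is taken from the argument if given, else from the
    ``.classes.json`` sidecar written by :func:`write_labels`. Codes not in
    the table (other than ``unknown_code``) raise ``ValueError``.
    """
    path = Path(path)
    raster = read_raster(path)
    if raster.n_bands != 1:
        raise ValueError(f"label raster must be single-band, got {raster.n_bands}")
    if class_table is None:
        sidecar = path.with_suffix(path.suffix + ".classes.json")
        if not sidecar.exists():
            raise ValueError(f"no class table given and no sidecar at {sidecar}")
        data = json.loads(sidecar.read_text())
        class_table = {int(k): v for k, v in data["class_table"].items()}
        if unknown_code is None:
            unknown_code = int(data["unknown_code"])
    if unknown_code is None:
        unknown_code = -1
    labels = np.rint(raster.values[0]).astype(np.int64)
    return LabelRaster(labels, class_table, unknown_code=unknown_code)
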