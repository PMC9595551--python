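"""Read and write 3D volumes and per-lacuna tables, carrying voxel spacing.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` with ``z`` = slice index (ascending TIFF
  page / file order).
* ``spacing`` is the voxel edge length per axis in micrometres, ordered
  ``(sz, sy, sx)``; anisotropic spacing is supported throughout.
* All geometry downstream is computed in physical micrometres.

Spacing given explicitly by the caller is the source of truth and overrides
anything recorded in a file.  Volumes written by :func:`write_volume` embed
the spacing (and sample name) as a JSON ``ImageDescription`` tag so that
round trips need no sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, InputError

Spacing = tuple[float, float, float]

RECORD_COLUMNS = [
    "id",
    "voxel_count",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "max_feret_um",
    "min_orth_feret_um",
    "aspect_ratio",
]


def _check_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ConfigError(f"spacing must have three entries (sz, sy, sx), got {spacing!r}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ConfigError(f"voxel spacing must be positive and finite, got {spacing!r}")
    return spacing


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with per-axis voxel spacing in um.

    Higher intensity means more mineralized (X-ray attenuating) material;
    voids (lacunae, canals) are dark.
    """

    data: np.ndarray
    spacing: Spacing
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ConfigError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def physical_volume_mm3(self) -> float:
        """Physical volume of the whole grid in mm^3."""
        nz, ny, nx = self.data.shape
        return nz * ny * nx * self.voxel_volume_um3 / 1e9


@dataclass
class BinaryMask:
    """Boolean void mask (True = candidate lacuna/canal voxel)."""

    data: np.ndarray
    spacing: Spacing
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ConfigError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def void_fraction(self) -> float:
        return float(self.data.mean())


def _numeric_key(p: Path):
    """Sort key that orders slice_2 before slice_10."""
    parts = re.split(r"(\d+)", p.name)
    return [int(s) if s.isdigit() else s for s in parts]


def read_volume(path, spacing: Sequence[float] | None = None) -> VoxelGrid:
    """Read a volume from a multi-page TIFF, a directory of single-page
    TIFFs, or a JSON sidecar describing a raw binary file.

    Parameters
    ----------
    path
        TIFF file, directory of numbered TIFF slices, or a ``.json`` sidecar
        with keys ``shape``, ``dtype``, ``spacing_um`` and ``raw`` (path of
        the raw file, relative to the sidecar).
    spacing
        ``(sz, sy, sx)`` in um.  Overrides any spacing recorded in the file;
        required if the file records none.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such volume: {path}")

    name = path.stem
    file_spacing = None

    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_key,
        )
        if not files:
            raise InputError(f"directory contains no TIFF slices: {path}")
        slices = []
        shape0 = None
        for p in files:
            page = tifffile.imread(p)
            if page.ndim != 2:
                raise InputError(f"slice is not a single 2D page: {p}")
            if shape0 is None:
                shape0 = page.shape
            elif page.shape != shape0:
                raise InputError(
                    f"inconsistent slice shapes: {p} has {page.shape}, expected {shape0}"
                )
            slices.append(page)
        data = np.stack(slices, axis=0)
    elif path.suffix.lower() == ".json":
        meta = json.loads(path.read_text())
        raw_path = path.parent / meta.get("raw", path.stem + ".raw")
        if not raw_path.exists():
            raise InputError(f"no such raw file: {raw_path}")
        data = np.fromfile(raw_path, dtype=np.dtype(meta["dtype"]))
        shape = tuple(int(n) for n in meta["shape"])
        if data.size != int(np.prod(shape)):
            raise InputError(
                f"raw file {raw_path} has {data.size} elements, expected {np.prod(shape)}"
            )
        data = data.reshape(shape)
        file_spacing = meta.get("spacing_um")
        name = meta.get("name", name)
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if data.ndim == 2:
            data = data[np.newaxis]
        meta = _parse_description(desc)
        file_spacing = meta.get("spacing_um")
        name = meta.get("name", name) or name

    if spacing is not None:
        spacing = _check_spacing(spacing)
    elif file_spacing is not None:
        spacing = _check_spacing(file_spacing)
    else:
        raise ConfigError(
            f"no voxel spacing recorded in {path}; pass spacing=(sz, sy, sx) explicitly"
        )
    return VoxelGrid(data=data, spacing=spacing, name=name)


def _parse_description(desc) -> dict:
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        return {}
    return meta if isinstance(meta, dict) else {}


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as a multi-page grayscale TIFF (lossless for integer
    dtypes), with spacing and name embedded as a JSON description tag."""
    path = Path(path)
    desc = json.dumps({"spacing_um": list(grid.spacing), "name": grid.name})
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    try:
        tifffile.imwrite(path, data, description=desc, photometric="minisblack")
    except (OSError, PermissionError) as exc:
        raise InputError(f"cannot write volume to {path}: {exc}") from exc


def mask_to_grid(mask: BinaryMask) -> VoxelGrid:
    """View a binary mask as a uint8 grid (for TIFF serialization)."""
    return VoxelGrid(mask.data.astype(np.uint8), mask.spacing, mask.name)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert LacunaRecord objects to a tidy DataFrame (one row per label)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.label,
                "voxel_count": r.voxel_count,
                "volume_um3": r.volume_um3,
                "centroid_z_um": r.centroid_um[0],
                "centroid_y_um": r.centroid_um[1],
                "centroid_x_um": r.centroid_um[2],
                "max_feret_um": r.max_feret_um,
                "min_orth_feret_um": r.min_orth_feret_um,
                "aspect_ratio": r.aspect_ratio,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable, path) -> None:
    """Write per-lacuna records as CSV (header always present)."""
    try:
        records_to_frame(records).to_csv(path, index=False)
    except (OSError, PermissionError) as exc:
        raise InputError(f"cannot write records to {path}: {exc}") from exc


def read_records(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such records file: {path}")
    return pd.read_csv(path)
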