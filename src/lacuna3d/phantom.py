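"""Synthetic bone phantoms with planted, fully known lacuna populations.

A phantom is a two-level intensity volume (bright mineralized matrix, dark
voids) into which we plant

* ellipsoidal lacunae — volumes drawn from a right-skewed log-normal law
  truncated to 20-2000 um^3, aspect ratios (c/a) from a normal law
  truncated to (0, 1], orientations uniform on the rotation group, centers
  uniform with rejection; and
* straight cylindrical vascular canals, each larger than the 2000 um^3
  cutoff so the counting window must reject them.

The middle semi-axis b is drawn uniformly in [c, a] (tri-axial proportions
beyond the aspect ratio are a modeling choice; see docs/methods.md).

Planted lacunae keep a clearance of one bounding-sphere sum plus a
separation margin from each other and from the canals, stay clear of the
domain border, and — so that recovered count can equal planted count
*exactly* on a clean phantom — every accepted ellipsoid is validated to
digitize, on the target voxel lattice, to a single nonempty 6-connected
component whose voxel volume lies strictly inside (10, 2000) um^3; draws
that fail are re-placed or re-drawn.

Degradation (`degrade`) emulates the blur/noise penalty seen on
plastic-embedded scans: a Gaussian blur with a physical-unit sigma followed
by additive white Gaussian noise.

Same seed + parameters -> bit-identical phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ConfigError, NumericError, PackingError
from .labeling import STRUCTURE_6
from .volume_io import BinaryMask, Spacing, VoxelGrid, _check_spacing


@dataclass
class EllipsoidSpec:
    """One planted lacuna: center (z, y, x) um, semi-axes a >= b >= c um,
    rotation matrix mapping body axes to world axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: np.ndarray  # (3, 3), world = center + R @ body

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ConfigError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if self.rotation.shape != (3, 3):
            raise ConfigError("rotation must be a 3x3 matrix")

    @property
    def true_volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def true_ar(self) -> float:
        a, _, c = self.semi_axes
        return c / a


@dataclass
class CanalSpec:
    """Straight cylindrical canal from start to end (z, y, x um)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_um: float

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ConfigError(f"canal radius must be positive, got {self.radius_um}")
        if self.volume_um3 <= 2000.0:
            raise ConfigError(
                f"canal volume {self.volume_um3:.0f} um^3 must exceed the 2000 um^3 "
                "cutoff (it must be rejectable as a non-lacunar cavity)"
            )

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def volume_um3(self) -> float:
        return math.pi * self.radius_um**2 * self.length_um


@dataclass
class PhantomTruth:
    """Ground-truth roster of planted objects."""

    lacunae: list[EllipsoidSpec]
    canals: list[CanalSpec]
    domain_volume_mm3: float
    seed: int

    @property
    def planted_concentration_per_mm3(self) -> float:
        return len(self.lacunae) / self.domain_volume_mm3

    def to_frame(self) -> pd.DataFrame:
        """One row per planted object (lacunae then canals)."""
        rows = []
        for i, e in enumerate(self.lacunae, start=1):
            q = Rotation.from_matrix(e.rotation).as_quat()  # (x, y, z, w)
            rows.append(
                {
                    "kind": "lacuna",
                    "id": i,
                    "z_um": e.center[0], "y_um": e.center[1], "x_um": e.center[2],
                    "a_um": e.semi_axes[0], "b_um": e.semi_axes[1], "c_um": e.semi_axes[2],
                    "quat_x": q[0], "quat_y": q[1], "quat_z": q[2], "quat_w": q[3],
                    "true_volume_um3": e.true_volume_um3,
                    "true_ar": e.true_ar,
                    "radius_um": np.nan,
                    "end_z_um": np.nan, "end_y_um": np.nan, "end_x_um": np.nan,
                }
            )
        for i, ca in enumerate(self.canals, start=1):
            rows.append(
                {
                    "kind": "canal",
                    "id": i,
                    "z_um": ca.start[0], "y_um": ca.start[1], "x_um": ca.start[2],
                    "a_um": np.nan, "b_um": np.nan, "c_um": np.nan,
                    "quat_x": np.nan, "quat_y": np.nan, "quat_z": np.nan, "quat_w": np.nan,
                    "true_volume_um3": ca.volume_um3,
                    "true_ar": np.nan,
                    "radius_um": ca.radius_um,
                    "end_z_um": ca.end[0], "end_y_um": ca.end[1], "end_x_um": ca.end[2],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PhantomParams:
    """Generator parameters.

    Defaults correspond to an inner-petrous-like sample: ~95,000 lacunae
    per mm^3, right-skewed volumes with mean ~130 um^3, mean aspect ratio
    ~0.46, at ~1 um voxels, plus a few transcortical canals.
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    spacing: Spacing = (1.0, 1.0, 1.0)
    concentration_per_mm3: float = 95_000.0
    volume_mean_um3: float = 130.0
    volume_sd_um3: float = 90.0
    volume_range_um3: tuple[float, float] = (20.0, 2000.0)
    ar_mean: float = 0.46
    ar_sd: float = 0.11
    n_canals: int = 3
    canal_radius_um: float = 4.0
    bone_level: float = 200.0
    void_level: float = 0.0
    blur_sigma_um: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    name: str = "phantom"

    def __post_init__(self):
        self.spacing = _check_spacing(self.spacing)
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ConfigError(f"shape must be three positive ints, got {self.shape}")
        if self.concentration_per_mm3 <= 0:
            raise ConfigError("concentration must be positive")
        if self.volume_mean_um3 <= 0 or self.volume_sd_um3 <= 0:
            raise ConfigError("volume distribution parameters must be positive")
        lo, hi = self.volume_range_um3
        if not (0 < lo < hi):
            raise ConfigError(f"volume range must satisfy 0 < lo < hi, got {self.volume_range_um3}")
        if not (0 < self.ar_mean <= 1) or self.ar_sd <= 0:
            raise ConfigError("AR distribution parameters out of range")
        if self.n_canals < 0 or self.canal_radius_um <= 0:
            raise ConfigError("bad canal parameters")
        if self.blur_sigma_um < 0 or self.noise_sd < 0:
            raise ConfigError("blur sigma and noise SD must be >= 0")
        if self.void_level >= self.bone_level:
            raise ConfigError("void level must be darker than bone level")

    @property
    def domain_size_um(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=np.float64) * np.asarray(self.spacing)

    @property
    def domain_volume_mm3(self) -> float:
        return float(np.prod(self.domain_size_um)) / 1e9


#: Bone-type presets anchored to the published per-sample tables:
#: concentrations per mm^3 (inner petrous ~95,000; outer petrous ~55,000;
#: mastoid ~28,000; femur ~27,000), mean volumes and aspect ratios per type.
PRESETS: dict[str, dict] = {
    "ip": dict(concentration_per_mm3=95_000.0, volume_mean_um3=130.0, volume_sd_um3=100.0,
               ar_mean=0.46, ar_sd=0.11, name="ip_phantom"),
    "op": dict(concentration_per_mm3=55_000.0, volume_mean_um3=280.0, volume_sd_um3=190.0,
               ar_mean=0.46, ar_sd=0.11, name="op_phantom"),
    "t": dict(concentration_per_mm3=28_000.0, volume_mean_um3=190.0, volume_sd_um3=170.0,
              ar_mean=0.47, ar_sd=0.11, name="t_phantom"),
    "f": dict(concentration_per_mm3=27_000.0, volume_mean_um3=130.0, volume_sd_um3=90.0,
              ar_mean=0.37, ar_sd=0.10, name="f_phantom"),
}


def preset_params(preset: str, **overrides) -> PhantomParams:
    """PhantomParams for a named bone-type preset (ip, op, t, f)."""
    key = preset.lower()
    if key not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[key])
    kwargs.update(overrides)
    return PhantomParams(**kwargs)


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Parameters of the underlying normal from arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def draw_volumes(params: PhantomParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """n lacuna volumes (um^3): log-normal truncated to the volume range by
    rejection, so the law stays a proper truncation (no mass at the bounds)."""
    mu, sigma = _lognormal_mu_sigma(params.volume_mean_um3, params.volume_sd_um3)
    lo, hi = params.volume_range_um3
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        draw = rng.lognormal(mu, sigma, size=max(need * 2, 16))
        good = draw[(draw > lo) & (draw < hi)][:need]
        out[filled:filled + good.size] = good
        filled += good.size
    if filled < n:
        raise NumericError("volume law rejects nearly all draws; check parameters")
    return out


def draw_aspect_ratios(params: PhantomParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """n aspect ratios c/a from a normal law truncated to (0, 1]."""
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        draw = rng.normal(params.ar_mean, params.ar_sd, size=max(need * 2, 16))
        good = draw[(draw > 0) & (draw <= 1)][:need]
        out[filled:filled + good.size] = good
        filled += good.size
    if filled < n:
        raise NumericError("AR law rejects nearly all draws; check parameters")
    return out


def _semi_axes(volume: float, ar: float, b_frac: float) -> tuple[float, float, float]:
    """Semi-axes (a, b, c) with c = ar * a, b = c + b_frac * (a - c), and
    (4/3) pi a b c = volume."""
    beta = ar + b_frac * (1.0 - ar)  # b / a
    a = (3.0 * volume / (4.0 * math.pi * beta * ar)) ** (1.0 / 3.0)
    return a, beta * a, ar * a


def _digitize_ellipsoid(spec: EllipsoidSpec, shape, spacing) -> np.ndarray | None:
    """Boolean local crop of the ellipsoid's digitization (voxel centers
    inside), or None if its bounding box leaves the lattice entirely."""
    spacing = np.asarray(spacing, dtype=np.float64)
    center = np.asarray(spec.center, dtype=np.float64)
    a = spec.semi_axes[0]
    lo = np.maximum(np.floor((center - a) / spacing - 1).astype(int), 0)
    hi = np.minimum(np.ceil((center + a) / spacing + 1).astype(int), np.asarray(shape))
    if np.any(hi <= lo):
        return None
    idx = [np.arange(lo[d], hi[d]) for d in range(3)]
    centers = [(idx[d] + 0.5) * spacing[d] - center[d] for d in range(3)]
    zz, yy, xx = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) @ spec.rotation  # = R^T @ (p - c)
    ax = np.asarray(spec.semi_axes)
    inside = np.sum((pts / ax) ** 2, axis=-1) <= 1.0
    return inside, lo


def _valid_digitization(spec: EllipsoidSpec, params: PhantomParams) -> bool:
    """Single nonempty 6-connected component, voxel volume strictly inside
    (10, 2000) um^3 — so the counting window retains it unambiguously."""
    dig = _digitize_ellipsoid(spec, params.shape, params.spacing)
    if dig is None:
        return False
    inside, _ = dig
    count = int(inside.sum())
    vv = float(np.prod(params.spacing))
    if count == 0 or not (10.0 < count * vv < 2000.0):
        return False
    _, n = ndimage.label(inside, structure=STRUCTURE_6)
    return n == 1


def _place_canals(params: PhantomParams, rng: np.random.Generator) -> list[CanalSpec]:
    """Straight canals along x, spanning the full domain, mutually separated."""
    if params.n_canals == 0:
        return []
    Lz, Ly, Lx = params.domain_size_um
    r = params.canal_radius_um
    vol = math.pi * r * r * Lx
    if vol <= 2000.0:
        raise ConfigError(
            f"canal volume {vol:.0f} um^3 <= 2000 um^3; increase radius or domain size"
        )
    margin = 2.0 * max(params.spacing)
    lo, hi_z, hi_y = r + margin, Lz - r - margin, Ly - r - margin
    if hi_z <= lo or hi_y <= lo:
        raise ConfigError("domain too small for the requested canals")
    centers: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centers) == params.n_canals:
            break
        z = rng.uniform(lo, hi_z)
        y = rng.uniform(lo, hi_y)
        if all((z - cz) ** 2 + (y - cy) ** 2 >= (2 * r + 2 * margin) ** 2 for cz, cy in centers):
            centers.append((z, y))
    if len(centers) < params.n_canals:
        raise PackingError(
            "could not place canals without overlap",
            achieved=len(centers), requested=params.n_canals,
        )
    return [CanalSpec(start=(z, y, 0.0), end=(z, y, float(Lx)), radius_um=r) for z, y in centers]


def sample_population(params: PhantomParams) -> PhantomTruth:
    """Draw the planted population (exactly round(concentration x volume)
    lacunae plus the configured canals); deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.concentration_per_mm3 * params.domain_volume_mm3))
    if n < 1:
        raise ConfigError(
            f"expected lacuna count {n} < 1; enlarge the domain or concentration"
        )
    canals = _place_canals(params, rng)

    L = params.domain_size_um
    sep = 2.0 * max(params.spacing)
    border = 1.0 * max(params.spacing)
    accepted: list[EllipsoidSpec] = []
    centers = np.empty((n, 3))
    radii = np.empty(n)
    canal_zy = np.array([[c.start[0], c.start[1]] for c in canals]).reshape(-1, 2)
    canal_r = params.canal_radius_um

    budget = 2000 * n
    tries = 0
    while len(accepted) < n:
        volume = float(draw_volumes(params, 1, rng)[0])
        ar = float(draw_aspect_ratios(params, 1, rng)[0])
        b_frac = float(rng.uniform())
        axes = _semi_axes(volume, ar, b_frac)
        rot = Rotation.random(rng=rng).as_matrix()
        placed = False
        for attempt in range(60):
            tries += 1
            if tries > budget:
                raise PackingError(
                    f"packing gave up after {tries} tries "
                    f"({len(accepted)}/{n} lacunae placed); lower the concentration "
                    "or enlarge the domain",
                    achieved=len(accepted), requested=n,
                )
            a = axes[0]
            low = a + border
            high = L - (a + border)
            if np.any(high <= low):
                break  # object too large for the domain; redraw
            center = rng.uniform(low, high)
            k = len(accepted)
            if k:
                d2 = np.sum((centers[:k] - center) ** 2, axis=1)
                if np.any(d2 < (radii[:k] + a + sep) ** 2):
                    continue
            if len(canal_zy):
                dzy = np.sum((canal_zy - center[:2]) ** 2, axis=1)
                if np.any(dzy < (canal_r + a + sep) ** 2):
                    continue
            spec = EllipsoidSpec(center=tuple(center), semi_axes=axes, rotation=rot)
            if not _valid_digitization(spec, params):
                # sub-voxel placement can fragment thin objects; nudge first,
                # then re-orient, before giving up on this draw
                if attempt % 10 == 9:
                    rot = Rotation.random(rng=rng).as_matrix()
                continue
            centers[k] = center
            radii[k] = a
            accepted.append(spec)
            placed = True
            break
        if not placed:
            continue  # redraw volume/AR/orientation

    return PhantomTruth(
        lacunae=accepted,
        canals=canals,
        domain_volume_mm3=params.domain_volume_mm3,
        seed=params.seed,
    )


def rasterize(truth: PhantomTruth, params: PhantomParams) -> tuple[VoxelGrid, BinaryMask]:
    """Paint the truth onto the voxel lattice.

    A voxel is void iff its center lies inside any planted ellipsoid or
    canal; the intensity grid is bone_level everywhere and void_level on
    the mask.
    """
    shape = params.shape
    spacing = np.asarray(params.spacing)
    mask = np.zeros(shape, dtype=bool)

    for spec in truth.lacunae:
        dig = _digitize_ellipsoid(spec, shape, spacing)
        if dig is None:
            continue
        inside, lo = dig
        sl = tuple(slice(lo[d], lo[d] + inside.shape[d]) for d in range(3))
        mask[sl] |= inside

    for canal in truth.canals:
        _paint_canal(mask, canal, spacing)

    grid_data = np.full(shape, params.bone_level, dtype=np.float32)
    grid_data[mask] = params.void_level
    grid = VoxelGrid(grid_data, params.spacing, name=params.name)
    return grid, BinaryMask(mask, params.spacing, name=params.name)


def _paint_canal(mask: np.ndarray, canal: CanalSpec, spacing: np.ndarray) -> None:
    start = np.asarray(canal.start)
    end = np.asarray(canal.end)
    r = canal.radius_um
    lo = np.maximum(np.floor((np.minimum(start, end) - r) / spacing - 1).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(start, end) + r) / spacing + 1).astype(int),
                    np.asarray(mask.shape))
    if np.any(hi <= lo):
        return
    idx = [np.arange(lo[d], hi[d]) for d in range(3)]
    centers = [(idx[d] + 0.5) * spacing[d] for d in range(3)]
    zz, yy, xx = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    axis = end - start
    length2 = float(axis @ axis)
    rel = pts - start
    t = np.clip((rel @ axis) / length2, 0.0, 1.0)
    closest = start + t[..., None] * axis
    d2 = np.sum((pts - closest) ** 2, axis=-1)
    sl = tuple(slice(lo[d], hi[d]) for d in range(3))
    mask[sl] |= d2 <= r * r


def degrade(grid: VoxelGrid, blur_sigma_um: float, noise_sd: float, seed: int) -> VoxelGrid:
    """Gaussian blur (physical-unit sigma, converted per axis by the voxel
    spacing) followed by additive zero-mean white Gaussian noise.

    sigma = 0 and noise 0 return the input unchanged; deterministic given
    the seed.  Blur uses reflective boundaries, so the global mean is
    preserved.
    """
    if blur_sigma_um < 0 or noise_sd < 0:
        raise ConfigError("blur sigma and noise SD must be >= 0")
    data = np.asarray(grid.data, dtype=np.float64)
    if blur_sigma_um > 0:
        sigma_vox = [blur_sigma_um / s for s in grid.spacing]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    if blur_sigma_um == 0 and noise_sd == 0:
        return grid
    return VoxelGrid(data.astype(np.float32), grid.spacing, name=grid.name)


def make_phantom(params: PhantomParams) -> tuple[VoxelGrid, BinaryMask, PhantomTruth]:
    """Sample, rasterize and (optionally) degrade in one call.

    The degradation seed is derived from the population seed so one seed
    fixes the whole phantom.
    """
    truth = sample_population(params)
    grid, mask = rasterize(truth, params)
    if params.blur_sigma_um > 0 or params.noise_sd > 0:
        grid = degrade(grid, params.blur_sigma_um, params.noise_sd,
                       seed=(params.seed + 1) % (2**31))
    return grid, mask, truth
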