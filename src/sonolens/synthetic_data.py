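"""Generators for every synthetic input the experiments consume.

Three target families drive the limit sweeps: a binary disc (focal
enlargement), two monopoles (bifocal separation), and the fixed-15 mm
bifocal at varying depth (focal-depth series).  A skull-like elliptical
shell phantom stands in for a CT-derived human skull when exercising
aberration correction, and a noisy raster-scan generator emulates
needle-hydrophone measurements for the scan-versus-simulation
comparator.

All generators are deterministic given their parameters (and seed,
where randomness is involved).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .wave_engine import (
    WATER_SOUND_SPEED,
    ComplexField,
    Medium,
    SimulationGrid,
)

__all__ = [
    "TargetPattern",
    "SkullPhantom",
    "ScanData",
    "make_disc_target",
    "make_bifocal_target",
    "make_depth_series_target",
    "make_skull_phantom",
    "make_synthetic_scan",
    "write_scan",
    "read_scan",
]


@dataclass
class TargetPattern:
    """Desired normalised amplitude distribution over the grid.

    ``weights`` has the grid's volume shape, values in [0, 1] with max
    exactly 1.  ``foci`` lists nominal focus centres as (x, z) in 2-D
    or (x, y, z) in 3-D, metres.
    """

    weights: np.ndarray
    foci: list
    depth: float
    separation: Optional[float] = None
    diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("target weights must be non-negative")
        if self.weights.max() != 1.0:
            raise ValueError("target weights must be normalised to max 1")

    def recovered_foci(self, grid: SimulationGrid) -> list:
        """Focus centres read back from the weight map (2-D grids)."""
        iz, ix = np.nonzero(self.weights)
        out = []
        for zi in np.unique(iz):
            xs = ix[iz == zi]
            # split into contiguous runs along x
            breaks = np.nonzero(np.diff(np.sort(xs)) > 1)[0]
            groups = np.split(np.sort(xs), breaks + 1)
            for g in groups:
                out.append((float(np.mean(grid.x[g])), float(grid.z[zi])))
        return out


@dataclass
class SkullPhantom:
    """Elliptical bone shell standing in for a CT-derived skull.

    ``outer_radii`` are the lateral/axial semi-axes of the outer table;
    the shell has uniform ``thickness`` except that the x > 0 side is
    scaled by ``asymmetry`` (emulating a focus placed under a thicker
    part of the skull).  ``crown_z`` positions the lowest point of the
    outer table on the beam axis.
    """

    outer_radii: tuple
    thickness: float
    c_bone: float
    rho_bone: float
    asymmetry: float = 1.0
    crown_z: float = 10e-3
    alpha_bone: float = 6.9  # dB/cm/MHz, cortical-bone-typical

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.thickness >= min(self.outer_radii):
            raise ValueError("shell thickness must be positive and below the radii")
        if self.c_bone <= WATER_SOUND_SPEED:
            raise ValueError("bone sound speed must exceed the water value")
        if self.rho_bone <= 0 or self.asymmetry <= 0:
            raise ValueError("density and asymmetry must be positive")

    def rasterize(self, grid: SimulationGrid, c0: float, rho0: float) -> Medium:
        """Voxelised sound-speed/density maps on a 2-D grid."""
        if not grid.is_2d:
            raise NotImplementedError("the skull phantom rasterises on 2-D grids")
        a, b = self.outer_radii
        zc = self.crown_z + b  # ellipse centre on axis, crown at crown_z
        X = grid.x[None, :]
        Z = grid.z[:, None] - zc
        t = np.where(X > 0, self.thickness * self.asymmetry, self.thickness)
        outer = (X / a) ** 2 + (Z / b) ** 2 <= 1.0
        inner = (X / (a - t)) ** 2 + (Z / (b - t)) ** 2 < 1.0
        shell = outer & ~inner
        c = np.where(shell, self.c_bone, c0)
        rho = np.where(shell, self.rho_bone, rho0)
        alpha = np.where(shell, self.alpha_bone, 0.0)
        return Medium(c=c, rho=rho, alpha=alpha, c0=c0, rho0=rho0)

    def interior_mask(self, grid: SimulationGrid) -> np.ndarray:
        """Head-interior (brain cavity) voxels, inside the inner table."""
        a, b = self.outer_radii
        zc = self.crown_z + b
        X = grid.x[None, :]
        Z = grid.z[:, None] - zc
        t = np.where(X > 0, self.thickness * self.asymmetry, self.thickness)
        return (X / (a - t)) ** 2 + (Z / (b - t)) ** 2 < 1.0


@dataclass
class ScanData:
    """2-D (or line) raster scan of pressure magnitude."""

    x: np.ndarray  # m, strictly monotone
    y: np.ndarray  # m, strictly monotone (single value for line scans)
    amplitude: np.ndarray  # (ny, nx) or (nx,), >= 0
    z_depth: float  # scan plane depth, m
    step: float  # scan step, m
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for ax in (self.x, self.y):
            if len(ax) > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError("scan positions must be strictly monotone")
        if np.any(self.amplitude < 0):
            raise ValueError("scan magnitudes must be non-negative")


# ---------------------------------------------------------------------------
# target generators
# ---------------------------------------------------------------------------


def make_disc_target(diameter: float, depth: float, grid: SimulationGrid) -> TargetPattern:
    """Binary disc of the given diameter, centred on axis at ``depth``."""
    if diameter < grid.dh:
        raise ValueError("disc diameter must be at least one grid cell")
    iz = grid.z_index(depth)
    w = np.zeros(grid.volume_shape())
    r = diameter / 2
    if grid.is_2d:
        sel = np.abs(grid.x) <= r + 1e-12
        if grid.x[sel].min() - grid.dh < grid.x.min() or grid.x[sel].max() + grid.dh > grid.x.max():
            raise ValueError("disc does not fit inside the grid")
        w[iz, sel] = 1.0
    else:
        sel = grid.y[:, None] ** 2 + grid.x[None, :] ** 2 <= (r + 1e-12) ** 2
        w[iz][sel] = 1.0
    return TargetPattern(weights=w, foci=[(0.0, depth)], depth=depth, diameter=diameter)


def make_bifocal_target(separation: float, depth: float, grid: SimulationGrid) -> TargetPattern:
    """Two unit-weight monopole voxels at (+/- separation/2, depth)."""
    if separation < 2 * grid.dh:
        raise ValueError("separation must be at least two grid cells")
    iz = grid.z_index(depth)
    w = np.zeros(grid.volume_shape())
    foci = []
    for sx in (-separation / 2, separation / 2):
        ix = grid.x_index(sx)  # raises when outside the grid
        if grid.is_2d:
            w[iz, ix] = 1.0
        else:
            w[iz, grid.ny // 2, ix] = 1.0
        foci.append((sx, depth))
    if int(np.sum(w > 0)) != 2:
        raise ValueError("monopoles collapsed onto a single voxel")
    return TargetPattern(weights=w, foci=foci, depth=depth, separation=separation)


def make_depth_series_target(
    depth: float, grid: SimulationGrid, separation: float = 15e-3
) -> TargetPattern:
    """Fixed-separation (default 15 mm) bifocal target at a caller-varied depth."""
    return make_bifocal_target(separation, depth, grid)


def make_skull_phantom(
    outer_radii: tuple = (70e-3, 85e-3),
    thickness: float = 6e-3,
    c_bone: float = 2800.0,
    rho_bone: float = 1850.0,
    asymmetry: float = 1.4,
    crown_z: float = 10e-3,
    alpha_bone: float = 6.9,
) -> SkullPhantom:
    """Human-head-scale elliptical shell with literature-typical cortical
    bone properties (sound speed, density and absorption).

    Real skulls are laterally asymmetric, so the default phantom carries
    a 1.4x thicker +x side; a perfectly symmetric smooth shell aberrates
    so little that an uncorrected lens performs on par with a corrected
    one.  Pass ``asymmetry=1.0`` for the symmetric variant.
    """
    return SkullPhantom(
        outer_radii=outer_radii,
        thickness=thickness,
        c_bone=c_bone,
        rho_bone=rho_bone,
        asymmetry=asymmetry,
        crown_z=crown_z,
        alpha_bone=alpha_bone,
    )


# ---------------------------------------------------------------------------
# synthetic hydrophone scans
# ---------------------------------------------------------------------------


def make_synthetic_scan(
    field: ComplexField,
    noise_sd: float = 0.0,
    position_jitter_sd: float = 0.0,
    seed: Optional[int] = None,
    step: Optional[float] = None,
) -> ScanData:
    """Sample |field| on a raster lattice with hydrophone-like noise.

    Gaussian amplitude noise (``noise_sd`` as a fraction of the field
    peak) and Gaussian positioning jitter are added; magnitudes are
    clamped at zero.  Deterministic for a fixed seed.
    """
    if field.kind != "plane":
        raise ValueError("scans are taken on plane fields")
    if noise_sd < 0 or position_jitter_sd < 0:
        raise ValueError("noise and jitter standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    mag = field.magnitude
    dh = field.dh
    step = dh if step is None else step
    stride = max(1, int(round(step / dh)))
    peak = float(mag.max())

    if mag.ndim == 1:
        nx = mag.shape[0]
        xs = (np.arange(nx) - (nx - 1) / 2.0) * dh
        xg, yg = xs[::stride], np.array([0.0])
        if position_jitter_sd > 0:
            from scipy.interpolate import interp1d

            jit = rng.normal(0.0, position_jitter_sd, size=len(xg))
            f = interp1d(xs, mag, bounds_error=False, fill_value=0.0)
            vals = f(xg + jit)
        else:
            vals = mag[::stride].copy()
    else:
        ny, nx = mag.shape
        xs = (np.arange(nx) - (nx - 1) / 2.0) * dh
        ys = (np.arange(ny) - (ny - 1) / 2.0) * dh
        xg, yg = xs[::stride], ys[::stride]
        if position_jitter_sd > 0:
            from scipy.interpolate import RegularGridInterpolator

            f = RegularGridInterpolator((ys, xs), mag, bounds_error=False, fill_value=0.0)
            YY, XX = np.meshgrid(yg, xg, indexing="ij")
            jit = rng.normal(0.0, position_jitter_sd, size=(2,) + YY.shape)
            vals = f(np.stack([YY + jit[0], XX + jit[1]], axis=-1))
        else:
            vals = mag[::stride, ::stride].copy()

    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd * peak, size=vals.shape)
    vals = np.maximum(vals, 0.0)
    return ScanData(
        x=xg, y=yg, amplitude=vals, z_depth=field.z, step=stride * dh,
        meta={"noise_sd": noise_sd, "position_jitter_sd": position_jitter_sd, "seed": seed},
    )


def write_scan(scan: ScanData, path: "str | Path") -> None:
    """Write a scan as delimited text (x, y, amplitude columns)."""
    path = Path(path)
    amp = np.atleast_2d(scan.amplitude)
    rows = []
    for iy, yv in enumerate(np.atleast_1d(scan.y)):
        for ix, xv in enumerate(scan.x):
            rows.append((xv, yv, amp[iy, ix]))
    header = f"# z_depth={scan.z_depth!r} step={scan.step!r}\nx\ty\tamplitude"
    np.savetxt(path, np.asarray(rows), delimiter="\t", header=header, comments="")


def read_scan(path: "str | Path") -> ScanData:
    """Read a delimited-text scan written by :func:`write_scan` (or a
    real hydrophone export with the same x/y/amplitude layout)."""
    path = Path(path)
    z_depth, step = 0.0, 0.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        kv = dict(tok.split("=") for tok in first[1:].split())
        z_depth = float(kv.get("z_depth", 0.0))
        step = float(kv.get("step", 0.0))
    data = np.loadtxt(path, delimiter="\t", skiprows=2 if first.startswith("#") else 1)
    data = np.atleast_2d(data)
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    amp = data[:, 2].reshape(len(ys), len(xs))
    if len(ys) == 1:
        amp = amp[0]
    if step == 0.0 and len(xs) > 1:
        step = float(xs[1] - xs[0])
    return ScanData(x=xs, y=ys, amplitude=amp, z_depth=z_depth, step=step)
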