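"""Source models for the planar and focused single-element transducers.

Two hardware presets are provided: a planar 44 mm / 0.5 MHz disc
(``"tx_0.5_44"``) and a focused 82 mm bowl with 63.2 mm radius of
curvature at 1.645 MHz (``"h204"``).  A parametric focused family with
geometric focus at F-number times aperture supports the focused-versus-
planar comparison.

The holographic plane — where the printed lens sits and where phase is
recorded — is the emitting surface for the planar transducer.  For a
bowl it is the flat exit plane of the housing, so the bowl field must
first be projected onto that plane (:func:`project_bowl_to_exit_plane`)
and combined with the time-reversed recording during lens design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import hankel2

from .wave_engine import ComplexField, Medium, SimulationGrid

__all__ = [
    "TransducerSpec",
    "SourceAperture",
    "PRESETS",
    "get_preset",
    "f_number",
    "make_planar_source",
    "project_bowl_to_exit_plane",
    "make_parametric_focused",
    "normalize_power",
]


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry and drive parameters of a single-element source."""

    kind: str  # "planar" | "focused"
    aperture: float  # diameter d, m
    f0: float  # working frequency, Hz
    roc: Optional[float] = None  # radius of curvature, m (focused only)
    exit_plane_offset: float = 0.0  # m, relative to the bowl rim plane

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "focused"):
            raise ValueError("kind must be 'planar' or 'focused'")
        if self.aperture <= 0 or self.f0 <= 0:
            raise ValueError("aperture and frequency must be positive")
        if self.kind == "planar" and self.roc is not None:
            raise ValueError("planar transducers carry no radius of curvature")
        if self.kind == "focused":
            if self.roc is None:
                raise ValueError("focused transducers require a radius of curvature")
            if self.roc <= self.aperture / 2:
                raise ValueError("radius of curvature must exceed the aperture radius")

    @property
    def geometric_focus(self) -> Optional[float]:
        """Axial distance from the bowl to its centre of curvature."""
        return self.roc if self.kind == "focused" else None


#: Hardware presets matching the two physical transducers.
PRESETS = {
    "tx_0.5_44": TransducerSpec(kind="planar", aperture=44e-3, f0=0.5e6),
    "h204": TransducerSpec(kind="focused", aperture=82e-3, f0=1.645e6, roc=63.2e-3),
}


def get_preset(name: str) -> TransducerSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown transducer preset {name!r}; known: {sorted(PRESETS)}")


@dataclass
class SourceAperture:
    """Complex surface field over the holographic plane plus its mask."""

    field: ComplexField
    mask: np.ndarray

    def __post_init__(self) -> None:
        vals = self.field.values
        if vals.shape != self.mask.shape:
            raise ValueError("field and mask shapes differ")
        if np.any(vals[~self.mask] != 0):
            raise ValueError("aperture field must vanish outside the active mask")


def f_number(focal_depth: float, aperture: float) -> float:
    """F = f/d: focal depth over aperture diameter."""
    if focal_depth <= 0 or aperture <= 0:
        raise ValueError("focal depth and aperture must be positive")
    return focal_depth / aperture


def _aperture_mask(spec: TransducerSpec, grid: SimulationGrid) -> np.ndarray:
    r = spec.aperture / 2
    if grid.is_2d:
        mask = np.abs(grid.x) <= r + 1e-12
    else:
        mask = grid.y[:, None] ** 2 + grid.x[None, :] ** 2 <= (r + 1e-12) ** 2
    # require >= 4 cells of clearance to the lateral grid edge
    half_extent = (grid.nx - 1) / 2.0 * grid.dh
    if r > half_extent - 4 * grid.dh:
        raise ValueError("aperture does not fit in the grid with a 4-cell margin")
    return mask


def make_planar_source(spec: TransducerSpec, grid: SimulationGrid) -> SourceAperture:
    """Uniform unit-amplitude, zero-phase piston over a disc of diameter d."""
    mask = _aperture_mask(spec, grid)
    vals = np.where(mask, 1.0 + 0j, 0.0 + 0j)
    fld = ComplexField(values=vals, kind="plane", dh=grid.dh, f0=spec.f0, z=0.0)
    return SourceAperture(field=fld, mask=mask)


def project_bowl_to_exit_plane(
    spec: TransducerSpec,
    medium: Medium,
    grid: SimulationGrid,
    sources_per_cell: float = 2.0,
) -> SourceAperture:
    """Simulate the bowl radiating to its flat exit plane.

    Axial depth z is measured from the bowl apex (the transducer
    surface), so the geometric focus — the centre of curvature — lies
    at z = roc.  The bowl surface (an arc in 2-D, a spherical cap in
    3-D) is discretised into uniformly driven monopoles and the
    outgoing Green's function is summed on the exit plane, the plane
    through the bowl rim at z = roc (1 - cos(theta_max)) plus any
    ``exit_plane_offset``.
    """
    if spec.kind != "focused":
        raise ValueError("exit-plane projection applies to focused transducers only")
    k = 2 * np.pi * spec.f0 / medium.c_scalar
    roc = spec.roc
    a = spec.aperture / 2
    theta_max = np.arcsin(a / roc)
    sag = roc * (1 - np.cos(theta_max))  # bowl depth, apex to rim plane
    mask = _aperture_mask(spec, grid)
    z_plane = sag + spec.exit_plane_offset

    if grid.is_2d:
        n_src = max(64, int(np.ceil(2 * roc * theta_max / grid.dh * sources_per_cell)))
        th = (np.arange(n_src) + 0.5) / n_src * 2 * theta_max - theta_max
        xs = roc * np.sin(th)
        zs = roc * (1 - np.cos(th))  # bowl surface, z in [0, sag]
        ds = roc * (2 * theta_max / n_src)
        r = np.sqrt((grid.x[:, None] - xs[None, :]) ** 2 + (z_plane - zs[None, :]) ** 2)
        # outgoing cylindrical wave under exp(+i w t): H0^(2)(kr)
        vals = (ds * hankel2(0, k * np.maximum(r, grid.dh / 4))).sum(axis=1)
    else:
        # the exit field of an axisymmetric cap is axisymmetric: quadrature
        # on a radial line, then interpolation onto the transverse grid
        n_th = max(64, int(np.ceil(roc * theta_max / grid.dh * sources_per_cell)))
        th = (np.arange(n_th) + 0.5) / n_th * theta_max
        dth = theta_max / n_th
        rho_max = 1.05 * float(np.sqrt(grid.x.max() ** 2 + grid.y.max() ** 2))
        rho = np.linspace(0.0, rho_max, max(256, 2 * grid.nx))
        line = np.zeros(len(rho), dtype=np.complex128)
        for t in th:
            rs = roc * np.sin(t)
            zs = roc * (1 - np.cos(t))
            n_phi = max(16, int(np.ceil(2 * np.pi * rs / grid.dh * sources_per_cell)))
            phi = (np.arange(n_phi) + 0.5) / n_phi * 2 * np.pi
            dA = roc**2 * np.sin(t) * dth * (2 * np.pi / n_phi)
            r = np.sqrt(
                rho[:, None] ** 2 + rs**2 - 2 * rho[:, None] * rs * np.cos(phi)[None, :]
                + (z_plane - zs) ** 2
            )
            r = np.maximum(r, grid.dh / 4)
            line += dA * (np.exp(-1j * k * r) / r).sum(axis=1)
        rr = np.sqrt(grid.x[None, :] ** 2 + grid.y[:, None] ** 2)
        vals = np.interp(rr, rho, line.real) + 1j * np.interp(rr, rho, line.imag)
    vals = np.where(mask, vals, 0.0)
    peak = np.max(np.abs(vals))
    if peak > 0:
        vals = vals / peak
    fld = ComplexField(values=vals, kind="plane", dh=grid.dh, f0=spec.f0, z=z_plane)
    return SourceAperture(field=fld, mask=mask)


def make_parametric_focused(aperture: float, f_num: float, f0: float) -> TransducerSpec:
    """Focused spec with geometric focus at ``f_num * aperture``."""
    if not (0.5 <= f_num <= 4.0):
        raise ValueError("F-number outside the supported range [0.5, 4]")
    return TransducerSpec(kind="focused", aperture=aperture, f0=f0, roc=f_num * aperture)


def normalize_power(src: SourceAperture) -> SourceAperture:
    """Scale the aperture so its integrated |p|^2 over the plane is 1.

    Makes planar/focused field comparisons amplitude-fair.
    """
    vals = src.field.values
    cell = src.field.dh if vals.ndim == 1 else src.field.dh**2
    power = float(np.sum(np.abs(vals) ** 2) * cell)
    if power == 0:
        raise ValueError("aperture carries no power")
    fld = src.field.copy_with(vals / np.sqrt(power))
    return SourceAperture(field=fld, mask=src.mask)
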