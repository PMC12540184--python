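"""Phase-only hologram lens synthesis.

A recorded, conjugated holographic-plane field is turned into a
manufacturable lens: each pixel's desired transmitted phase is mapped to
a material thickness through the single-layer transmission coefficient

    T(h) = 2 Z exp(-i k0 (d - h)) / [2 Z cos(kL h) + i (Z^2 + 1) sin(kL h)]

where Z = ZL/Z0 is the lens impedance normalised by water, k0 and kL the
water/lens wavenumbers and d the total lens thickness measured from the
bottom of the lens (the remaining d - h is water path).  A cubic-spline
lookup inverts unwrapped transmitted phase to height over the thinnest
height range spanning a full 2 pi cycle.

Amplitude information of the ideal hologram is discarded (phase-only
lens); internal multiple reflections beyond the single-layer model are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .transducers import SourceAperture, TransducerSpec, make_planar_source, project_bowl_to_exit_plane
from .wave_engine import (
    WATER_DENSITY,
    WATER_SOUND_SPEED,
    ComplexField,
    Medium,
    SimulationGrid,
    TimeHarmonicSource,
    backpropagate_time_reversal,
    propagate_volume,
    timedomain_solve,
)

__all__ = [
    "LensMaterial",
    "LensHeightMap",
    "PhaseHeightLUT",
    "transmission_coefficient",
    "build_phase_height_lut",
    "design_lens",
    "forward_simulate",
    "export_stl",
    "export_height_image",
]

#: Default base (minimum) lens thickness, m.
DEFAULT_BASE_THICKNESS = 1e-3


@dataclass(frozen=True)
class LensMaterial:
    """Acoustic constants of the printed lens material.

    Defaults are typical for stereolithography clear resin; override
    them when the material has been characterised.
    """

    cL: float = 2580.0  # m/s
    rhoL: float = 1171.0  # kg/m^3
    c0: float = WATER_SOUND_SPEED
    rho0: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if self.cL <= 0 or self.rhoL <= 0 or self.c0 <= 0 or self.rho0 <= 0:
            raise ValueError("material properties must be positive")

    @property
    def ZL(self) -> float:
        return self.rhoL * self.cL

    @property
    def Z0(self) -> float:
        return self.rho0 * self.c0

    @property
    def Z(self) -> float:
        """Impedance normalised by water."""
        return self.ZL / self.Z0

    def k0(self, f0: float) -> float:
        return 2 * np.pi * f0 / self.c0

    def kL(self, f0: float) -> float:
        return 2 * np.pi * f0 / self.cL


@dataclass
class LensHeightMap:
    """Per-pixel lens thickness h(x, y) plus its material constants."""

    h: np.ndarray  # m, grid-plane shaped
    d: float  # total thickness reference, m
    pitch: float  # pixel pitch, m
    material: LensMaterial
    f0: float
    mask: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.h)):
            raise ValueError("height map contains non-finite values")
        if np.any(self.h < 0) or np.any(self.h > self.d):
            raise ValueError("heights must lie within [0, d]")

    def transmission(self) -> np.ndarray:
        """Complex per-pixel transmission of the printed lens."""
        return transmission_coefficient(self.h, self.material, self.f0, self.d)


def transmission_coefficient(
    h: "float | np.ndarray", material: LensMaterial, f0: float, d: float
) -> "complex | np.ndarray":
    """Single-layer complex transmission through a lens pixel of height h."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0) or np.any(h_arr > d + 1e-15):
        raise ValueError("height must lie within [0, d]")
    Z = material.Z
    k0 = material.k0(f0)
    kL = material.kL(f0)
    num = 2 * Z * np.exp(-1j * k0 * (d - h_arr))
    den = 2 * Z * np.cos(kL * h_arr) + 1j * (Z**2 + 1) * np.sin(kL * h_arr)
    T = num / den
    return complex(T) if np.ndim(h) == 0 else T


@dataclass
class PhaseHeightLUT:
    """Cubic-spline inversion of transmitted phase to height.

    ``heights``/``phases`` are the sampled (strictly monotone) curve;
    ``phase0`` is the transmitted phase at the minimum height, the
    branch anchor for the modulo-2pi inversion.
    """

    heights: np.ndarray
    phases: np.ndarray  # unwrapped arg T, same length
    transmissions: np.ndarray
    phase0: float
    spline: CubicSpline
    material: LensMaterial
    f0: float
    d: float

    def height_for_phase(self, phase: "float | np.ndarray") -> np.ndarray:
        """Smallest height whose transmitted phase matches ``phase`` mod 2 pi."""
        sign = 1.0 if self.phases[-1] > self.phases[0] else -1.0
        rel = np.mod(sign * (np.asarray(phase, dtype=float) - self.phase0), 2 * np.pi)
        return np.asarray(self.spline(self.phase0 + sign * rel))


def build_phase_height_lut(
    material: LensMaterial,
    f0: float,
    d: Optional[float] = None,
    n_samples: int = 512,
    h_min: float = DEFAULT_BASE_THICKNESS,
) -> PhaseHeightLUT:
    """Sample T(h) and fit height against unwrapped transmitted phase.

    The height range starts at the base thickness ``h_min`` and extends
    to the smallest height achieving a full 2 pi of transmitted phase;
    ``d`` defaults to ``h_min`` plus 1.2 phase cycles of height.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    dk = abs(material.k0(f0) - material.kL(f0))
    if d is None:
        if dk == 0:
            raise ValueError(
                "matched sound speeds give no thickness-phase coupling; "
                "choose a different lens material"
            )
        d = h_min + 1.2 * (2 * np.pi / dk)
    hs = np.linspace(h_min, d, n_samples)
    T = transmission_coefficient(hs, material, f0, d)
    ph = np.unwrap(np.angle(T))
    span = ph - ph[0]
    reach = np.nonzero(np.abs(span) >= 2 * np.pi)[0]
    if len(reach) == 0:
        raise ValueError(
            "transmitted phase spans less than 2 pi within [h_min, d]; "
            "increase the total thickness d"
        )
    stop = reach[0] + 1
    hs, ph, T = hs[:stop], ph[:stop], T[:stop]
    dph = np.diff(ph)
    if not (np.all(dph > 0) or np.all(dph < 0)):
        raise ValueError("transmitted phase is not monotone in height for this material")
    spline = (
        CubicSpline(ph, hs) if dph[0] > 0 else CubicSpline(ph[::-1], hs[::-1])
    )
    return PhaseHeightLUT(
        heights=hs,
        phases=ph,
        transmissions=T,
        phase0=float(ph[0]),
        spline=spline,
        material=material,
        f0=f0,
        d=float(d),
    )


# ---------------------------------------------------------------------------
# design pipeline
# ---------------------------------------------------------------------------


def _source_aperture(
    transducer: TransducerSpec, medium: Medium, grid: SimulationGrid
) -> SourceAperture:
    if transducer.kind == "planar":
        return make_planar_source(transducer, grid)
    # the bowl projection is a free-field step even when the target
    # medium is heterogeneous: the lens sits at the exit plane, in water
    water = Medium.water(c0=medium.c0, rho0=medium.rho0)
    return project_bowl_to_exit_plane(transducer, water, grid)


def design_lens(
    target,
    transducer: TransducerSpec,
    medium: Medium,
    material: LensMaterial,
    grid: SimulationGrid,
    lut: Optional[PhaseHeightLUT] = None,
    stepping=None,
) -> LensHeightMap:
    """Time-reversal design of a phase-only lens.

    Pipeline: back-propagate the target monopoles to the holographic
    plane and conjugate; for focused transducers combine the recording
    with the bowl's exit-plane field (the second simulation); take the
    per-pixel phase difference between the desired hologram and the
    incident field; convert phase to height through the LUT.  The
    amplitude of the recorded field is discarded.
    """
    f0 = transducer.f0
    if lut is None:
        lut = build_phase_height_lut(material, f0)
    source = _source_aperture(transducer, medium, grid)
    z_holo = source.field.z
    recorded = backpropagate_time_reversal(target, medium, z_holo, grid, f0, stepping=stepping)
    desired_phase = np.angle(recorded.values)
    incident_phase = np.angle(np.where(source.mask, source.field.values, 1.0))
    lens_phase = desired_phase - incident_phase
    h = lut.height_for_phase(lens_phase)
    h = np.where(source.mask, h, lut.heights[0])
    return LensHeightMap(
        h=h,
        d=lut.d,
        pitch=grid.dh,
        material=material,
        f0=f0,
        mask=source.mask,
        meta={
            "z_holo": z_holo,
            "transducer_kind": transducer.kind,
            "design_heterogeneous": not medium.is_homogeneous,
        },
    )


def forward_simulate(
    lens: LensHeightMap,
    transducer: TransducerSpec,
    medium: Medium,
    grid: SimulationGrid,
    stepping=None,
) -> ComplexField:
    """Forward verification: drive the transducer through the printed
    lens and return the field volume.

    The holographic-plane field is the incident aperture multiplied by
    the full complex transmission T(h) (amplitude ripple included).
    Homogeneous media propagate with the angular spectrum; heterogeneous
    media run the time-domain solver with the lens plane as the source.
    """
    source = _source_aperture(transducer, medium, grid)
    plane_vals = source.field.values * lens.transmission() * source.mask
    z_holo = source.field.z
    if medium.is_homogeneous:
        plane = ComplexField(values=plane_vals, kind="plane", dh=grid.dh, f0=lens.f0, z=z_holo)
        vol = propagate_volume(plane, grid.z, medium)
        vol.meta["engine"] = "asm"
        return vol
    src = TimeHarmonicSource.from_plane(plane_vals, grid.z_index(z_holo), grid, lens.f0)
    vol = timedomain_solve(medium, src, grid, stepping=stepping)
    vol.meta["engine"] = "timedomain"
    return vol


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_stl(lens: LensHeightMap, path: "str | Path"):
    """Write the lens as a watertight STL mesh.

    Height samples are treated as surface vertices on the pixel pitch;
    the solid is the closed volume between z = 0 and the (piecewise
    bilinear) top surface, so the mesh volume equals the trapezoidal
    integral of thickness.
    """
    import trimesh

    h = np.atleast_2d(lens.h)
    if not np.all(np.isfinite(h)):
        raise ValueError("height map contains non-finite values")
    ny, nx = h.shape
    if ny < 2:  # 2-D designs produce a one-pixel-deep ribbon
        h = np.vstack([h, h])
        ny = 2
    p = lens.pitch
    xs = np.arange(nx) * p
    ys = np.arange(ny) * p
    XX, YY = np.meshgrid(xs, ys)

    top = np.stack([XX.ravel(), YY.ravel(), h.ravel()], axis=1)
    bot = np.stack([XX.ravel(), YY.ravel(), np.zeros(h.size)], axis=1)
    vertices = np.vstack([top, bot])
    idx = np.arange(nx * ny).reshape(ny, nx)
    NB = nx * ny  # offset of bottom vertices

    faces = []
    a, b, c, d = idx[:-1, :-1], idx[:-1, 1:], idx[1:, 1:], idx[1:, :-1]
    # top surface (normals +z) and bottom (normals -z)
    faces.append(np.stack([a.ravel(), b.ravel(), c.ravel()], axis=1))
    faces.append(np.stack([a.ravel(), c.ravel(), d.ravel()], axis=1))
    faces.append(np.stack([a.ravel(), c.ravel(), b.ravel()], axis=1) + NB)
    faces.append(np.stack([a.ravel(), d.ravel(), c.ravel()], axis=1) + NB)

    def wall(edge_top: np.ndarray, flip: bool):
        e0, e1 = edge_top[:-1], edge_top[1:]
        quads = [
            np.stack([e0, e1, e1 + NB], axis=1),
            np.stack([e0, e1 + NB, e0 + NB], axis=1),
        ]
        if flip:
            quads = [q[:, ::-1] for q in quads]
        faces.extend(quads)

    wall(idx[0, :], flip=False)
    wall(idx[-1, :], flip=True)
    wall(idx[:, 0], flip=True)
    wall(idx[:, -1], flip=False)

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.vstack(faces), process=True)
    if not mesh.is_watertight:
        raise RuntimeError("generated lens mesh is not watertight")
    mesh.fix_normals()  # consistent outward winding -> positive volume
    mesh.export(str(path))
    return mesh


def export_height_image(lens: LensHeightMap, path: "str | Path") -> None:
    """16-bit grayscale height image with a text sidecar giving the scale."""
    from PIL import Image

    h = np.atleast_2d(lens.h)
    lo, hi = float(h.min()), float(h.max())
    scale = (hi - lo) or 1.0
    img = np.round((h - lo) / scale * 65535).astype(np.uint16)
    Image.fromarray(img, mode="I;16").save(str(path))
    sidecar = Path(str(path)).with_suffix(".txt")
    sidecar.write_text(
        f"h_min_m = {lo!r}\nh_max_m = {hi!r}\npitch_m = {lens.pitch!r}\n"
        f"d_m = {lens.d!r}\n"
    )
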