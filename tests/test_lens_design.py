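"""Transmission equation, phase-height lookup, design pipeline, STL export."""

import numpy as np
import pytest

import sonolens as sl
from sonolens.lens_design import (
    DEFAULT_BASE_THICKNESS,
    LensMaterial,
    build_phase_height_lut,
    design_lens,
    export_stl,
    forward_simulate,
    transmission_coefficient,
)


class TestTransmissionCoefficient:
    def test_zero_height_is_pure_water_delay(self, material):
        f0, d = 0.5e6, 8e-3
        T = transmission_coefficient(0.0, material, f0, d)
        assert abs(T) == pytest.approx(1.0, abs=1e-12)
        assert np.angle(T) == pytest.approx(
            np.angle(np.exp(-1j * material.k0(f0) * d)), abs=1e-12
        )

    def test_impedance_matched_lens_is_transparent(self):
        # same sound speed and density as water: |T| = 1, arg T = -k0 d
        matched = LensMaterial(cL=1482.0, rhoL=994.0)
        f0, d = 0.5e6, 8e-3
        for h in np.linspace(0, d, 17):
            T = transmission_coefficient(h, matched, f0, d)
            assert abs(T) == pytest.approx(1.0, abs=1e-9)
            assert np.angle(T * np.exp(1j * matched.k0(f0) * d)) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_quarter_wave_magnitude(self):
        # kL h = pi/2 -> |T| = 2Z/(Z^2+1); Z = 1.8 gives 0.849
        f0 = 0.5e6
        mat = LensMaterial(cL=2580.0, rhoL=1.8 * 1482.0 * 994.0 / 2580.0)
        assert mat.Z == pytest.approx(1.8, rel=1e-9)
        h = (np.pi / 2) / mat.kL(f0)
        T = transmission_coefficient(h, mat, f0, d=10e-3)
        assert abs(T) == pytest.approx(2 * 1.8 / (1.8**2 + 1), rel=1e-9)
        assert abs(T) == pytest.approx(0.849, abs=5e-4)

    def test_magnitude_never_exceeds_unity(self):
        """|T| <= 1 for all heights and impedances (energy passivity)."""
        f0 = 0.5e6
        for Z in (0.3, 0.7, 1.0, 1.8, 2.05, 4.0):
            mat = LensMaterial(cL=2580.0, rhoL=Z * 1482.0 * 994.0 / 2580.0)
            d = 12e-3
            T = transmission_coefficient(np.linspace(0, d, 400), mat, f0, d)
            assert np.max(np.abs(T)) <= 1.0 + 1e-12

    def test_height_outside_range_refused(self, material):
        with pytest.raises(ValueError):
            transmission_coefficient(-1e-3, material, 0.5e6, 8e-3)
        with pytest.raises(ValueError):
            transmission_coefficient(9e-3, material, 0.5e6, 8e-3)


class TestPhaseHeightLUT:
    def test_inversion_round_trip(self, material, lut_500k, rng):
        """100 random phases map to heights whose transmitted phase
        matches to < 0.01 rad."""
        f0 = 0.5e6
        phases = rng.uniform(-np.pi, np.pi, 100)
        hs = lut_500k.height_for_phase(phases)
        T = transmission_coefficient(hs, material, f0, lut_500k.d)
        err = np.abs(np.angle(T * np.exp(-1j * phases)))
        assert np.max(err) < 0.01

    def test_phase_monotone_over_selected_range(self, lut_500k):
        assert np.all(np.diff(lut_500k.phases) > 0) or np.all(
            np.diff(lut_500k.phases) < 0
        )

    def test_heights_span_one_cycle_above_base(self, lut_500k):
        assert lut_500k.heights[0] == pytest.approx(DEFAULT_BASE_THICKNESS)
        assert lut_500k.heights[-1] <= lut_500k.d

    def test_matched_material_degenerate(self):
        matched = LensMaterial(cL=1482.0, rhoL=994.0)
        with pytest.raises(ValueError):
            build_phase_height_lut(matched, 0.5e6)

    def test_insufficient_thickness_reports_remedy(self, material):
        with pytest.raises(ValueError, match="thickness"):
            build_phase_height_lut(material, 0.5e6, d=2e-3)


class TestDesignLens:
    def test_single_focus_forward_verifies_on_target(
        self, water, grid_2d, planar_tx, material
    ):
        tgt = sl.make_disc_target(grid_2d.dh, 50e-3, grid_2d)
        lens = design_lens(tgt, planar_tx, water, material, grid_2d)
        assert np.all((lens.h >= 0) & (lens.h <= lens.d))
        vol = forward_simulate(lens, planar_tx, water, grid_2d)
        mag = np.abs(vol.values)
        iz, ix = np.unravel_index(np.argmax(mag), mag.shape)
        assert abs(grid_2d.z[iz] - 50e-3) <= grid_2d.dh
        assert abs(grid_2d.x[ix]) <= grid_2d.dh

    def test_bifocal_height_map_mirror_symmetric(
        self, water, grid_2d, planar_tx, material, lut_500k
    ):
        tgt = sl.make_bifocal_target(16e-3, 50e-3, grid_2d)
        lens = design_lens(tgt, planar_tx, water, material, grid_2d, lut=lut_500k)
        # symmetry up to LUT quantisation at the 2 pi wrap line
        h, hm = lens.h, lens.h[::-1]
        cyc = lut_500k.heights[-1] - lut_500k.heights[0]
        diff = np.minimum(np.abs(h - hm), cyc - np.abs(h - hm))
        assert np.max(diff[lens.mask]) < 1e-6

    def test_design_deterministic(self, water, grid_2d, planar_tx, material):
        tgt = sl.make_bifocal_target(16e-3, 50e-3, grid_2d)
        l1 = design_lens(tgt, planar_tx, water, material, grid_2d)
        l2 = design_lens(tgt, planar_tx, water, material, grid_2d)
        assert np.array_equal(l1.h, l2.h)

    @pytest.mark.parametrize("separation", [10e-3, 15e-3, 25e-3])
    def test_bifocal_foci_recovered_within_one_wavelength(
        self, separation, water, grid_2d, planar_tx, material, lut_500k
    ):
        """Headline parameter recovery: forward-verified foci land within
        one wavelength of the designed monopole positions."""
        lam = water.c0 / planar_tx.f0
        tgt = sl.make_bifocal_target(separation, 50e-3, grid_2d)
        lens = design_lens(tgt, planar_tx, water, material, grid_2d, lut=lut_500k)
        vol = forward_simulate(lens, planar_tx, water, grid_2d)
        rep = sl.evaluate_field(vol, tgt)
        assert rep.distinct
        got = sorted(pos[0] for pos, _ in rep.detected_foci[:2])
        want = sorted(x for x, _ in tgt.foci)
        for g_, w_ in zip(got, want):
            assert abs(g_ - w_) < lam


class TestExportSTL:
    def _slab_lens(self, h_values, material):
        h = np.asarray(h_values, dtype=float)
        return sl.LensHeightMap(
            h=h,
            d=float(h.max()) + 1e-3,
            pitch=1e-3,
            material=material,
            f0=0.5e6,
            mask=np.ones_like(h, bool),
        )

    def test_constant_slab_volume(self, material, tmp_path):
        lens = self._slab_lens(np.full((12, 10), 3e-3), material)
        mesh = export_stl(lens, tmp_path / "slab.stl")
        area = (12 - 1) * (10 - 1) * (1e-3) ** 2
        assert mesh.volume == pytest.approx(area * 3e-3, rel=5e-3)
        assert (tmp_path / "slab.stl").exists()

    def test_checkerboard_volume_is_mean_height(self, material, tmp_path):
        h = np.full((16, 16), 2e-3)
        h[::2, ::2] = 4e-3
        h[1::2, 1::2] = 4e-3
        lens = self._slab_lens(h, material)
        mesh = export_stl(lens, tmp_path / "cb.stl")
        area = 15 * 15 * (1e-3) ** 2
        assert mesh.volume == pytest.approx(3e-3 * area, rel=5e-3)

    def test_designed_lens_mesh_watertight(
        self, water, grid_2d, planar_tx, material, tmp_path
    ):
        tgt = sl.make_bifocal_target(16e-3, 50e-3, grid_2d)
        lens = design_lens(tgt, planar_tx, water, material, grid_2d)
        mesh = export_stl(lens, tmp_path / "lens.stl")
        assert mesh.is_watertight

    def test_non_finite_heights_refused(self, material, tmp_path):
        h = np.full((8, 8), 2e-3)
        lens = self._slab_lens(h, material)
        lens.h[3, 3] = np.nan
        with pytest.raises((ValueError, RuntimeError)):
            export_stl(lens, tmp_path / "bad.stl")
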