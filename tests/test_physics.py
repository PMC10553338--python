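"""Spectral attenuation model and phantom generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcct_cardiac.physics import (CALCIUM, IODINE, WATER, DetectabilityPhantomSpec,
                                  DynamicPhantomConfig, EnergyGrid, MaterialModel,
                                  disk_fraction, lv_mask_volume_ml,
                                  make_detectability_phantom,
                                  make_dynamic_phantom, mass_attenuation)


class TestMassAttenuation:
    def test_kedge_jump_ratio_matches_configured_jump(self):
        eps = 1e-9
        lo = mass_attenuation(IODINE, 33.2 - eps)
        hi = mass_attenuation(IODINE, 33.2 + eps)
        assert hi > lo
        assert hi / lo == pytest.approx(IODINE.kedge_jump, abs=1e-9)

    def test_null_material_is_zero_everywhere(self):
        null = MaterialModel("null", 0.0, 0.0)
        e = np.linspace(10, 80, 30)
        assert np.all(mass_attenuation(null, e) == 0)

    def test_decreasing_with_energy_away_from_edge(self):
        # PE ~ E^-3 dominates the decline on each side of any edge
        e_low = np.linspace(11, 33.1, 40)
        e_high = np.linspace(33.3, 79, 40)
        for mat in (WATER, IODINE, CALCIUM):
            for e in (e_low, e_high):
                mu = mass_attenuation(mat, e)
                assert np.all(np.diff(mu) < 0), mat.name

    def test_water_attenuates_more_at_25_than_60_kev(self):
        assert mass_attenuation(WATER, 25.0) > mass_attenuation(WATER, 60.0)

    def test_energy_outside_grid_raises(self):
        with pytest.raises(ValueError):
            mass_attenuation(WATER, 5.0)
        with pytest.raises(ValueError):
            mass_attenuation(WATER, 90.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(11, 79), st.floats(0, 5), st.floats(0, 5),
           st.floats(0, 40), st.floats(0, 40))
    def test_mixture_linearity(self, e, cw, ci, cca, cca2):
        """Voxel attenuation is the concentration-weighted sum of materials."""
        total = (cw * mass_attenuation(WATER, e)
                 + ci * mass_attenuation(IODINE, e)
                 + (cca + cca2) * mass_attenuation(CALCIUM, e))
        parts = (cw * mass_attenuation(WATER, e)
                 + ci * mass_attenuation(IODINE, e)
                 + cca * mass_attenuation(CALCIUM, e)
                 + cca2 * mass_attenuation(CALCIUM, e))
        assert total == pytest.approx(parts, rel=1e-12)


class TestEnergyGrid:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            EnergyGrid(np.array([10.0, 10.0, 20.0]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            EnergyGrid(np.array([-1.0, 10.0, 20.0]))


class TestDynamicPhantom:
    def test_truth_stroke_volume_from_cohort_scale_volumes(self):
        # group-mean DLVV/SLVV of 0.045/0.022 mL give SV 0.023 mL
        ph = make_dynamic_phantom(dlvv_ml=0.045, slvv_ml=0.022)
        assert ph.truth["sv_ml"] == pytest.approx(0.023, abs=1e-12)

    def test_slvv_above_dlvv_rejected(self):
        with pytest.raises(ValueError):
            DynamicPhantomConfig(dlvv_ml=0.02, slvv_ml=0.03)

    def test_heart_rate_outside_band_rejected(self):
        with pytest.raises(ValueError):
            DynamicPhantomConfig(heart_rate_bpm=200.0)

    def test_equal_volumes_give_static_masks(self):
        ph = make_dynamic_phantom(dlvv_ml=0.03, slvv_ml=0.03)
        m0 = ph.lv_mask(0.0)
        for phase in (0.2, 0.5, 0.8):
            assert np.array_equal(ph.lv_mask(phase), m0)

    def test_same_seed_is_voxel_identical(self):
        a = make_dynamic_phantom(seed=7).render(0.3)
        b = make_dynamic_phantom(seed=7).render(0.3)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_mask_volume_extremes_match_truth_within_one_voxel(self):
        ph = make_dynamic_phantom(grid_n=96, voxel_mm=0.125,
                                  dlvv_ml=0.045, slvv_ml=0.022)
        for phase, key in ((0.0, "dlvv_ml"), (0.5, "slvv_ml")):
            mask = ph.lv_mask(phase)
            vol = lv_mask_volume_ml(mask, ph.voxel_mm)
            # one-voxel area change at this radius, sphere-equivalent
            area = mask.sum() * ph.voxel_mm**2
            r = np.sqrt(area / np.pi)
            tol = 2 * r * ph.voxel_mm**2 / 1000.0 + 1e-6
            assert vol == pytest.approx(ph.truth[key], abs=max(tol, 2e-3 * ph.truth[key]))

    def test_waveform_is_periodic_at_configured_rate(self):
        ph = make_dynamic_phantom(heart_rate_bpm=400.0)
        t = np.linspace(0, 1, 11)
        assert np.allclose(ph.phase_at(t), ph.phase_at(t + 60.0 / 400.0))


class TestDetectabilityPhantom:
    def test_default_grid_has_four_rows_and_five_diameters(self):
        ph = make_detectability_phantom()
        targets = [c for c in ph.cylinders if c.material != "water"]
        rows = {(c.material, c.concentration) for c in targets}
        assert rows == {("calcium", 10.0), ("calcium", 20.0),
                        ("calcium", 40.0), ("iodine", 10.0)}
        assert sorted({c.diameter_mm for c in targets}) == [0.5, 1.0, 1.5, 2.0, 2.5]

    def test_rendered_area_within_10pct_for_d_ge_4_voxels(self):
        ph = make_detectability_phantom()
        for cyl in ph.cylinders:
            d_vox = cyl.diameter_mm / ph.voxel_mm
            if d_vox < 4:
                continue
            area = ph.cylinder_fraction(cyl).sum()
            expect = np.pi * (d_vox / 2) ** 2
            assert area == pytest.approx(expect, rel=0.10)

    def test_rendered_ca40_mean_concentration(self):
        ph = make_detectability_phantom()
        maps = ph.render()
        cyl = next(c for c in ph.cylinders
                   if c.material == "calcium" and c.concentration == 40.0
                   and c.diameter_mm == 2.5)
        interior = ph.cylinder_fraction(cyl) > 0.999
        assert maps["calcium"][interior].mean() == pytest.approx(40.0, rel=0.01)

    def test_overlapping_cylinders_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_detectability_phantom(DetectabilityPhantomSpec(
                col_pitch_mm=0.5))

    def test_zero_diameter_renders_empty_with_warning(self):
        with pytest.warns(UserWarning, match="zero diameter"):
            ph = make_detectability_phantom(DetectabilityPhantomSpec(
                diameters_mm=(0.0, 2.0), water_vial_mm=0.0))
        empty = [c for c in ph.cylinders if c.diameter_mm == 0]
        assert all(ph.cylinder_fraction(c).sum() == 0 for c in empty)


class TestRasterization:
    def test_disk_area_fraction_integrates_to_circle_area(self):
        frac = disk_fraction((64, 64), (31.7, 30.2), 10.3)
        assert frac.sum() == pytest.approx(np.pi * 10.3**2, rel=2e-3)

    def test_volume_conventions(self):
        mask3 = np.ones((10, 10, 10), dtype=bool)
        assert lv_mask_volume_ml(mask3, 0.125) == pytest.approx(
            1000 * 0.125**3 / 1000.0)
        # 2D: a mask of area A maps to the sphere with equatorial area A
        mask = disk_fraction((64, 64), (31.5, 31.5), 12.0) >= 0.5
        vol = lv_mask_volume_ml(mask, 0.125)
        area_mm2 = mask.sum() * 0.125**2
        expect = 4 / (3 * np.sqrt(np.pi)) * area_mm2**1.5 / 1000.0
        assert vol == pytest.approx(expect, rel=1e-9)
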