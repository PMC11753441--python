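"""Phantom generation: geometry, activity bookkeeping, MR/CT surrogates."""

import numpy as np
import pytest

from ovopet.mumaps import hu_to_mu_511
from ovopet.petsim import decay_factor
from ovopet.phantoms import (
    LABEL_IDS,
    AcquisitionMeta,
    BedSpec,
    CoilSpec,
    EggGeometry,
    HardwareSpec,
    OrganSpec,
    default_organs,
    make_egg_phantom,
    make_hardware_mumap,
    make_inovo_phantom,
    simulate_ct_volume,
    simulate_mr_volume,
)
from ovopet.volume import make_grid


class TestEggPhantom:
    def test_uniform_fill_value(self):
        activity, labels, _ = make_egg_phantom(fill_concentration=117.0)
        liquid = labels.values == LABEL_IDS["liquid"]
        assert liquid.any()
        assert np.all(activity.values[liquid] == 117.0)
        assert np.all(activity.values[~liquid] == 0.0)

    def test_zero_fill_keeps_labels(self):
        a0, l0, _ = make_egg_phantom(fill_concentration=0.0)
        a1, l1, _ = make_egg_phantom(fill_concentration=117.0)
        assert np.all(a0.values == 0.0)
        np.testing.assert_array_equal(l0.values, l1.values)

    def test_liquid_volume_matches_analytic_ellipsoid(self):
        geom = EggGeometry(semi_axes_mm=(22.5, 22.5, 28.5), shell_thickness_mm=0.0)
        _, labels, _ = make_egg_phantom(geom, 1.0)
        n = int(np.sum(labels.values == LABEL_IDS["liquid"]))
        analytic = 4.0 / 3.0 * np.pi * 22.5 * 22.5 * 28.5  # 1 mm voxels
        assert abs(n - analytic) / analytic < 0.02

    def test_rasterization_converges_with_voxel_size(self):
        geom = EggGeometry(semi_axes_mm=(12.0, 12.0, 15.0), shell_thickness_mm=0.0)
        analytic = 4.0 / 3.0 * np.pi * 12.0**2 * 15.0
        errs = []
        for vs, n in ((1.0, 40), (0.5, 80)):
            _, labels, _ = make_egg_phantom(geom, 1.0, make_grid((n, n, n), vs))
            vol = np.sum(labels.values == LABEL_IDS["liquid"]) * vs**3
            errs.append(abs(vol - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_overflow_error_names_axis(self):
        grid = make_grid((96, 96, 40), 1.0)  # egg's long (z) axis cannot fit
        with pytest.raises(ValueError, match="axis 'z'"):
            make_egg_phantom(EggGeometry(), 1.0, grid)

    def test_mu_truth_values(self):
        _, labels, mu = make_egg_phantom()
        assert np.all(mu.values[labels.values == LABEL_IDS["liquid"]] == 0.096)
        assert np.all(mu.values[labels.values == LABEL_IDS["shell"]] == 0.17)


class TestInOvoPhantom:
    GRID = make_grid((64, 64, 64), 1.5)

    def test_total_activity_is_true_in_egg_decayed(self):
        meta = AcquisitionMeta(dispensed_activity_kBq=5000.0, residual_activity_kBq=200.0)
        activity, _, _, _ = make_inovo_phantom(EggGeometry(), default_organs(), meta, self.GRID)
        total = activity.values.sum() * activity.voxel_volume_cc
        expected = (5000.0 - 200.0) * decay_factor("F-18", 60.0)
        assert total == pytest.approx(expected, rel=5e-3)

    def test_lost_fraction_bookkeeping(self):
        net = 4800.0
        meta = AcquisitionMeta(
            dispensed_activity_kBq=5000.0,
            residual_activity_kBq=200.0,
            lost_activity_kBq=0.10 * net,
        )
        activity, _, _, _ = make_inovo_phantom(EggGeometry(), default_organs(), meta, self.GRID)
        total = activity.values.sum() * activity.voxel_volume_cc
        # calibrator reports dispensed - residual; the image only ever sees 90%
        expected = 0.9 * meta.calibrator_injected_kBq * decay_factor("F-18", 60.0)
        assert total == pytest.approx(expected, rel=5e-3)

    def test_organ_uptake_ratios(self):
        meta = AcquisitionMeta()
        activity, labels, _, _ = make_inovo_phantom(EggGeometry(), default_organs(), meta, self.GRID)
        bg = activity.values[labels.values == LABEL_IDS["liquid"]].mean()
        for name, ratio in (("brain", 2.0), ("liver", 3.0), ("xenograft", 4.0)):
            organ = activity.values[labels.values == LABEL_IDS[name]].mean()
            assert organ / bg == pytest.approx(ratio)

    def test_overlapping_organs_error_lists_pair(self):
        organs = [
            OrganSpec("brain", (0, 0, 0), 4.0, 2.0),
            OrganSpec("liver", (0, 0, 0), 5.0, 3.0, "sphere"),
        ]
        with pytest.raises(ValueError, match=r"\('brain', 'liver'\)"):
            make_inovo_phantom(EggGeometry(), organs, AcquisitionMeta(), self.GRID)

    def test_organ_outside_liquid_error(self):
        organs = [OrganSpec("brain", (0, 0, 27.0), 4.0, 2.0)]
        with pytest.raises(ValueError, match="outside the liquid"):
            make_inovo_phantom(EggGeometry(), organs, AcquisitionMeta(), self.GRID)


class TestAcquisitionMeta:
    def test_bookkeeping_identities(self):
        m = AcquisitionMeta(
            dispensed_activity_kBq=5000.0, residual_activity_kBq=300.0, lost_activity_kBq=470.0
        )
        assert m.calibrator_injected_kBq == 4700.0
        assert m.true_in_egg_kBq == 4230.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dispensed_activity_kBq": 5000.0, "residual_activity_kBq": 6000.0},
            {"dispensed_activity_kBq": 5000.0, "residual_activity_kBq": 200.0, "lost_activity_kBq": 4900.0},
            {"dispensed_activity_kBq": -1.0},
        ],
    )
    def test_invariant_violations(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionMeta(**kwargs)


class TestHardware:
    GRID = make_grid((96, 96, 16), 1.0)

    def test_no_components_gives_zero_maps(self):
        bed, coil = make_hardware_mumap(
            HardwareSpec(include_bed=False, include_coil=False), self.GRID
        )
        assert not bed.values.any() and not coil.values.any()

    def test_annulus_mu_mass_matches_analytic(self):
        spec = HardwareSpec(coil=CoilSpec(86.0, 5.0, 0.02), include_bed=False)
        _, coil = make_hardware_mumap(spec, self.GRID)
        ri, ro = 43.0, 48.0
        analytic = np.pi * (ro**2 - ri**2) * 0.02  # per-slice mass, 1 mm voxels
        per_slice = coil.values.sum(axis=(0, 1))
        np.testing.assert_allclose(per_slice, analytic, rtol=0.03)

    def test_bed_confined_below_midplane(self):
        spec = HardwareSpec(bed=BedSpec(28.0, 120.0, 8.0, 0.05), include_coil=False)
        bed, _ = make_hardware_mumap(spec, self.GRID)
        iy = np.nonzero(bed.values)[1]
        assert iy.size > 0
        assert iy.max() < self.GRID.shape[1] // 2  # bed opens upward, lies at y < center

    def test_coil_intersecting_egg_error(self):
        spec = HardwareSpec(coil=CoilSpec(inner_diameter_mm=40.0), include_bed=False)
        with pytest.raises(ValueError, match="intersects the egg"):
            make_hardware_mumap(spec, self.GRID, egg=EggGeometry())


class TestSurrogateMR:
    def test_noise_free_is_piecewise_constant(self):
        _, labels, _ = make_egg_phantom()
        mr = simulate_mr_volume(labels, noise_sd=0.0)
        assert set(np.unique(mr.values)) <= {2.0, 100.0}

    def test_seed_determinism(self):
        _, labels, _ = make_egg_phantom()
        a = simulate_mr_volume(labels, noise_sd=5.0, seed=11)
        b = simulate_mr_volume(labels, noise_sd=5.0, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_label_error(self):
        _, labels, _ = make_egg_phantom()
        with pytest.raises(ValueError, match=r"missing label\(s\) \[2\]"):
            simulate_mr_volume(labels, contrast={0: 2.0, 1: 100.0})

    def test_threshold_separates_compartments(self):
        from skimage.filters import threshold_otsu

        _, labels, _ = make_egg_phantom()
        mr = simulate_mr_volume(labels, noise_sd=5.0, seed=3)
        thr = threshold_otsu(mr.values)
        seg = mr.values > thr
        truth = labels.values == LABEL_IDS["liquid"]
        assert np.mean(seg != truth) < 0.01


class TestSurrogateCT:
    def test_air_and_water_anchors(self):
        mu = make_grid((4, 4, 4), 1.0, unit="cm-1")
        assert np.all(simulate_ct_volume(mu).values == -1000.0)
        mu.values[:] = 0.096
        assert np.all(simulate_ct_volume(mu).values == pytest.approx(0.0))

    def test_bilinear_roundtrip_on_hardware(self):
        spec = HardwareSpec()
        grid = make_grid((96, 96, 8), 1.0)
        bed, coil = make_hardware_mumap(spec, grid)
        for template in (bed, coil):
            back = hu_to_mu_511(simulate_ct_volume(template))
            nz = template.values > 0
            np.testing.assert_allclose(back.values[nz], template.values[nz], rtol=0.01)

    def test_out_of_range_mu_error(self):
        mu = make_grid((3, 3, 3), 1.0, unit="cm-1")
        mu.values[0, 0, 0] = 5.0
        with pytest.raises(ValueError, match="invertible range"):
            simulate_ct_volume(mu)
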