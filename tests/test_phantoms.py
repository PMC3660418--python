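"""Phantom generation and ground-truth oracle checks."""

import math

import numpy as np
import pytest

from acinomorph.morphometry import surface_area, region_volume
from acinomorph.phantoms import (PhantomSpec, ground_truth_morphometry,
                                 make_calibration_phantom,
                                 make_terminal_unit_phantom)

from conftest import small_spec


class TestCalibrationPhantoms:
    def test_cuboid_exact_count(self):
        lv = make_calibration_phantom("cuboid", {"shape": (2, 1, 1)}, (8, 8, 8))
        assert int(lv.labels.sum()) == 2

    def test_tiny_sphere_single_voxel(self):
        lv = make_calibration_phantom(
            "sphere", {"radius": 0.4, "center": (4, 4, 4)}, (9, 9, 9)
        )
        assert int(lv.labels.sum()) == 1
        assert lv.labels[4, 4, 4] == 1

    def test_sphere_count_matches_analytic_volume(self):
        # centre-inclusion count of an r=30 digitized sphere vs (4/3) pi r^3
        lv = make_calibration_phantom(
            "sphere", {"radius": 30.0, "center": (31, 31, 31)}, (63, 63, 63)
        )
        count = int(lv.labels.sum())
        analytic = 4.0 / 3.0 * math.pi * 30.0**3
        assert abs(count - analytic) / analytic < 0.02

    def test_impulse_and_errors(self):
        lv = make_calibration_phantom("impulse", {"position": (1, 2, 3)}, (4, 5, 6))
        assert int(lv.labels.sum()) == 1 and lv.labels[1, 2, 3] == 1
        with pytest.raises(ValueError, match="axis z"):
            make_calibration_phantom("cuboid", {"shape": (10, 1, 1)}, (4, 8, 8))
        with pytest.raises(ValueError, match="sphere|cuboid|cylinder"):
            make_calibration_phantom("pyramid", {}, (8, 8, 8))

    def test_determinism(self):
        a = make_calibration_phantom("sphere", {"radius": 5.5}, (16, 16, 16))
        b = make_calibration_phantom("sphere", {"radius": 5.5}, (16, 16, 16))
        assert np.array_equal(a.labels, b.labels)


class TestFaceCountingBias:
    @pytest.mark.parametrize("radius", [20, 25, 30])
    def test_sphere_face_count_ratio_near_three_halves(self, radius):
        # 6-neighbour faces estimate the integral of |nx|+|ny|+|nz| whose
        # spherical mean is 3/2: the ratio to 4 pi r^2 must sit in [1.4, 1.6]
        n = 2 * radius + 5
        c = (n - 1) / 2.0
        lv = make_calibration_phantom(
            "sphere", {"radius": radius, "center": (c, c, c)}, (n, n, n)
        )
        S = surface_area(lv.labels.astype(bool), 1.0)
        ratio = S / (4 * math.pi * radius**2)
        assert 1.40 <= ratio <= 1.60


class TestTerminalUnitPhantom:
    def test_symmetric_daughters_give_equal_ground_truth(self):
        spec = small_spec(
            daughter1_semiaxes_um=(30.0, 25.0, 25.0),
            daughter2_semiaxes_um=(30.0, 25.0, 25.0),
            mouth1_radius_um=16.0, mouth2_radius_um=16.0,
            wall_bumpiness=0.0,
        )
        rec = ground_truth_morphometry(spec)
        assert rec.d1_um == rec.d2_um
        assert rec.S1_um2 == pytest.approx(rec.S2_um2, rel=0.02)
        assert rec.V1_nL == pytest.approx(rec.V2_nL, rel=0.02)

    def test_seed_determinism_and_bump_variation(self):
        spec = small_spec(rng_seed=4)
        lv_a, gt_a, _ = make_terminal_unit_phantom(spec)
        lv_b, gt_b, _ = make_terminal_unit_phantom(small_spec(rng_seed=4))
        assert np.array_equal(lv_a.labels, lv_b.labels)
        assert gt_a.record == gt_b.record
        lv_c, _, _ = make_terminal_unit_phantom(small_spec(rng_seed=5))
        assert not np.array_equal(lv_a.labels, lv_c.labels)

    def test_mouth_radii_define_ground_truth_diameters(self):
        # circular mouths: both axes equal the diameter, geometric mean too
        spec = PhantomSpec(
            grid_shape=(160, 144, 168),
            mother_radius_um=45.0,
            daughter1_semiaxes_um=(60.0, 50.0, 50.0),
            daughter2_semiaxes_um=(50.0, 42.0, 42.0),
            mouth1_radius_um=40.0, mouth2_radius_um=30.0,
        )
        rec = ground_truth_morphometry(spec, refine=2)
        assert rec.d1_um == 80.0
        assert rec.d2_um == 60.0

    def test_ground_truth_positive_and_ordered(self, unit128):
        _, _, gt, _, _ = unit128
        r = gt.record
        assert r.d1_um >= r.d2_um
        for v in (r.d0_um, r.d1_um, r.d2_um, r.S1_um2, r.S2_um2, r.V1_nL, r.V2_nL):
            assert v > 0

    def test_labels_disjoint_and_connected(self, unit128):
        _, lv, _, _, _ = unit128
        lv.validate()  # raises if labels overlap or regions are disconnected

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="semiaxis"):
            small_spec(mouth1_radius_um=40.0).validate()
        with pytest.raises(ValueError, match="bifurcation_angle"):
            small_spec(bifurcation_angle_deg=200.0).validate()
        with pytest.raises(ValueError, match="fit"):
            small_spec(daughter1_semiaxes_um=(80.0, 70.0, 70.0)).validate()


class TestOracle:
    def test_spherical_sac_volume_is_one_nanoliter(self):
        # (4/3) pi (62.04 um)^3 ~ 1e6 um^3 = 1 nL
        spec = PhantomSpec(
            grid_shape=(176, 160, 192),
            mother_radius_um=40.0,
            daughter1_semiaxes_um=(62.04, 62.04, 62.04),
            daughter2_semiaxes_um=(34.0, 28.0, 28.0),
            mouth1_radius_um=18.0, mouth2_radius_um=14.0,
            wall_bumpiness=0.0,
        )
        rec = ground_truth_morphometry(spec, refine=2)
        assert rec.V1_nL == pytest.approx(1.000, rel=0.02)
        # face-counting oracle carries the ~3/2 smooth-surface bias
        assert rec.S1_um2 / (4 * math.pi * 62.04**2) == pytest.approx(1.5, rel=0.03)

    def test_similarity_scaling(self):
        spec = small_spec(wall_bumpiness=0.0)
        rec = ground_truth_morphometry(spec, refine=2)
        doubled = PhantomSpec.from_dict({
            **spec.to_dict(),
            **{k: 2 * getattr(spec, k) for k in (
                "mother_radius_um", "mother_length_um", "mouth1_radius_um",
                "mouth2_radius_um", "voxel_size_um", "neck_length_um",
                "septum_gap_um", "bump_correlation_um", "mouth_taper_um")},
            "daughter1_semiaxes_um": tuple(2 * a for a in spec.daughter1_semiaxes_um),
            "daughter2_semiaxes_um": tuple(2 * a for a in spec.daughter2_semiaxes_um),
        })
        rec2 = ground_truth_morphometry(doubled, refine=2)
        assert rec2.d0_um == pytest.approx(2 * rec.d0_um, rel=1e-9)
        assert rec2.V1_nL == pytest.approx(8 * rec.V1_nL, rel=1e-3)
        assert rec2.V2_nL == pytest.approx(8 * rec.V2_nL, rel=1e-3)
        assert rec2.S1_um2 == pytest.approx(4 * rec.S1_um2, rel=1e-3)
        assert rec2.S2_um2 == pytest.approx(4 * rec.S2_um2, rel=1e-3)

    def test_refinement_convergence(self):
        spec = small_spec()
        a = ground_truth_morphometry(spec, refine=4)
        b = ground_truth_morphometry(spec, refine=8)
        for k in ("S1_um2", "S2_um2", "V1_nL", "V2_nL"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), rel=0.02)

    def test_coarse_labels_match_oracle_volumes(self, unit128):
        spec, lv, gt, _, _ = unit128
        h = spec.voxel_size_um
        v1 = region_volume(lv.labels == 2, h)
        v2 = region_volume(lv.labels == 3, h)
        assert v1 == pytest.approx(gt.record.V1_nL, rel=0.02)
        assert v2 == pytest.approx(gt.record.V2_nL, rel=0.02)
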