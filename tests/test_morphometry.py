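"""Diameters, face-counting surface areas, voxel volumes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acinomorph.extraction import extract_terminal_unit
from acinomorph.morphometry import (MorphometryRecord, count_exposed_faces,
                                    measure_unit, mouth_axes, mouth_diameter,
                                    region_volume, round_sig, surface_area)


class TestMouthAxes:
    def test_digitized_circle_recovers_diameter(self):
        # ring of a 60 um diameter circle snapped to the 1.74 um grid
        h, r = 1.74, 30.0
        phi = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.stack([np.zeros_like(phi), r * np.sin(phi), r * np.cos(phi)], axis=1)
        pts = np.round(pts / h) * h
        lo, sh = mouth_axes(pts, normal=(1.0, 0.0, 0.0))
        assert abs(lo - 60.0) <= h
        assert abs(sh - 60.0) <= h

    def test_rectangle_long_axis_is_diagonal(self):
        # 80 x 45 rectangle: long axis = its diagonal (the maximal chord),
        # short axis = extent perpendicular to that chord
        pts = np.array([
            [0.0, 0.0, 0.0], [0.0, 0.0, 80.0], [0.0, 45.0, 80.0], [0.0, 45.0, 0.0],
        ])
        lo, sh = mouth_axes(pts, normal=(1.0, 0.0, 0.0))
        diag = math.hypot(80.0, 45.0)
        assert lo == pytest.approx(diag, abs=1e-9)          # ~91.79
        assert sh == pytest.approx(2 * 80 * 45 / diag, abs=1e-9)  # ~78.44

    def test_degenerate_rings_rejected(self):
        same = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate|identical"):
            mouth_axes(same)
        collinear = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], dtype=float)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            mouth_axes(collinear)


class TestMouthDiameter:
    def test_examples(self):
        assert mouth_diameter(60.0, 60.0) == 60.0
        assert mouth_diameter(80.0, 45.0) == pytest.approx(60.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1.0, 500.0), st.floats(1.0, 500.0))
    def test_symmetric_and_bounded(self, a, b):
        d = mouth_diameter(a, b)
        assert d == pytest.approx(mouth_diameter(b, a))
        assert min(a, b) <= d <= max(a, b)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1.0, 100.0), st.floats(1.0, 100.0), st.floats(1.01, 2.0))
    def test_strictly_monotone(self, a, b, f):
        assert mouth_diameter(a * f, b) > mouth_diameter(a, b)
        assert mouth_diameter(a, b * f) > mouth_diameter(a, b)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mouth_diameter(0.0, 5.0)


class TestSurfaceAndVolume:
    def test_single_voxel(self):
        region = np.zeros((3, 3, 3), bool); region[1, 1, 1] = True
        assert surface_area(region, 1.74) == pytest.approx(6 * 1.74**2)  # 18.1656
        assert region_volume(region, 1.74) == pytest.approx(1.74**3 / 1e6)  # 5.268024e-6 nL

    def test_two_voxel_block(self):
        region = np.zeros((3, 3, 4), bool); region[1, 1, 1:3] = True
        assert surface_area(region, 1.74) == pytest.approx(10 * 1.74**2)  # 30.276

    @pytest.mark.parametrize("abc", [(1, 1, 1), (2, 1, 1), (3, 4, 5), (7, 2, 9)])
    def test_cuboid_closed_forms(self, abc):
        a, b, c = abc
        h = 1.74
        region = np.zeros((a + 2, b + 2, c + 2), bool)
        region[1:a + 1, 1:b + 1, 1:c + 1] = True
        assert surface_area(region, h) == pytest.approx(2 * (a * b + b * c + c * a) * h**2)
        assert region_volume(region, h) == pytest.approx(a * b * c * h**3 / 1e6)

    def test_volume_linearity(self):
        region = np.zeros((12, 12, 12), bool)
        rng = np.random.default_rng(0)
        region.flat[rng.choice(region.size, size=1000, replace=False)] = True
        assert region_volume(region, 1.74) == pytest.approx(1000 * 1.74**3 / 1e6)

    def test_border_faces_count_as_exposed(self):
        region = np.ones((2, 2, 2), bool)  # fills the whole array
        assert count_exposed_faces(region) == 24

    def test_sphere_face_count_bias(self):
        r, n = 30, 65
        c = (n - 1) / 2.0
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        region = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r * r
        h = 1.74
        ratio = surface_area(region, h) / (4 * math.pi * (r * h) ** 2)
        assert 1.40 <= ratio <= 1.60

    def test_digitized_sphere_one_nanoliter(self):
        # r = 62.04 um at 1.74 um voxels: V ~ 1e6 um^3 = 1 nL
        h = 1.74
        r_vox = 62.04 / h
        n = 75
        c = (n - 1) / 2.0
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        region = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r_vox**2
        assert region_volume(region, h) == pytest.approx(1.000, rel=0.02)

    def test_surface_additivity_across_a_cut(self):
        # S(A) + S(B) = S(A u B) + 2 * interface faces * h^2
        rng = np.random.default_rng(3)
        blob = rng.random((10, 10, 10)) > 0.4
        A = blob.copy(); A[5:] = False
        B = blob.copy(); B[:5] = False
        interface = int((blob[4] & blob[5]).sum())
        h = 1.74
        assert surface_area(A, h) + surface_area(B, h) == pytest.approx(
            surface_area(blob, h) + 2 * interface * h**2
        )

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            surface_area(np.zeros((3, 3, 3), bool), 1.0)
        with pytest.raises(ValueError, match="empty"):
            region_volume(np.zeros((3, 3, 3), bool), 1.0)


class TestMeasureUnit:
    def test_recovery_against_oracle_on_truth_mask(self, unit96):
        _, _, gt, ann, mask = unit96
        unit = extract_terminal_unit(mask, ann)
        rec = measure_unit(unit, "u")
        g = gt.record
        for k in ("d0_um", "d1_um", "d2_um", "V1_nL", "V2_nL", "S1_um2", "S2_um2"):
            assert getattr(rec, k) == pytest.approx(getattr(g, k), rel=0.05), k

    def test_symmetric_unit_measures_equal(self):
        from acinomorph.phantoms import (boundary_mask_from_labels,
                                         make_terminal_unit_phantom)
        from conftest import small_spec

        spec = small_spec(
            daughter1_semiaxes_um=(30.0, 25.0, 25.0),
            daughter2_semiaxes_um=(30.0, 25.0, 25.0),
            mouth1_radius_um=16.0, mouth2_radius_um=16.0,
            wall_bumpiness=0.0,
        )
        lv, _, ann = make_terminal_unit_phantom(spec)
        unit = extract_terminal_unit(boundary_mask_from_labels(lv), ann)
        rec = measure_unit(unit, "sym")
        assert rec.d1_um == pytest.approx(rec.d2_um, rel=0.02)
        assert rec.S1_um2 == pytest.approx(rec.S2_um2, rel=0.02)
        assert rec.V1_nL == pytest.approx(rec.V2_nL, rel=0.02)

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="positive"):
            MorphometryRecord("u", -1, 2, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError, match="major/minor"):
            MorphometryRecord("u", 10, 5, 8, 1, 1, 1, 1)

    def test_sig_fig_export(self):
        assert round_sig(91.787, 3) == 91.8
        assert round_sig(0.030456, 3) == 0.0305
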