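"""Dice, volumetry, geometric models, Macdonald measures, study reports."""

import math

import numpy as np
import pytest

from growcutvol.core import ImageGeometry, LabelMap
from growcutvol.datasets import pituitary_adenoma_cases
from growcutvol.metrics import (
    GeometricMeasures,
    compare_pair,
    dice,
    geometric_volume,
    label_volume,
    macdonald_area,
    macdonald_response,
    study_report,
    summarize,
)

from conftest import binary_map


def shifted_cubes():
    a = np.zeros((8, 8, 8), dtype=np.int16)
    a[0:4, 0:4, 0:4] = 1
    b = np.zeros((8, 8, 8), dtype=np.int16)
    b[0:4, 0:4, 2:6] = 1
    return binary_map(a), binary_map(b)


class TestDice:
    def test_identical_masks(self):
        a, _ = shifted_cubes()
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4), dtype=np.int16)
        b[3, 3, 3] = 1
        assert dice(binary_map(a), binary_map(b)) == 0.0

    def test_shifted_cube_half_overlap(self):
        a, b = shifted_cubes()
        assert dice(a, b) == 0.5  # |A|=|B|=64, |A∩B|=32

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = binary_map(rng.random((6, 6, 6)) < 0.4)
            b = binary_map(rng.random((6, 6, 6)) < 0.4)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_empty_vs_empty_defined_as_one(self):
        z = binary_map(np.zeros((3, 3, 3), dtype=np.int16))
        assert dice(z, z) == 1.0

    def test_geometry_mismatch_raises(self):
        a = binary_map(np.zeros((3, 3, 3), dtype=np.int16))
        b = binary_map(np.zeros((4, 4, 4), dtype=np.int16))
        with pytest.raises(ValueError):
            dice(a, b)

    def test_strictly_decreasing_as_overlap_shrinks(self):
        """Moving one mask voxel-by-voxel off the other lowers the DSC."""
        base = np.zeros((10, 4, 4), dtype=np.int16)
        base[0:4] = 1
        prev = None
        for shift in range(5):
            other = np.roll(base, shift, axis=0)
            d = dice(binary_map(base), binary_map(other))
            if prev is not None:
                assert d < prev
            prev = d


class TestLabelVolume:
    def test_unit_spacing(self):
        arr = np.zeros((10, 10, 10), dtype=np.int16)
        arr.ravel()[:1000] = 1
        assert label_volume(binary_map(arr)) == (1000, 1000.0)

    def test_anisotropic_spacing(self):
        arr = np.zeros((30, 30, 30), dtype=np.int16)
        arr.ravel()[:5162] = 1
        voxels, vol = label_volume(binary_map(arr, spacing=(0.5, 0.5, 0.6)))
        assert voxels == 5162
        assert vol == pytest.approx(774.3)

    def test_empty_mask(self):
        assert label_volume(binary_map(np.zeros((3, 3, 3), np.int16))) == (0, 0.0)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="label"):
            label_volume(binary_map(np.zeros((3, 3, 3), np.int16)), label=9)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(8)
        arr = (rng.random((6, 6, 6)) < 0.5).astype(np.int16)
        a = arr.copy()
        a[3:] = 0
        b = arr - a
        va = label_volume(binary_map(a))[1]
        vb = label_volume(binary_map(b))[1]
        assert va + vb == pytest.approx(label_volume(binary_map(arr))[1])


class TestSummarize:
    def test_study_dsc_column(self):
        """The ten published DSC values give 75.60/85.87/81.97/3.39."""
        dscs = [r.dsc_percent for r in pituitary_adenoma_cases()]
        s = summarize(dscs)
        assert round(s.min, 2) == 75.60
        assert round(s.max, 2) == 85.87
        assert round(s.mean, 2) == 81.97
        assert round(s.std, 2) == 3.39

    def test_constant_list(self):
        s = summarize([5, 5, 5])
        assert (s.min, s.max, s.mean, s.std) == (5, 5, 5, 0)

    def test_sample_std_uses_nminus1(self):
        s = summarize([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.std == pytest.approx(math.sqrt(5 / 3), abs=1e-5)  # ≈1.29099

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_single_value_has_no_std(self):
        assert summarize([3.0]).std is None


class TestGeometricVolume:
    def test_spherical_closed_form(self):
        v = geometric_volume(GeometricMeasures(d=2.0), "spherical")
        assert v == pytest.approx(4 * math.pi / 3)

    def test_ellipsoid_reduces_to_sphere(self):
        for d in (1.0, 3.7, 20.0):
            sph = geometric_volume(GeometricMeasures(d=d), "spherical")
            ell = geometric_volume(GeometricMeasures(a=d, b=d, c=d), "ellipsoid")
            assert ell == pytest.approx(sph)

    def test_mean_radius_unit(self):
        g = GeometricMeasures.from_radii(1.0, 1.0, 1.0)
        assert geometric_volume(g, "mean_radius") == pytest.approx(4 * math.pi / 3)

    def test_caliper_formula(self):
        assert geometric_volume(GeometricMeasures(a=4, b=2), "caliper") == 8.0

    def test_missing_measure_raises(self):
        with pytest.raises(ValueError, match="requires"):
            geometric_volume(GeometricMeasures(d=2.0), "ellipsoid")


def brute_force_bidimensional(mask, spacing):
    """Independent oracle: exhaustive pairwise loop over voxel centers."""
    pts = [
        (i * spacing[0], j * spacing[1])
        for i, j in zip(*np.nonzero(mask))
    ]
    best, pair = 0.0, None
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            if d > best:
                best, pair = d, (pts[i], pts[j])
    if pair is None or best == 0:
        return float(np.mean(spacing)) ** 2
    ux = (pair[1][0] - pair[0][0]) / best
    uy = (pair[1][1] - pair[0][1]) / best
    proj = [-uy * x + ux * y for x, y in pts]
    perp = max(proj) - min(proj)
    if perp == 0:
        perp = float(np.mean(spacing))
    return best * perp


class TestMacdonald:
    def test_single_voxel_convention(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert macdonald_area(m, (1.0, 1.0)) == 1.0

    def test_rectangle_matches_brute_force_oracle(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 10:20] = True  # 20 × 10 mm filled rectangle
        assert macdonald_area(m, (1.0, 1.0)) == pytest.approx(
            brute_force_bidimensional(m, (1.0, 1.0))
        )

    def test_disk_close_to_analytic(self):
        """Rasterized 20 mm disk: d·d_perp ≈ 400 mm² within 5 %."""
        ii, jj = np.mgrid[0:25, 0:25]
        m = (ii - 12.0) ** 2 + (jj - 12.0) ** 2 < 10.0**2
        area = macdonald_area(m, (1.0, 1.0))
        assert area == pytest.approx(400.0, rel=0.05)

    def test_empty_slice_raises(self):
        with pytest.raises(ValueError, match="empty"):
            macdonald_area(np.zeros((4, 4), dtype=bool))

    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [(100, 50, True), (100, 51, False), (100, 0, True)],
    )
    def test_response_rule_boundary_inclusive(self, baseline, followup, expected):
        assert macdonald_response(baseline, followup) is expected

    def test_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            macdonald_response(0, 0)


class TestComparePairAndReport:
    def test_identical_masks_full_agreement(self):
        a, _ = shifted_cubes()
        rec = compare_pair(a, a, "x")
        assert rec.dsc_percent == 100.0
        assert rec.volume_manual_mm3 == rec.volume_auto_mm3
        assert rec.voxels_manual == rec.voxels_auto

    def test_shifted_cube_record(self):
        a, b = shifted_cubes()
        rec = compare_pair(a, b, "shifted")
        assert rec.dsc_percent == 50.0
        assert rec.voxels_manual == 64 and rec.voxels_auto == 64

    def test_study_report_reproduces_published_summary(self):
        """Feeding the ten published per-case rows reproduces every printed
        summary cell: 6.37±3.96 / 6.47±4.14 cm³, voxel means 48082.1 /
        48056.9, DSC 81.97±3.39 with range 75.60–85.87."""
        table, summary = study_report(pituitary_adenoma_cases())
        assert len(table) == 10
        v = summary.volume_manual_cm3
        assert (round(v.min, 2), round(v.max, 2)) == (0.76, 15.27)
        assert (round(v.mean, 2), round(v.std, 2)) == (6.37, 3.96)
        v = summary.volume_auto_cm3
        assert (round(v.mean, 2), round(v.std, 2)) == (6.47, 4.14)
        assert round(summary.voxels_manual.mean, 1) == 48082.1
        assert round(summary.voxels_auto.mean, 1) == 48056.9
        assert summary.voxels_manual.std is None
        d = summary.dsc_percent
        assert (round(d.min, 2), round(d.max, 2)) == (75.60, 85.87)
        assert (round(d.mean, 2), round(d.std, 2)) == (81.97, 3.39)

    def test_identical_records_zero_spread(self):
        recs = pituitary_adenoma_cases()[:1] * 10
        _, summary = study_report(recs)
        s = summary.dsc_percent
        assert s.std == 0 and s.min == s.max == s.mean

    def test_two_point_summary(self):
        recs = [r for r in pituitary_adenoma_cases()[:2]]
        recs[0] = type(recs[0])(
            case_id="a", volume_manual_mm3=1, volume_auto_mm3=1,
            voxels_manual=1, voxels_auto=1, dsc_percent=60.0,
        )
        recs[1] = type(recs[1])(
            case_id="b", volume_manual_mm3=1, volume_auto_mm3=1,
            voxels_manual=1, voxels_auto=1, dsc_percent=80.0,
        )
        _, summary = study_report(recs)
        assert summary.dsc_percent.mean == 70.0
        assert summary.dsc_percent.std == pytest.approx(14.142, abs=1e-3)

    def test_fewer_than_two_records_raises(self):
        with pytest.raises(ValueError):
            study_report(pituitary_adenoma_cases()[:1])
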