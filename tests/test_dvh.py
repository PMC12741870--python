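"""DVH reconstruction, objectives and percentile bands against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oartx import (
    ObjectiveSpec,
    band,
    build_dvh,
    dose_at_volume,
    parse_objective,
    volume_at_dose,
)
from oartx.dvh import dvh_from_csv, dvh_to_csv
from oartx.errors import DomainError, EmptyDVHError

from conftest import random_truncated_curve


# --- independent oracles ---------------------------------------------------

def oracle_volume(points, dose):
    """Nearest-segment linear evaluation written independently of the package."""
    pts = sorted((float(d), float(v)) for d, v in points)
    if dose < pts[0][0]:
        return 100.0
    if dose > pts[-1][0]:
        return 0.0
    for (d0, v0), (d1, v1) in zip(pts, pts[1:]):
        if d0 <= dose <= d1:
            if d1 == d0:
                return max(v0, v1)
            return v0 + (v1 - v0) * (dose - d0) / (d1 - d0)
    return pts[-1][1]


def oracle_dose(points, volume):
    """Segment-by-segment inversion: collect every dose where the curve first
    reaches <= target on each segment, then take the smallest."""
    pts = sorted((float(d), float(v)) for d, v in points)
    if volume >= 100.0:
        return 0.0
    candidates = [d for d, v in pts if v <= volume]
    for (da, va), (db, vb) in zip(pts, pts[1:]):
        if va > volume >= vb and va != vb:
            candidates.append(da + (va - volume) * (db - da) / (va - vb))
    if not candidates:
        return pts[-1][0]
    return min(candidates)


# --- padding and interpolation --------------------------------------------

class TestPadding:
    def test_worked_example(self):
        dvh = build_dvh([(10, 80), (20, 20)])
        assert volume_at_dose(dvh, 5) == 100.0
        assert volume_at_dose(dvh, 25) == 0.0
        assert volume_at_dose(dvh, 15) == pytest.approx(50.0)

    def test_padding_is_exact_on_random_curves(self):
        """Below/above the listed range the padding is exactly 100 / exactly 0."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pts = random_truncated_curve(rng)
            dvh = build_dvh(pts)
            below = max(0.0, pts[0, 0] - rng.uniform(0.001, 5.0))
            above = pts[-1, 0] + rng.uniform(0.001, 5.0)
            if below < pts[0, 0]:
                assert volume_at_dose(dvh, below) == 100.0
            assert volume_at_dose(dvh, above) == 0.0

    def test_node_identity_and_monotonicity(self):
        rng = np.random.default_rng(7)
        pts = random_truncated_curve(rng)
        dvh = build_dvh(pts)
        for d, v in pts:
            assert volume_at_dose(dvh, d) == pytest.approx(v, abs=1e-12)
        grid = np.linspace(0, pts[-1, 0] + 5, 400)
        vals = np.asarray(volume_at_dose(dvh, grid))
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals >= 0) & (vals <= 100))


class TestBuildDvh:
    def test_empty_rejected(self):
        with pytest.raises(EmptyDVHError):
            build_dvh([])

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            build_dvh([(-1, 50)])

    def test_duplicates_collapse_keeping_max(self):
        dvh = build_dvh([(10, 40), (10, 60), (20, 10)])
        assert volume_at_dose(dvh, 10) == 60.0

    def test_nonmonotone_repaired_with_running_min(self, caplog):
        dvh = build_dvh([(5, 50), (10, 70), (20, 10)])
        assert volume_at_dose(dvh, 10) == 50.0
        assert np.all(np.diff(dvh.volumes) <= 0)

    def test_volumes_clipped(self):
        dvh = build_dvh([(1, 120), (2, -5)])
        assert dvh.volumes.max() == 100.0 and dvh.volumes.min() == 0.0


# --- oracle equivalence ----------------------------------------------------

def test_volume_at_dose_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        pts = random_truncated_curve(rng)
        dvh = build_dvh(pts)
        for dose in rng.uniform(0, pts[-1, 0] + 3, size=20):
            assert volume_at_dose(dvh, dose) == pytest.approx(
                oracle_volume(pts, dose), abs=1e-9
            )


def test_dose_at_volume_inverse_of_strict_segments():
    dvh = build_dvh([(10, 80), (20, 20)])
    assert dose_at_volume(dvh, 50) == pytest.approx(15.0, abs=1e-6)
    assert dose_at_volume(dvh, 100) == 0.0
    rng = np.random.default_rng(1)
    for _ in range(100):
        pts = random_truncated_curve(rng)
        dvh = build_dvh(pts)
        # composition on strictly decreasing interior values
        for v in rng.uniform(dvh.volumes.min(), dvh.volumes.max(), size=10):
            d = dose_at_volume(dvh, v)
            assert volume_at_dose(dvh, d) == pytest.approx(v, abs=1e-6)


def test_dose_at_volume_matches_segment_inversion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        pts = random_truncated_curve(rng)
        dvh = build_dvh(pts)
        for v in rng.uniform(0, 100, size=20):
            assert dose_at_volume(dvh, v) == pytest.approx(
                oracle_dose(dvh.points, v), abs=1e-6
            )


def test_dose_at_volume_flat_segment_left_endpoint():
    dvh = build_dvh([(5, 80), (10, 50), (15, 50), (20, 10)])
    assert dose_at_volume(dvh, 50) == pytest.approx(10.0)


@given(st.floats(min_value=-10, max_value=-0.01))
@settings(max_examples=20, deadline=None)
def test_negative_query_dose_rejected(dose):
    dvh = build_dvh([(10, 80), (20, 20)])
    with pytest.raises(DomainError):
        volume_at_dose(dvh, dose)


# --- bands ------------------------------------------------------------------

class TestBand:
    def test_single_curve_degenerate(self):
        dvh = build_dvh([(10, 80), (20, 20)])
        b = band([dvh], grid_step=0.5)
        for arr in (b.lo, b.p20, b.median, b.p80):
            np.testing.assert_allclose(arr, b.hi)

    def test_identical_curves_zero_width(self):
        dvh = build_dvh([(10, 80), (20, 20)])
        b = band([dvh] * 20, grid_step=1.0)
        np.testing.assert_allclose(b.lo, b.hi)

    def test_band_equals_per_point_percentiles(self):
        rng = np.random.default_rng(3)
        curves = [build_dvh(random_truncated_curve(rng)) for _ in range(15)]
        b = band(curves, grid_step=0.7)
        values = np.vstack([[oracle_volume(c.points, d) for d in b.grid] for c in curves])
        np.testing.assert_allclose(b.lo, values.min(axis=0), atol=1e-9)
        np.testing.assert_allclose(b.p20, np.percentile(values, 20, axis=0), atol=1e-9)
        np.testing.assert_allclose(b.median, np.percentile(values, 50, axis=0), atol=1e-9)
        np.testing.assert_allclose(b.p80, np.percentile(values, 80, axis=0), atol=1e-9)
        np.testing.assert_allclose(b.hi, values.max(axis=0), atol=1e-9)

    def test_ordering_invariant_many_random_families(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            curves = [build_dvh(random_truncated_curve(rng)) for _ in range(5)]
            b = band(curves, grid_step=2.0)
            assert np.all(b.lo <= b.p20 + 1e-12)
            assert np.all(b.p20 <= b.median + 1e-12)
            assert np.all(b.median <= b.p80 + 1e-12)
            assert np.all(b.p80 <= b.hi + 1e-12)

    def test_grid_spans_one_step_past_max_dose(self):
        dvh = build_dvh([(10, 80), (20, 20)])
        b = band([dvh], grid_step=0.5)
        assert b.grid[0] == 0.0
        assert b.grid[-1] >= dvh.max_dose
        assert b.grid[-1] - dvh.max_dose <= 0.5 + 1e-12


# --- objective parsing and CSV interop -------------------------------------

def test_parse_objective_strings():
    spec = parse_objective("V42.5Gy@Rectum")
    assert (spec.kind, spec.threshold, spec.structure) == ("V_at_dose", 42.5, "Rectum")
    spec = parse_objective("D2%@PTV_High")
    assert (spec.kind, spec.threshold, spec.structure) == ("D_at_volume", 2.0, "PTV_High")
    with pytest.raises(DomainError):
        parse_objective("X5@Y")


def test_objective_spec_validation():
    with pytest.raises(DomainError):
        ObjectiveSpec("D_at_volume", 150.0, "Rectum")
    with pytest.raises(DomainError):
        ObjectiveSpec("V_at_dose", -1.0, "Rectum")


def test_dvh_csv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    data = {
        "tpms": {"Bladder": build_dvh(random_truncated_curve(rng))},
        "secondary": {"Bladder": build_dvh(random_truncated_curve(rng))},
    }
    path = tmp_path / "dvh.csv"
    dvh_to_csv(data, path)
    back = dvh_from_csv(path)
    for src in data:
        np.testing.assert_allclose(back[src]["Bladder"].doses, data[src]["Bladder"].doses)
        np.testing.assert_allclose(back[src]["Bladder"].volumes, data[src]["Bladder"].volumes)
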