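"""Volumetric response classification, growth patterns, threshold
derivation and the cohort summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icbrad import (
    Category,
    GrowthPattern,
    ResponseCriteriaConfig,
    VolumeTrajectory,
    bidimensional_product,
    classify_growth_pattern,
    classify_response,
    fisher_exact_2x2,
    planumetric_to_volumetric_threshold,
    relative_change,
    summarize_cohort,
    volumetric_threshold_percent,
)
from icbrad.response import (
    classify_cohort,
    response_rate,
    volumetric_to_planumetric_threshold,
)


def traj(v1, v2, v3, arm="ICB", animal_id="a"):
    return VolumeTrajectory(animal_id=animal_id, v1=v1, v2=v2, v3=v3, arm=arm)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "v_from,v_to,expected", [(10, 0, -100.0), (10, 10, 0.0), (10, 14, 40.0)]
    )
    def test_values(self, v_from, v_to, expected):
        assert relative_change(v_from, v_to) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 5.0)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "v,expected,responder,rescued",
        [
            ((10, 12, 0), Category.CR, True, False),    # total regression
            ((10, 8, 3), Category.PR, True, False),     # −70% from baseline
            ((10, 20, 14), Category.SD, True, True),    # pseudoprogression rescue
            ((10, 20, 15), Category.PD, False, False),  # +50%, only −25% regression
            ((10, 10, 10), Category.SD, True, False),
            ((10, 40, 5), Category.PR, True, False),    # %V32 = −87.5 route to PR
        ],
    )
    def test_categories(self, v, expected, responder, rescued):
        call = classify_response(traj(*v))
        assert call.category is expected
        assert call.responder is responder
        assert call.pseudoprogression_rescued is rescued

    @pytest.mark.parametrize(
        "v,expected",
        [
            ((10, 10, 3.5), Category.PR),   # %V31 = −65.0 exactly → PR
            ((10, 20, 14.0), Category.SD),  # %V31 = +40 and %V32 = −30 → rescued
            ((10, 10, 14.0), Category.PD),  # %V31 = +40 exactly, no rescue
            ((10, 10, 13.999), Category.SD),
            ((10, 10, 3.501), Category.SD),
        ],
    )
    def test_threshold_boundaries(self, v, expected):
        assert classify_response(traj(*v)).category is expected

    def test_regrowth_after_complete_response_uses_v31_only(self):
        call = classify_response(traj(10, 0, 2))
        assert call.category is Category.PR  # −80% from baseline
        assert call.growth_pattern is GrowthPattern.INDETERMINATE
        assert call.pct_v32 is None

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            traj(0, 1, 1)
        with pytest.raises(ValueError):
            traj(10, -1, 1)
        with pytest.raises(ValueError):
            traj(10, math.inf, 1)

    @given(
        v2=st.floats(0.1, 100),
        v3a=st.floats(0, 200),
        v3b=st.floats(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_final_volume(self, v2, v3a, v3b):
        """Shrinking the final volume never worsens the category."""
        order = {Category.PD: 0, Category.SD: 1, Category.PR: 2, Category.CR: 3}
        lo, hi = sorted((v3a, v3b))
        better = classify_response(traj(10, v2, lo)).category
        worse = classify_response(traj(10, v2, hi)).category
        assert order[better] >= order[worse]


class TestGrowthPattern:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ((10, 12, 8), GrowthPattern.G2),
            ((10, 8, 6), GrowthPattern.G1),
            ((10, 8, 9), GrowthPattern.G4),
            ((10, 12, 15), GrowthPattern.G3),
            ((10, 10, 10), GrowthPattern.G1),  # zero change → non-growth branch
        ],
    )
    def test_sign_patterns(self, v, expected):
        assert classify_growth_pattern(traj(*v)) is expected

    def test_strict_mode_flags_zero_change(self):
        assert (classify_growth_pattern(traj(10, 10, 8), strict=True)
                is GrowthPattern.INDETERMINATE)

    def test_regrowth_from_zero_is_an_error(self):
        with pytest.raises(ValueError):
            classify_growth_pattern(traj(10, 0, 2))


class TestThresholdDerivation:
    def test_identity(self):
        assert planumetric_to_volumetric_threshold(0.0) == 0.0

    def test_rano_pd_conversion(self):
        assert planumetric_to_volumetric_threshold(0.25) == pytest.approx(
            1.25 ** 1.5 - 1, abs=1e-12
        )
        assert volumetric_threshold_percent(0.25) == 40.0

    def test_rano_pr_conversion(self):
        assert planumetric_to_volumetric_threshold(-0.5) == pytest.approx(
            0.5 ** 1.5 - 1, abs=1e-12
        )
        assert volumetric_threshold_percent(-0.5) == -65.0

    @given(st.floats(-0.99, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, a):
        v = planumetric_to_volumetric_threshold(a)
        assert volumetric_to_planumetric_threshold(v) == pytest.approx(a, abs=1e-12)

    def test_strictly_increasing(self):
        xs = np.linspace(-0.9, 2.0, 200)
        ys = [planumetric_to_volumetric_threshold(x) for x in xs]
        assert np.all(np.diff(ys) > 0)


def _brute_force_diameters(points: np.ndarray, px: float) -> float:
    """Oracle: product of the max pairwise center distance and the max
    extent perpendicular to it, over all point pairs."""
    d1 = 0.0
    u_best = None
    for i in range(len(points)):
        d = points - points[i]
        dist = np.hypot(d[:, 0], d[:, 1])
        j = int(np.argmax(dist))
        if dist[j] > d1:
            d1 = dist[j]
            u_best = (points[j] - points[i]) / dist[j]
    if u_best is None:
        return px * px
    v = np.array([-u_best[1], u_best[0]])
    proj = points @ v
    d2 = proj.max() - proj.min()
    if d2 == 0.0:
        d2 = px * (abs(v[0]) + abs(v[1]))
    return d1 * d2


class TestBidimensionalProduct:
    def test_sphere_matches_d_squared_and_oracle(self):
        sp = 1.0
        n = 27
        ax = (np.arange(n) - (n - 1) / 2.0) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = X ** 2 + Y ** 2 + Z ** 2 <= 10.0 ** 2
        area = bidimensional_product(mask, (sp, sp, sp))
        assert area == pytest.approx(400.0, rel=0.05)
        z = int(np.argmax(mask.sum(axis=(0, 1))))
        ii, jj = np.nonzero(mask[:, :, z])
        pts = np.column_stack([ii * sp, jj * sp]).astype(float)
        assert area == pytest.approx(_brute_force_diameters(pts, sp), rel=1e-6)

    def test_convergence_with_resolution(self):
        errs = []
        for sp in (1.0, 0.5):
            n = int(26 / sp) + 3
            ax = (np.arange(n) - (n - 1) / 2.0) * sp
            X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
            mask = X ** 2 + Y ** 2 + Z ** 2 <= 10.0 ** 2
            errs.append(abs(bidimensional_product(mask, (sp,) * 3) - 400.0))
        assert errs[1] <= errs[0] * 0.6 + 1e-9

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert bidimensional_product(mask, (1, 1, 1)) == pytest.approx(1.0)

    def test_axis_aligned_box_matches_oracle(self):
        mask = np.zeros((14, 8, 6), dtype=bool)
        mask[2:12, 2:6, 2:4] = True  # 10 x 4 x 2 mm
        ii, jj = np.nonzero(mask[:, :, 2])
        pts = np.column_stack([ii, jj]).astype(float)
        expected = _brute_force_diameters(pts, 1.0)
        assert bidimensional_product(mask, (1, 1, 1)) == pytest.approx(expected, rel=1e-9)
        # bracketed by the axis-extent product and the squared diagonal
        assert 27.0 <= expected <= (9 ** 2 + 3 ** 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            bidimensional_product(np.zeros((3, 3, 3), bool), (1, 1, 1))


def _enumerate_fisher(table) -> float:
    """Oracle: sum hypergeometric point probabilities ≤ the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    p_obs = pmf(a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[1, 0], [0, 1]], 1.0),
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-7)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t = rng.integers(0, 13, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                _enumerate_fisher(t.tolist()), rel=1e-7, abs=1e-12
            )

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [0, 3]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [0, 3]])


class TestCohortSummary:
    def test_counts_rates_and_fisher(self):
        trajs = (
            [traj(10, 8, 2, arm="ICB", animal_id=f"i{k}") for k in range(3)]
            + [traj(10, 15, 20, arm="ICB", animal_id="i3")]
            + [traj(10, 8, 3, arm="C", animal_id="c0")]
            + [traj(10, 15, 20, arm="C", animal_id=f"c{k}") for k in range(1, 4)]
        )
        s = summarize_cohort(classify_cohort(trajs))
        assert s.n_per_arm == {"C": 4, "ICB": 4}
        for arm in s.n_per_arm:
            assert sum(s.category_counts[arm].values()) == s.n_per_arm[arm]
        assert s.response_rate["ICB"] == pytest.approx(75.0)
        assert s.response_rate["C"] == pytest.approx(25.0)
        assert s.fisher_p == pytest.approx(34 / 70, rel=1e-7)

    def test_all_responders(self):
        s = summarize_cohort(classify_cohort([traj(10, 8, 2, animal_id=str(k))
                                              for k in range(5)]))
        assert s.response_rate["ICB"] == 100.0
        assert s.fisher_p is None  # single arm

    def test_printed_cohort_rate(self):
        assert response_rate(101, 212) == pytest.approx(47.64, abs=0.005)
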