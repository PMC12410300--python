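"""Voxelwise GLM t-maps, thresholds and cluster extraction.

Oracles: per-voxel closed-form OLS / pooled-t scalar formulas computed
independently of the vectorized implementation, an independent
t-quantile by numerical CDF inversion, and a flood-fill connected-
component labeller.
"""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from petbloodnorm import (
    TMap,
    Volume,
    extract_clusters,
    regression_tmap,
    t_threshold,
    two_sample_tmap,
)

from conftest import full_mask


# ---------------------------------------------------------------------------
# scalar oracles


def ols_t_scalar(y, x):
    """Closed-form simple-regression t via the normal equations."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    ss_res = sum((yi - ybar - slope * (xi - xbar)) ** 2 for xi, yi in zip(x, y))
    se = math.sqrt(ss_res / (n - 2) / sxx)
    return slope / se if se > 0 else math.copysign(math.inf, slope) if slope else 0.0


def pooled_t_scalar(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    return (ma - mb) / se


def flood_fill_components(field, connectivity):
    """Connected components of a binary 3-D field by explicit flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or (
                    connectivity == 18 and order <= 2
                ) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    shape = field.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in np.argwhere(field):
        start = tuple(start)
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = set()
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= w[i] < shape[i] for i in range(3)) and field[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def _vols(arrays, voxel_mm=1.0):
    return [Volume(a.astype(float), (voxel_mm,) * 3, "Bq/mL") for a in arrays]


# ---------------------------------------------------------------------------
# regression t-map


class TestRegressionTMap:
    def test_constant_covariate_is_an_error(self):
        vols = _vols([np.ones((3, 3, 3)) * k for k in range(3)])
        with pytest.raises(ValueError, match="variance"):
            regression_tmap(vols, [2.0, 2.0, 2.0], full_mask((3, 3, 3)))

    def test_fewer_than_three_subjects_is_an_error(self):
        vols = _vols([np.ones((3, 3, 3))] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            regression_tmap(vols, [0.0, 1.0], full_mask((3, 3, 3)))

    def test_symmetric_values_give_zero_slope_and_zero_t(self):
        vols = _vols([np.full((2, 2, 2), v) for v in (1.0, 0.0, 1.0)])
        tmap = regression_tmap(vols, [-1.0, 0.0, 1.0], full_mask((2, 2, 2)))
        np.testing.assert_array_equal(tmap.t.values, 0.0)

    def test_matches_closed_form_oracle_voxelwise(self):
        rng = np.random.default_rng(10)
        n, shape = 5, (4, 4, 4)
        data = rng.normal(3.0, 1.0, (n, *shape))
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        tmap = regression_tmap(_vols(data), x, full_mask(shape))
        assert tmap.dof == 3
        for idx in np.ndindex(*shape):
            y = [data[i][idx] for i in range(n)]
            assert tmap.t.values[idx] == pytest.approx(ols_t_scalar(y, x), rel=1e-10)

    def test_example_linear_trend(self):
        # y = (1.0, 2.1, 2.9, 4.2, 4.8) against x = 1..5 at every voxel
        vals = [1.0, 2.1, 2.9, 4.2, 4.8]
        vols = _vols([np.full((2, 2, 2), v) for v in vals])
        tmap = regression_tmap(vols, [1, 2, 3, 4, 5], full_mask((2, 2, 2)))
        expected = ols_t_scalar(vals, [1, 2, 3, 4, 5])
        np.testing.assert_allclose(tmap.t.values, expected, rtol=1e-12)

    def test_equals_correlation_identity(self):
        # t = r * sqrt((n-2)/(1-r^2)) at every voxel
        rng = np.random.default_rng(11)
        n, shape = 8, (3, 3, 3)
        data = rng.normal(0, 1, (n, *shape))
        x = rng.normal(0, 1, n)
        tmap = regression_tmap(_vols(data), x, full_mask(shape))
        for idx in np.ndindex(*shape):
            y = np.array([data[i][idx] for i in range(n)])
            r = np.corrcoef(x, y)[0, 1]
            expected = r * math.sqrt((n - 2) / (1 - r * r))
            assert tmap.t.values[idx] == pytest.approx(expected, rel=1e-9)

    def test_perfect_fit_yields_signed_infinity(self):
        x = [1.0, 2.0, 3.0]
        vols = _vols([np.full((2, 2, 2), xi) for xi in x])
        tmap = regression_tmap(vols, x, full_mask((2, 2, 2)))
        assert np.all(np.isposinf(tmap.t.values))


# ---------------------------------------------------------------------------
# two-sample t-map


class TestTwoSampleTMap:
    def test_identical_groups_zero_everywhere(self):
        vols = _vols([np.full((3, 3, 3), 2.0)] * 2)
        tmap = two_sample_tmap(vols, vols, full_mask((3, 3, 3)))
        np.testing.assert_array_equal(tmap.t.values, 0.0)
        assert tmap.degenerate.all()

    def test_known_pooled_t_value(self):
        a = _vols([np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)])
        b = _vols([np.full((2, 2, 2), v) for v in (4.0, 5.0, 6.0)])
        tmap = two_sample_tmap(a, b, full_mask((2, 2, 2)))
        expected = pooled_t_scalar([1, 2, 3], [4, 5, 6])  # -3.6742...
        assert expected == pytest.approx(-3.67423, abs=1e-5)
        np.testing.assert_allclose(tmap.t.values, expected, rtol=1e-12)
        assert tmap.dof == 4

    def test_swapping_groups_negates_map(self):
        rng = np.random.default_rng(12)
        a = _vols(rng.normal(1, 1, (3, 2, 2, 2)))
        b = _vols(rng.normal(0, 1, (4, 2, 2, 2)))
        t_ab = two_sample_tmap(a, b, full_mask((2, 2, 2)))
        t_ba = two_sample_tmap(b, a, full_mask((2, 2, 2)))
        np.testing.assert_array_equal(t_ab.t.values, -t_ba.t.values)

    def test_matches_scalar_oracle_on_2v2(self):
        rng = np.random.default_rng(13)
        shape = (3, 3, 3)
        a = rng.normal(0, 1, (2, *shape))
        b = rng.normal(0.5, 1, (2, *shape))
        tmap = two_sample_tmap(_vols(a), _vols(b), full_mask(shape))
        for idx in np.ndindex(*shape):
            expected = pooled_t_scalar([a[i][idx] for i in range(2)], [b[i][idx] for i in range(2)])
            assert tmap.t.values[idx] == pytest.approx(expected, rel=1e-10)

    def test_single_subject_group_is_an_error(self):
        vols = _vols([np.ones((2, 2, 2))])
        with pytest.raises(ValueError):
            two_sample_tmap(vols, vols * 2, full_mask((2, 2, 2)))


# ---------------------------------------------------------------------------
# t thresholds


class TestTThreshold:
    def test_median_of_symmetric_distribution_is_zero(self):
        for dof in (1, 5, 50):
            assert t_threshold(0.5, dof, "one") == pytest.approx(0.0, abs=1e-12)

    def test_quantile_matches_numerical_cdf_inversion(self):
        # independent oracle: invert the integrated t density
        def t_pdf(x, v):
            return (
                math.gamma((v + 1) / 2)
                / (math.sqrt(v * math.pi) * math.gamma(v / 2))
                * (1 + x * x / v) ** (-(v + 1) / 2)
            )

        dof, p = 20, 0.005
        def tail(t):
            val, _ = integrate.quad(t_pdf, t, np.inf, args=(dof,))
            return val - p

        oracle = optimize.brentq(tail, 0, 50)
        assert oracle == pytest.approx(2.845, abs=5e-4)
        assert t_threshold(p, dof, "one") == pytest.approx(oracle, rel=1e-8)

    def test_two_sided_equals_halved_one_sided(self):
        assert t_threshold(0.05, 10, "two") == pytest.approx(
            t_threshold(0.025, 10, "one"), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_threshold(0.0, 10)
        with pytest.raises(ValueError):
            t_threshold(0.05, 0)
        with pytest.raises(ValueError):
            t_threshold(0.05, 10, "three")


# ---------------------------------------------------------------------------
# cluster extraction


def _binary_tmap(field):
    vol = Volume(field.astype(float), (1.0, 1.0, 1.0), "t")
    return TMap(
        t=vol,
        dof=10,
        contrast="test",
        mask=full_mask(field.shape),
        degenerate=np.zeros(field.shape, dtype=bool),
    )


class TestExtractClusters:
    def test_empty_map_gives_empty_list(self):
        assert extract_clusters(_binary_tmap(np.zeros((4, 4, 4))), 0.5) == []

    def test_extent_threshold_is_strict(self):
        # a straight 51-voxel line survives "more than 50", a 50-voxel one not
        for length, expected in [(50, 0), (51, 1)]:
            field = np.zeros((60, 3, 3))
            field[:length, 1, 1] = 1.0
            clusters = extract_clusters(_binary_tmap(field), 0.5, min_size=50)
            assert len(clusters) == expected

    def test_matches_flood_fill_oracle_on_random_fields(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            field = rng.random((8, 8, 8)) < 0.35
            for conn in (6, 18, 26):
                expected = flood_fill_components(field, conn)
                clusters = extract_clusters(
                    _binary_tmap(field), 0.5, min_size=0, connectivity=conn
                )
                got = {
                    frozenset(map(tuple, c.voxel_indices)) for c in clusters
                }
                assert got == expected

    def test_clusters_partition_suprathreshold_set(self, default_cohort, default_mask):
        scans, truths = default_cohort
        tmap = regression_tmap(
            scans, [t.true_blood_Bq_per_g for t in truths], default_mask
        )
        clusters = extract_clusters(tmap, 3.0, min_size=0)
        supra = (tmap.t.values > 3.0) & default_mask.values.astype(bool)
        union = np.zeros_like(supra)
        total = 0
        for c in clusters:
            m = c.mask(supra.shape)
            assert not (union & m).any()  # no voxel in two clusters
            union |= m
            total += c.size_voxels
        assert total == int(supra.sum())
        np.testing.assert_array_equal(union, supra)

    def test_raising_thresholds_only_shrinks_clusters(self):
        rng = np.random.default_rng(21)
        field = rng.normal(0, 1, (10, 10, 10))
        tmap = _binary_tmap(field)
        base = extract_clusters(tmap, 0.5, min_size=0)
        base_union = np.zeros(field.shape, dtype=bool)
        for c in base:
            base_union |= c.mask(field.shape)
        for t_crit, min_size in [(1.0, 0), (0.5, 3), (1.5, 2)]:
            for c in extract_clusters(tmap, t_crit, min_size=min_size):
                assert base_union[tuple(c.voxel_indices.T)].all()

    def test_sorted_by_peak_then_size(self):
        field = np.zeros((20, 5, 5))
        field[0:3, 1, 1] = 2.0  # small, high peak
        field[10:18, 1, 1] = 1.0  # large, low peak
        clusters = extract_clusters(_binary_tmap(field), 0.5, min_size=0)
        assert [c.peak_t for c in clusters] == [2.0, 1.0]
        assert clusters[1].size_voxels == 8
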