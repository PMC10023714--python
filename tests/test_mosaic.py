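"""Mosaic statistics: brute-force oracles, hand values, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform, pdist

import retinamosaic as rm


def brute_force_nn(points: np.ndarray) -> np.ndarray:
    d = squareform(pdist(points))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_pair_counts(points: np.ndarray, r_max: float, bw: float) -> np.ndarray:
    """Ordered-pair tallies per half-open annulus, by explicit double loop logic."""
    n_bins = int(round(r_max / bw))
    counts = np.zeros(n_bins, dtype=int)
    n = len(points)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(points[i] - points[j])))
            if d < r_max:
                counts[int(d // bw)] += 1
    return counts


class TestNNDistances:
    def test_two_points_symmetric(self, square_3mm):
        p = rm.PointPattern(np.array([[1000.0, 1000.0], [1050.0, 1000.0]]), square_3mm)
        assert np.allclose(rm.nn_distances(p), [50.0, 50.0])

    def test_collinear_hand_case(self, square_3mm):
        pts = np.array([[1000.0, 1500.0], [1003.0, 1500.0], [1010.0, 1500.0]])
        p = rm.PointPattern(pts, square_3mm)
        assert np.allclose(rm.nn_distances(p), [3.0, 3.0, 7.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, square_3mm, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        p = rm.gen_uniform(square_3mm, n, seed=seed)
        assert np.allclose(rm.nn_distances(p), brute_force_nn(p.points))

    def test_requires_two_points(self, square_3mm):
        p = rm.PointPattern(np.array([[100.0, 100.0]]), square_3mm)
        with pytest.raises(rm.InsufficientPointsError):
            rm.nn_distances(p)


class TestRegularityIndex:
    def test_hand_computation_sample_sd(self):
        """NN set [3, 3, 7]: mean 4.333, sample SD 2.309, RI 1.876."""
        r = rm.regularity_from_distances(np.array([3.0, 3.0, 7.0]))
        assert np.isclose(r.mean_nn, 13.0 / 3.0)
        assert np.isclose(r.sd_nn, 2.3094, atol=1e-4)
        assert np.isclose(r.regularity_index, 1.8764, atol=1e-4)

    def test_perfect_grid_flagged_infinite(self):
        w = rm.Window.rectangle(1000.0, 1000.0)
        gx, gy = np.meshgrid(np.arange(100.0, 1000.0, 100.0),
                             np.arange(100.0, 1000.0, 100.0))
        p = rm.PointPattern(np.column_stack([gx.ravel(), gy.ravel()]), w)
        r = rm.regularity_index(p)
        assert r.is_infinite and r.regularity_index == np.inf

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10.0),
           dx=st.floats(-1e4, 1e4), dy=st.floats(-1e4, 1e4),
           seed=st.integers(0, 100))
    def test_similarity_invariance(self, angle, scale, dx, dy, seed):
        """RI is invariant under rotation + uniform scaling + translation."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, (40, 2))
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = scale * pts @ rot.T + [dx, dy]
        a = rm.regularity_from_distances(brute_force_nn(pts)).regularity_index
        b = rm.regularity_from_distances(brute_force_nn(moved)).regularity_index
        assert abs(a - b) < 1e-6 * max(1.0, abs(a))


class TestDensityRecoveryProfile:
    def test_rejects_single_point(self, square_3mm):
        p = rm.PointPattern(np.array([[100.0, 100.0]]), square_3mm)
        with pytest.raises(rm.InsufficientPointsError):
            rm.density_recovery_profile(p)

    def test_collinear_hand_counts_and_density(self, collinear_pattern):
        """3 points spaced 100 um: 4 ordered pairs at 100, 2 at 200."""
        drp = rm.density_recovery_profile(collinear_pattern)
        expected = np.zeros(20, dtype=int)
        expected[5] = 4   # [100, 120)
        expected[10] = 2  # [200, 220)
        assert np.array_equal(drp.pair_counts, expected)
        dens_100 = 4 / (3 * np.pi * (0.120 ** 2 - 0.100 ** 2))
        assert np.isclose(drp.bin_density[5], dens_100)
        assert np.isclose(dens_100, 96.46, atol=0.01)

    @pytest.mark.parametrize("seed", range(8))
    def test_pair_counts_match_brute_force(self, square_3mm, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 200))
        p = rm.gen_uniform(square_3mm, n, seed=300 + seed)
        drp = rm.density_recovery_profile(p)
        assert np.array_equal(drp.pair_counts,
                              brute_force_pair_counts(p.points, 400.0, 20.0))

    def test_uniform_profile_matches_edge_bias_formula(self, square_3mm):
        """Uncorrected DRP of CSR equals lambda*(n-1)/n * isotropized set
        covariance of the window - the closed-form calibration oracle."""
        L, n = 3000.0, 2000
        dens = np.mean([rm.density_recovery_profile(
            rm.gen_uniform(square_3mm, n, seed=s)).bin_density
            for s in range(25)], axis=0)
        lam = n / 9.0
        r = np.arange(10.0, 400.0, 20.0)
        pred = lam * (n - 1) / n * (1 - 4 * r / (np.pi * L) + r ** 2 / (np.pi * L ** 2))
        assert np.allclose(dens[1:], pred[1:], rtol=0.03)

    def test_hardcore_depletion_first_bin(self, square_3mm):
        """A 140 um exclusion empties the DRP's first bins."""
        p = rm.gen_hardcore(square_3mm, 120, 140.0, seed=0)
        drp = rm.density_recovery_profile(p)
        assert np.all(drp.pair_counts[:7] == 0)  # no pairs below 140 um

    def test_r_max_must_be_bin_multiple(self, collinear_pattern):
        with pytest.raises(rm.ParameterError):
            rm.density_recovery_profile(collinear_pattern, r_max=390.0, bin_width=20.0)


class TestExclusionZone:
    def test_uniform_pattern_zone_at_soma_scale(self, square_3mm):
        """Random patterns show no meaningful exclusion: zone in {0, 20} um."""
        zones = [rm.exclusion_zone(rm.density_recovery_profile(
            rm.gen_uniform(square_3mm, 2000, seed=s))) for s in range(10)]
        assert all(z <= 20.0 for z in zones)

    @pytest.mark.parametrize("dmin", [100.0, 150.0])
    def test_dmin_zone_recovery(self, square_3mm, dmin):
        hits = 0
        for s in range(20):
            p = rm.gen_dmin_mosaic(square_3mm, 120, dmin, 20.0, seed=s)
            z = rm.exclusion_zone(rm.density_recovery_profile(p))
            hits += abs(z - dmin) <= 20.0
        assert hits >= 16

    def test_hardcore_14um_invisible_at_bin_width(self, square_3mm):
        """A 14 um exclusion is sub-bin at 20 um resolution; at a density
        where bin counts are well populated the zone estimate stays at the
        bin floor."""
        for s in range(5):
            p = rm.gen_hardcore(square_3mm, 2000, 14.0, seed=s)
            z = rm.exclusion_zone(rm.density_recovery_profile(p))
            assert z <= 20.0

    def test_all_zero_profile_undefined(self, square_3mm):
        p = rm.PointPattern(np.array([[100.0, 100.0], [2900.0, 2900.0]]), square_3mm)
        drp = rm.density_recovery_profile(p, r_max=400.0, bin_width=20.0)
        # the only pair is farther than r_max: profile is all zero
        with pytest.raises(rm.UndefinedZoneError):
            rm.exclusion_zone(drp)


class TestNeighborDensityMap:
    def test_single_point(self, square_3mm):
        p = rm.PointPattern(np.array([[100.0, 100.0]]), square_3mm)
        assert rm.neighbor_density_map(p).per_point_count.tolist() == [0]

    def test_collinear_within_220(self, collinear_pattern):
        m = rm.neighbor_density_map(collinear_pattern, radius=220.0)
        assert m.per_point_count.tolist() == [2, 2, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force_and_symmetry(self, square_3mm, seed):
        p = rm.gen_uniform(square_3mm, 150, seed=seed)
        m = rm.neighbor_density_map(p, radius=220.0)
        d = squareform(pdist(p.points))
        np.fill_diagonal(d, np.inf)
        oracle = (d <= 220.0).sum(axis=1)
        assert np.array_equal(m.per_point_count, oracle)
        assert m.per_point_count.sum() % 2 == 0  # i counts j <=> j counts i

    def test_hotspot_cells_carry_higher_counts(self, square_3mm):
        """A dense dorsal cluster shows hotter neighbor counts than the rest."""
        rng = np.random.default_rng(0)
        sparse = rng.uniform(200, 2800, (60, 2))
        cluster = rng.normal([1500, 2500], 120, (60, 2))
        p = rm.PointPattern(np.vstack([sparse, cluster]), square_3mm)
        m = rm.neighbor_density_map(p, radius=220.0)
        assert m.per_point_count[60:].mean() > 2 * m.per_point_count[:60].mean()

    def test_invalid_radius(self, collinear_pattern):
        with pytest.raises(rm.ParameterError):
            rm.neighbor_density_map(collinear_pattern, radius=0.0)


class TestTorusLimit:
    def test_poisson_ri_constant(self):
        assert np.isclose(rm.POISSON_RI, 1.9131, atol=5e-4)

    def test_torus_ri_approaches_closed_form(self):
        """Edge-free uniform patterns: RI -> sqrt(pi/(4-pi)) at large n."""
        vals = []
        for s in range(5):
            pts = np.random.default_rng(s).uniform(0, 3000, (10000, 2))
            nn = rm.torus_nn_distances(pts, 3000.0, 3000.0)
            vals.append(rm.regularity_from_distances(nn).regularity_index)
        assert abs(np.mean(vals) - rm.POISSON_RI) < 0.02 * rm.POISSON_RI
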