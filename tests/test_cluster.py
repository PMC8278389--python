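"""Density-peaks clustering: densities, deltas, cutoff tuning, center
selection, assignment and the core/halo split."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import torsmap as tm
from torsmap.errors import SelectionError, TuningError


def brute_force_rho(D, d_c):
    n = D.shape[0]
    return np.array([sum(1 for j in range(n) if j != i and D[i, j] < d_c)
                     for i in range(n)])


def brute_force_delta(D, rho):
    n = D.shape[0]
    delta = np.empty(n)
    nh = np.empty(n, dtype=int)
    for i in range(n):
        higher = [j for j in range(n)
                  if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        if not higher:
            delta[i] = D[i].max()
            nh[i] = -1
        else:
            dists = [D[i, j] for j in higher]
            k = int(np.argmin(dists))
            delta[i] = dists[k]
            nh[i] = higher[k]
    return delta, nh


def random_matrix(rng, n=50, m=4):
    angles = rng.uniform(-np.pi, np.pi, (n, m))
    return tm.distance_matrix(angles).values


class TestComputeDensity:
    def test_hand_count_triangle(self):
        D = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        np.testing.assert_array_equal(tm.compute_density(D, 1.5), [2, 2, 2])

    def test_cutoff_below_min_distance_gives_zero(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(tm.compute_density(D, 0.5), [0, 0])

    def test_strict_inequality_at_cutoff(self):
        # a pair at exactly d_c is NOT counted
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(tm.compute_density(D, 1.0), [0, 0])

    def test_densities_are_integers(self, rng):
        D = random_matrix(rng)
        rho = tm.compute_density(D, 2.0)
        assert rho.dtype.kind == "i"


class TestComputeDelta:
    def test_increasing_density_chain(self):
        # colinear points with strictly increasing rho: delta is the
        # distance to the next point up the chain
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        rho = np.array([1, 2, 3, 4])
        delta, nh = tm.compute_delta(D, rho)
        np.testing.assert_allclose(delta[:3], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(nh[:3], [1, 2, 3])
        assert delta[3] == 6.0 and nh[3] == -1

    def test_all_equal_rho_tie_break_by_index(self, rng):
        D = random_matrix(rng, n=10)
        rho = np.full(10, 3)
        delta, nh = tm.compute_delta(D, rho)
        assert nh[0] == -1 and delta[0] == D[0].max()
        # every other point looks only at lower indices
        for i in range(1, 10):
            assert nh[i] < i
            assert delta[i] == pytest.approx(D[i, :i].min())

    def test_two_separated_blobs(self, rng):
        a = rng.normal(0.0, 0.05, (30, 2))
        b = rng.normal(0.0, 0.05, (30, 2)) + [3.0, 0.0]
        pts = np.vstack([a, b])
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        rho = tm.compute_density(D, 0.2)
        delta, _ = tm.compute_delta(D, rho)
        top2 = np.argsort(rho * delta)[-2:]
        assert delta[top2].min() > 2.0  # both blob maxima see the other blob


@pytest.mark.parametrize("seed", range(10))
def test_density_and_delta_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    D = random_matrix(rng)
    d_c = tm.tune_cutoff(D, 0.1)
    rho = tm.compute_density(D, d_c)
    np.testing.assert_array_equal(rho, brute_force_rho(D, d_c))
    delta, nh = tm.compute_delta(D, rho)
    delta_b, nh_b = brute_force_delta(D, rho)
    np.testing.assert_allclose(delta, delta_b, rtol=0, atol=0)
    np.testing.assert_array_equal(nh, nh_b)


class TestTuneCutoff:
    def test_two_percent_rule_hits_band(self, rng):
        D = random_matrix(rng, n=100)
        d_c = tm.tune_cutoff(D, 0.02)
        mean_rho = tm.compute_density(D, d_c).mean()
        assert 1.5 <= mean_rho <= 2.5

    def test_fraction_near_one_reaches_max_distance(self, rng):
        D = random_matrix(rng, n=20)
        d_c = tm.tune_cutoff(D, 0.95)
        assert d_c >= D.max()

    def test_equidistant_simplex_unattainable(self):
        n = 5
        D = np.ones((n, n)) - np.eye(n)
        with pytest.raises(TuningError):
            tm.tune_cutoff(D, 0.5)

    def test_deterministic(self, rng):
        D = random_matrix(rng)
        assert tm.tune_cutoff(D, 0.02) == tm.tune_cutoff(D, 0.02)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_fraction_domain(self, rng, bad):
        D = random_matrix(rng, n=10)
        with pytest.raises(ValueError):
            tm.tune_cutoff(D, bad)


class TestSelectCenters:
    def test_k_one_returns_global_density_max(self, reference_run):
        _, _, model = reference_run
        centers = tm.select_centers(model.rho_, model.delta_, k=1)
        # the global density maximum has the top gamma in a clean landscape
        assert model.rho_[centers[0]] == model.rho_.max()

    def test_threshold_too_high_is_selection_error(self, rng):
        D = random_matrix(rng)
        rho = tm.compute_density(D, tm.tune_cutoff(D, 0.1))
        delta, _ = tm.compute_delta(D, rho)
        with pytest.raises(SelectionError):
            tm.select_centers(rho, delta, rho_min=rho.max() + 1, delta_min=0.0)

    def test_manual_mode_orders_by_density(self, reference_run):
        _, _, model = reference_run
        picked = [int(model.centers_[3]), int(model.centers_[0])]
        out = tm.select_centers(model.rho_, model.delta_, mode="manual",
                                centers=picked)
        assert model.rho_[out[0]] >= model.rho_[out[1]]

    def test_manual_empty_rejected(self, reference_run):
        _, _, model = reference_run
        with pytest.raises(SelectionError):
            tm.select_centers(model.rho_, model.delta_, mode="manual",
                              centers=[])


class TestAssignAndHalo:
    def test_center_is_core(self, reference_run):
        _, _, model = reference_run
        assert model.is_core_[model.centers_].all()

    def test_descent_property(self, reference_run):
        _, _, model = reference_run
        non_centers = np.setdiff1d(np.arange(len(model.labels_)),
                                   model.centers_)
        nh = model.nearest_higher_[non_centers]
        ok = nh >= 0
        np.testing.assert_array_equal(model.labels_[non_centers[ok]],
                                      model.labels_[nh[ok]])

    def test_chained_point_beyond_cutoff_is_halo(self):
        # line of points: a dense cluster near 0 and a sparse chain walking
        # out to ~2*d_c; the chain end stays assigned (it descends through
        # the denser midpoint) but falls in the halo
        x = np.array([0.0, 0.02, 0.04, 0.06, 0.08, 0.5, 1.0])
        D = np.abs(x[:, None] - x[None, :])
        d_c = 0.45
        rho = tm.compute_density(D, d_c)
        delta, nh = tm.compute_delta(D, rho)
        centers = np.array([np.lexsort((np.arange(len(x)), -rho))[0]])
        assert x[centers[0]] < 0.1          # the center sits in the cluster
        labels, is_core = tm.assign_and_halo(D, rho, nh, centers, d_c=d_c)
        assert (labels == 1).all()
        assert not is_core[6]               # ~1 away from the center
        assert is_core[:5].all()

    def test_planted_partition_recovered_exactly(self, reference_run):
        _, truth, model = reference_run
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_labels_ordered_by_center_density(self, reference_run):
        _, _, model = reference_run
        rho_centers = model.rho_[model.centers_]
        assert np.all(np.diff(rho_centers) <= 0)

    def test_border_density_halo_option(self, world, table1_weights):
        traj, _ = tm.sample_unbiased(world, 1000, seed=11)
        m = tm.DensityPeaks(weights=table1_weights,
                            halo="border-density").fit(traj.angles)
        assert m.is_core_[m.centers_].all()
        assert m.n_clusters_ == 12


class TestDensityPeaksEstimator:
    def test_permutation_equivariance(self, world, table1_weights):
        traj, _ = tm.sample_unbiased(world, 400, seed=5)
        perm = np.random.default_rng(0).permutation(400)
        a = tm.DensityPeaks(weights=table1_weights).fit(traj.angles)
        b = tm.DensityPeaks(weights=table1_weights).fit(traj.angles[perm])
        np.testing.assert_array_equal(a.rho_[perm], b.rho_)
        assert adjusted_rand_score(a.labels_[perm], b.labels_) == 1.0

    def test_precomputed_metric_matches_torsion_metric(self, world,
                                                       table1_weights):
        traj, _ = tm.sample_unbiased(world, 300, seed=6)
        D = tm.distance_matrix(traj.angles, table1_weights)
        a = tm.DensityPeaks(weights=table1_weights).fit(traj.angles)
        b = tm.DensityPeaks(metric="precomputed").fit(D.values)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_fit_predict_returns_labels(self, world, table1_weights):
        traj, _ = tm.sample_unbiased(world, 200, seed=7)
        m = tm.DensityPeaks(weights=table1_weights)
        labels = m.fit_predict(traj.angles)
        np.testing.assert_array_equal(labels, m.labels_)
        assert labels.min() >= 1

    def test_get_set_params_round_trip(self):
        m = tm.DensityPeaks(neighbor_fraction=0.05)
        params = m.get_params()
        assert params["neighbor_fraction"] == 0.05
        m.set_params(k=3)
        assert m.k == 3

    def test_decision_graph_shape(self, reference_run):
        _, _, model = reference_run
        dg = model.decision_graph()
        assert list(dg.columns) == ["rho", "delta"]
        assert len(dg) == 6000
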