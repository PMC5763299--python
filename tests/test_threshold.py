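import itertools

import numpy as np
import pytest

from rwrb.io import EntityIndex
from rwrb.snf import FusedNetwork
from rwrb.threshold import (apply_threshold, degree_fit_diagnostic,
                            network_clustering, random_clustering,
                            threshold_scan)


def _adj(n, edges):
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return A

TRIANGLE = _adj(3, [(0, 1), (1, 2), (0, 2)])
PATH = _adj(3, [(0, 1), (1, 2)])
TRIANGLE_PENDANT = _adj(4, [(0, 1), (1, 2), (0, 2), (0, 3)])


def brute_force_clustering(A, denominator="all"):
    """All-triples oracle for the average clustering coefficient."""
    A = (A > 0).astype(int)
    n = A.shape[0]
    k = A.sum(axis=1)
    ci = np.zeros(n)
    contributors = 0
    for i in range(n):
        if k[i] <= 1:
            continue
        contributors += 1
        nbrs = [j for j in range(n) if A[i, j]]
        e_i = sum(A[a, b] for a, b in itertools.combinations(nbrs, 2))
        ci[i] = 2.0 * e_i / (float(k[i]) * (float(k[i]) - 1.0))
    denom = n if denominator == "all" else max(contributors, 1)
    return float(ci.sum() / denom) if n else 0.0


class TestNetworkClustering:
    def test_triangle_is_fully_clustered(self):
        assert network_clustering(TRIANGLE) == 1.0

    def test_path_has_no_triangles(self):
        assert network_clustering(PATH) == 0.0

    def test_triangle_with_pendant(self):
        # C_a = 1/3, C_b = C_c = 1, pendant contributes 0; divide by N = 4
        assert network_clustering(TRIANGLE_PENDANT) == pytest.approx(7 / 12)

    def test_contributor_denominator_variant(self):
        assert network_clustering(TRIANGLE_PENDANT, denominator="deg-gt-1") \
            == pytest.approx((7 / 3) / 3)

    def test_empty_graph(self):
        assert network_clustering(np.zeros((0, 0))) == 0.0
        assert network_clustering(np.zeros((5, 5))) == 0.0

    @pytest.mark.parametrize("n,p", [(10, 0.3), (25, 0.2), (50, 0.15)])
    def test_matches_all_triples_oracle(self, rng, n, p):
        for _ in range(5):
            A = (rng.random((n, n)) < p).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            assert network_clustering(A) == pytest.approx(
                brute_force_clustering(A), abs=1e-12)


class TestRandomClustering:
    def test_triangle_pendant_closed_form(self):
        # degrees (3,2,2,1): <k>=2, <k^2>=4.5 -> (2.5)^2/(8*4) = 0.1953125
        assert random_clustering(TRIANGLE_PENDANT) == pytest.approx(0.1953125)

    def test_regular_graph_closed_form(self):
        ring = _adj(6, [(i, (i + 1) % 6) for i in range(6)])
        # k=2 for all: (4-2)^2/(8*6)
        assert random_clustering(ring) == pytest.approx(4 / 48)

    def test_edgeless_graph_guard(self):
        assert random_clustering(np.zeros((4, 4))) == 0.0


def _fused(values):
    index = EntityIndex.from_labels([f"g{i:02d}" for i in range(len(values))])
    return FusedNetwork(index=index, values=np.asarray(values, float),
                        iterations_run=0, M=0)


def two_clique_matrix(rng, n=14, w_in=0.9, w_out=0.1, jitter=0.04):
    """Two planted cliques: constant weak between-block weight, jittered
    strong within-block weights (so the DCC plateau ends in a clean drop)."""
    half = n // 2
    values = np.full((n, n), w_out)
    mask = np.zeros((n, n), bool)
    mask[:half, :half] = mask[half:, half:] = True
    noise = rng.normal(0, jitter, (n, n))
    values[mask] = np.clip(w_in + ((noise + noise.T) / 2)[mask], 0.5, 0.99)
    np.fill_diagonal(values, 1.0)
    return values


def exhaustive_first_dcc_peak(values, step):
    """Independent scan: recompute DCC on the full grid with the oracle."""
    P = values.copy()
    np.fill_diagonal(P, 0.0)
    dcc, grid = [], []
    r = 0.0
    while r < 1.0 + step / 2:
        A = (P > r).astype(float)
        if not A.any():
            break
        grid.append(r)
        dcc.append(brute_force_clustering(A) - random_clustering(A))
        r += step
    for j in range(len(dcc) - 1):
        if dcc[j] > dcc[j + 1]:
            return grid[j]
    raise AssertionError("oracle found no local maximum")


class TestThresholdScan:
    def test_two_clique_peak_matches_oracle(self, rng):
        values = two_clique_matrix(rng)
        scan = threshold_scan(_fused(values), step=0.01)
        assert scan.selected == pytest.approx(
            exhaustive_first_dcc_peak(values, 0.01))
        assert 0.1 < scan.selected <= 0.9

    def test_grid_step_spacing(self, rng):
        scan = threshold_scan(_fused(two_clique_matrix(rng)), step=0.001)
        np.testing.assert_allclose(np.diff(scan.grid), 0.001, atol=1e-12)
        np.testing.assert_allclose(scan.dcc, scan.c - scan.c0)

    def test_constant_weight_matrix_has_no_peak(self):
        values = np.full((6, 6), 0.5)
        np.fill_diagonal(values, 1.0)
        with pytest.raises(ValueError, match="local maximum"):
            threshold_scan(_fused(values), step=0.1)

    def test_selection_invariant_to_relabeling(self, rng):
        values = two_clique_matrix(rng)
        perm = rng.permutation(len(values))
        scan1 = threshold_scan(_fused(values), step=0.01)
        scan2 = threshold_scan(_fused(values[np.ix_(perm, perm)]), step=0.01)
        assert scan1.selected == scan2.selected

    def test_scan_clustering_consistent_with_applied_threshold(self, rng):
        values = two_clique_matrix(rng)
        scan = threshold_scan(_fused(values), step=0.01)
        igsn = apply_threshold(_fused(values), scan.selected)
        j = int(np.argmin(np.abs(scan.grid - scan.selected)))
        assert network_clustering(igsn.adjacency) == pytest.approx(scan.c[j])


class TestApplyThreshold:
    def test_zero_threshold_keeps_all_positive_entries(self, rng):
        values = two_clique_matrix(rng, n=6)
        igsn = apply_threshold(_fused(values), 0.0)
        off = values.copy()
        np.fill_diagonal(off, 0.0)
        assert igsn.n_edges == (np.triu(off, 1) > 0).sum()

    def test_threshold_above_max_empties_graph(self, rng):
        igsn = apply_threshold(_fused(two_clique_matrix(rng, n=6)), 0.999)
        assert igsn.n_edges == 0
        assert len(igsn.index) == 6  # isolated nodes stay in V

    def test_entry_count_at_cutoff(self):
        values = np.array([[1.0, 0.2, 0.6],
                           [0.2, 1.0, 0.9],
                           [0.6, 0.9, 1.0]])
        igsn = apply_threshold(_fused(values), 0.5)
        assert igsn.n_edges == 2

    def test_out_of_range_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_threshold(_fused(two_clique_matrix(rng, n=6)), 1.0)


class TestDegreeFitDiagnostic:
    def _igsn_from_graph(self, G):
        import networkx as nx
        A = nx.to_numpy_array(G)
        index = EntityIndex.from_labels([f"n{i:04d}" for i in range(len(A))])
        return apply_threshold(
            FusedNetwork(index=index, values=A, iterations_run=0, M=0), 0.0)

    def test_heavy_tail_prefers_log_space_models(self):
        import networkx as nx
        igsn = self._igsn_from_graph(nx.barabasi_albert_graph(600, 2, seed=3))
        r2 = degree_fit_diagnostic(igsn)
        assert set(r2) == {"power_law", "lognormal", "gaussian"}
        assert all(v <= 1.0 for v in r2.values())
        assert r2["power_law"] > r2["gaussian"]
        # the lognormal form nests the power law, so its fit is at least as good
        assert r2["lognormal"] >= r2["power_law"] - 1e-12

    def test_lognormal_degrees_fit_lognormal_best(self):
        import networkx as nx
        rng = np.random.default_rng(5)
        w = rng.lognormal(2.0, 0.6, size=500)
        G = nx.expected_degree_graph(w, seed=5, selfloops=False)
        r2 = degree_fit_diagnostic(self._igsn_from_graph(G))
        assert r2["lognormal"] >= r2["gaussian"]
        assert r2["lognormal"] > 0.8

    def test_too_few_distinct_degrees_skipped(self):
        igsn = self._igsn_from_graph(__import__("networkx").path_graph(5))
        with pytest.warns(UserWarning, match="skipped"):
            assert degree_fit_diagnostic(igsn) == {}
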