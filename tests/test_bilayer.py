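import numpy as np
import pytest

from rwrb.bilayer import (BilayerNetwork, ProbabilityVector, WalkConfig,
                          initial_vector, rank_candidates, rwr,
                          transition_matrix)
from rwrb.io import EntityIndex


def make_bilayer(a_p, b_pg, w_g):
    m, n = len(a_p), len(w_g)
    return BilayerNetwork(
        pheno_index=EntityIndex.from_labels([f"MIM:{i}" for i in range(m)]),
        gene_index=EntityIndex.from_labels([f"g{i}" for i in range(n)]),
        a_p=np.asarray(a_p, float), b_pg=np.asarray(b_pg, float),
        w_g=np.asarray(w_g, float))


def random_bilayer(rng, m, n, assoc_density=0.2):
    a_p = rng.random((m, m)); a_p = (a_p + a_p.T) / 2; np.fill_diagonal(a_p, 1.0)
    w_g = rng.random((n, n)); w_g = (w_g + w_g.T) / 2; np.fill_diagonal(w_g, 1.0)
    b = (rng.random((m, n)) < assoc_density).astype(float)
    return make_bilayer(a_p, b, w_g)


class TestTransitionMatrix:
    def test_two_node_worked_example(self):
        bl = make_bilayer([[1.0]], [[1.0]], [[1.0]])
        M = transition_matrix(bl, lam=0.6)
        np.testing.assert_allclose(M, [[0.6, 0.4], [0.4, 0.6]])

    def test_rows_sum_to_one(self, rng):
        for _ in range(10):
            bl = random_bilayer(rng, 5, 8)
            M = transition_matrix(bl, lam=0.6)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_phenotype_without_genes_keeps_full_within_weight(self):
        a_p = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.array([[0.0, 0.0], [1.0, 0.0]])  # phenotype 0 has no gene link
        w_g = np.eye(2)
        M = transition_matrix(make_bilayer(a_p, b, w_g), lam=0.6)
        np.testing.assert_allclose(M[0, :2], a_p[0] / a_p[0].sum())
        assert M[0, 2:].sum() == 0.0

    def test_fully_isolated_row_becomes_self_loop(self):
        a_p = np.array([[0.0, 0.0], [0.0, 1.0]])
        b = np.zeros((2, 2))
        w_g = np.eye(2)
        M = transition_matrix(make_bilayer(a_p, b, w_g), lam=0.6)
        assert M[0, 0] == 1.0
        np.testing.assert_allclose(M.sum(axis=1), 1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            make_bilayer([[-1.0]], [[1.0]], [[1.0]])


class TestInitialVector:
    @pytest.fixture
    def indexes(self):
        return (EntityIndex.from_labels(["MIM:0", "MIM:1"]),
                EntityIndex.from_labels(["g0", "g1", "g2"]))

    def test_eta_splits_mass(self, indexes):
        pheno, gene = indexes
        p0 = initial_vector(["MIM:0"], ["g0", "g1"], 0.6, pheno, gene)
        np.testing.assert_allclose(p0.u, [0.4, 0.0])
        np.testing.assert_allclose(p0.v, [0.3, 0.3, 0.0])

    def test_phenotype_only_seed_gets_all_mass(self, indexes):
        pheno, gene = indexes
        p0 = initial_vector(["MIM:1"], [], 0.6, pheno, gene)
        assert p0.u[1] == 1.0 and p0.v.sum() == 0.0
        assert p0.mass == pytest.approx(1.0)

    def test_unit_mass_invariant(self, indexes):
        pheno, gene = indexes
        p0 = initial_vector(["MIM:0", "MIM:1"], ["g2"], 0.3, pheno, gene)
        assert p0.mass == pytest.approx(1.0)

    def test_no_seeds_rejected(self, indexes):
        pheno, gene = indexes
        with pytest.raises(ValueError):
            initial_vector([], [], 0.6, pheno, gene)


def closed_form(M, p0_full, gamma):
    n = len(p0_full)
    return gamma * np.linalg.solve(np.eye(n) - (1 - gamma) * M.T, p0_full)


class TestRwr:
    def test_two_node_worked_value(self):
        bl = make_bilayer([[1.0]], [[1.0]], [[1.0]])
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:0"], [], 0.6, bl.pheno_index, bl.gene_index)
        p_inf = rwr(M, p0, gamma=0.7, tol=1e-12)
        assert p_inf.u[0] == pytest.approx(0.8723, abs=5e-5)
        assert p_inf.v[0] == pytest.approx(0.1277, abs=5e-5)
        np.testing.assert_allclose(p_inf.full,
                                   closed_form(M, p0.full, 0.7), atol=1e-10)

    def test_matches_closed_form_on_random_instances(self, rng):
        for _ in range(10):
            bl = random_bilayer(rng, 6, 10)
            M = transition_matrix(bl, lam=0.6)
            p0 = initial_vector(["MIM:2"], ["g1", "g4"], 0.6,
                                bl.pheno_index, bl.gene_index)
            p_inf = rwr(M, p0, gamma=0.7, tol=1e-13, max_iter=5000)
            np.testing.assert_allclose(p_inf.full,
                                       closed_form(M, p0.full, 0.7), atol=1e-8)

    def test_mass_conserved_every_iteration(self, rng):
        bl = random_bilayer(rng, 4, 6)
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:0"], ["g0"], 0.6,
                            bl.pheno_index, bl.gene_index)
        p = p0.full
        for _ in range(30):
            p = 0.3 * (M.T @ p) + 0.7 * p0.full
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_restart_limit_returns_start(self, rng):
        bl = random_bilayer(rng, 4, 6)
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:1"], [], 0.6, bl.pheno_index, bl.gene_index)
        p_inf = rwr(M, p0, gamma=0.9999, tol=1e-13)
        np.testing.assert_allclose(p_inf.full, p0.full, atol=1e-3)

    def test_fixed_point_independent_of_starting_iterate(self, rng):
        bl = random_bilayer(rng, 5, 8)
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:0"], ["g3"], 0.6,
                            bl.pheno_index, bl.gene_index)
        reference = rwr(M, p0, gamma=0.7, tol=1e-13, max_iter=5000).full
        # iterate from a uniform start but with the same restart vector
        p = np.full(len(reference), 1.0 / len(reference))
        for _ in range(300):
            p = 0.3 * (M.T @ p) + 0.7 * p0.full
        np.testing.assert_allclose(p, reference, atol=1e-9)

    def test_nonconvergence_warns(self, rng):
        bl = random_bilayer(rng, 4, 6)
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:0"], [], 0.6, bl.pheno_index, bl.gene_index)
        with pytest.warns(UserWarning, match="did not converge"):
            out = rwr(M, p0, gamma=0.7, tol=1e-15, max_iter=2)
        assert not out.converged

    def test_permutation_equivariance(self, rng):
        bl = random_bilayer(rng, 3, 7)
        M = transition_matrix(bl, lam=0.6)
        p0 = initial_vector(["MIM:0"], ["g2"], 0.6,
                            bl.pheno_index, bl.gene_index)
        ref = rwr(M, p0, gamma=0.7, tol=1e-13).v
        perm = rng.permutation(7)
        w_perm = bl.w_g[np.ix_(perm, perm)]
        b_perm = bl.b_pg[:, perm]
        labels = [bl.gene_index.labels[i] for i in perm]
        bl2 = BilayerNetwork(pheno_index=bl.pheno_index,
                             gene_index=EntityIndex.from_labels(labels),
                             a_p=bl.a_p, b_pg=b_perm, w_g=w_perm)
        M2 = transition_matrix(bl2, lam=0.6)
        p0b = initial_vector(["MIM:0"], ["g2"], 0.6,
                             bl2.pheno_index, bl2.gene_index)
        out = rwr(M2, p0b, gamma=0.7, tol=1e-13).v
        np.testing.assert_allclose(out, ref[perm], atol=1e-10)


class TestRankCandidates:
    def _pv(self, scores):
        return ProbabilityVector(u=np.zeros(1), v=np.asarray(scores, float))

    def test_descending_ranks(self):
        gi = EntityIndex.from_labels(["a", "b", "c"])
        ranked = rank_candidates(self._pv([0.5, 0.3, 0.2]), gi, ["a", "b", "c"])
        assert [(g, r) for g, _s, r in ranked] == [("a", 1), ("b", 2), ("c", 3)]

    def test_max_scoring_control_is_rank_one(self, rng):
        gi = EntityIndex.from_labels([f"g{i}" for i in range(8)])
        scores = rng.random(8)
        control = ["g1", "g3", "g5"]
        ranked = rank_candidates(self._pv(scores), gi, control)
        best = max(control, key=lambda g: scores[gi[g]])
        assert ranked[0][0] == best and ranked[0][2] == 1

    def test_ties_share_worst_rank(self):
        gi = EntityIndex.from_labels(["a", "b", "c"])
        ranked = rank_candidates(self._pv([0.4, 0.4, 0.2]), gi, ["a", "b", "c"])
        assert sorted(r for _g, _s, r in ranked) == [2, 2, 3]

    def test_empty_control_rejected(self):
        gi = EntityIndex.from_labels(["a"])
        with pytest.raises(ValueError):
            rank_candidates(self._pv([0.1]), gi, [])


class TestWalkConfig:
    @pytest.mark.parametrize("field,value", [
        ("gamma", 0.0), ("gamma", 1.0), ("lam", 1.2), ("eta", -0.1)])
    def test_probabilities_must_be_interior(self, field, value):
        with pytest.raises(ValueError):
            WalkConfig(**{field: value})

    def test_defaults_follow_reported_optimum(self):
        cfg = WalkConfig()
        assert (cfg.gamma, cfg.lam, cfg.eta) == (0.7, 0.6, 0.6)
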