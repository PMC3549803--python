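import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special

from cyanoclock.containers import TransitionDataset
from cyanoclock.network import (
    MITConfig,
    chi2_critical,
    dof_term,
    learn_network,
    max_parent_bound,
    mdl_node_score,
    mit_node_score,
    mit_penalty,
    mutual_information,
)
from cyanoclock.preprocessing import build_transitions
from cyanoclock.synthetic import gen_discrete_dbn, random_dbn_truth


# ---- independent oracles ---------------------------------------------------


def mi_oracle(counts):
    """Brute-force plug-in mutual information by explicit cell summation."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                total += (counts[i, j] / n) * math.log(
                    counts[i, j] * n / (rows[i] * cols[j])
                )
    return total


def chi2_ppf_oracle(alpha, dof):
    """Quantile by numerical inversion of the regularized incomplete gamma."""
    return optimize.brentq(
        lambda x: special.gammainc(dof / 2.0, x / 2.0) - alpha, 1e-12, 1e4
    )


def make_data(x_t, x_next, r):
    x_t = np.asarray(x_t)
    x_next = np.asarray(x_next)
    genes = [f"g{i}" for i in range(x_t.shape[1])]
    return TransitionDataset(genes, x_t, x_next, np.asarray(r, int))


def brute_force_best_parents(data, target_idx, alpha, metric):
    """Exhaustive parent-set search with independently computed scores.

    MI is re-derived from raw transition pairs by dictionary counting; ties
    broken exactly as specified (smaller set first, then lexicographic gene
    order, scanning size-ascending and keeping strict improvements only).
    """
    n = data.n_transitions
    r = data.state_counts
    order = sorted(range(len(data.genes)), key=lambda i: data.genes[i])

    def score(parents):
        child = data.x_next[:, target_idx]
        if metric == "mit":
            if not parents:
                return 0.0
            joint = {}
            for k in range(n):
                key = (child[k],) + tuple(data.x_t[k, p] for p in parents)
                joint[key] = joint.get(key, 0) + 1
            child_m, par_m = {}, {}
            for key, c in joint.items():
                child_m[key[0]] = child_m.get(key[0], 0) + c
                par_m[key[1:]] = par_m.get(key[1:], 0) + c
            mi = sum(
                (c / n) * math.log(c * n / (child_m[k[0]] * par_m[k[1:]]))
                for k, c in joint.items()
            )
            pen = 0.0
            counts = sorted((int(r[p]) for p in parents), reverse=True)
            prod = 1
            for j, rp in enumerate(counts):
                dof = (int(r[target_idx]) - 1) * (rp - 1) * (prod if j else 1)
                pen += chi2_ppf_oracle(alpha, dof) if dof > 0 else 0.0
                prod *= rp
            return 2.0 * n * mi - pen
        # mdl (negated: maximized)
        joint = {}
        for k in range(n):
            key = (tuple(data.x_t[k, p] for p in parents), child[k])
            joint[key] = joint.get(key, 0) + 1
        cfg_m = {}
        for (cfg, _), c in joint.items():
            cfg_m[cfg] = cfg_m.get(cfg, 0) + c
        h = -sum((c / n) * math.log(c / cfg_m[cfg]) for (cfg, _), c in joint.items())
        n_par = (int(r[target_idx]) - 1) * int(
            np.prod([r[p] for p in parents]) if parents else 1
        )
        return -(n * h + 0.5 * math.log(n) * n_par)

    best, best_set = score(()), ()
    for size in range(1, len(order) + 1):
        for combo in itertools.combinations(order, size):
            s = score(combo)
            if s > best:
                best, best_set = s, combo
    return tuple(data.genes[i] for i in best_set), best


# ---- unit tests ------------------------------------------------------------


class TestMutualInformation:
    def test_independent_uniform_is_zero(self):
        assert mutual_information([[25, 25], [25, 25]]) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_is_ln2(self):
        assert mutual_information([[50, 0], [0, 50]]) == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [[[40, 10], [10, 40]], [[7, 2, 1], [3, 9, 4]], [[1, 0], [0, 0]]],
    )
    def test_matches_brute_force(self, table):
        assert mutual_information(table) == pytest.approx(mi_oracle(table), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([[0, 0], [0, 0]])


class TestDofAndChi2:
    def test_minimal_dof(self):
        assert dof_term(2, [2], 1) == 1

    def test_printed_formula_two_parents(self):
        assert dof_term(3, [3, 2], 1) == 4
        assert dof_term(3, [3, 2], 2) == (3 - 1) * (2 - 1) * 3

    def test_penalty_permutation_invariant(self):
        a = mit_penalty(0.999, 3, [2, 3, 3])
        b = mit_penalty(0.999, 3, [3, 3, 2])
        assert a == pytest.approx(b, abs=1e-12)

    def test_chi2_exponential_special_case(self):
        assert chi2_critical(0.5, 2) == pytest.approx(2 * math.log(2), rel=1e-8)
        assert chi2_critical(0.999, 2) == pytest.approx(-2 * math.log(0.001), rel=1e-8)

    def test_chi2_matches_gamma_inversion(self):
        for dof in (1, 3, 12):
            assert chi2_critical(0.999, dof) == pytest.approx(
                chi2_ppf_oracle(0.999, dof), rel=1e-6
            )

    def test_zero_dof_contributes_nothing(self):
        assert chi2_critical(0.999, 0) == 0.0


class TestNodeScores:
    def _copy_data(self, n=100):
        x = np.tile([0, 1], n // 2)
        both = np.column_stack([x, x])
        return make_data(both, both, [2, 2])

    def test_empty_parent_set_scores_zero(self):
        data = self._copy_data()
        assert mit_node_score("g1", [], data, 0.999) == 0.0

    def test_deterministic_copy_value(self):
        data = self._copy_data(100)
        expected = 200 * math.log(2) - chi2_ppf_oracle(0.999, 1)
        assert mit_node_score("g1", ["g0"], data, 0.999) == pytest.approx(expected, abs=1e-6)

    def test_independent_parent_penalized(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        data = make_data(np.column_stack([x, y]), np.column_stack([x, y]), [2, 2])
        assert mit_node_score("g1", ["g0"], data, 0.999) < 0

    def test_mdl_empty_parents_closed_form(self):
        data = self._copy_data(100)
        # balanced binary: H = ln 2
        expected = 100 * math.log(2) + 0.5 * math.log(100) * 1
        assert mdl_node_score("g1", [], data) == pytest.approx(expected, abs=1e-9)

    def test_mdl_deterministic_copy_no_entropy(self):
        data = self._copy_data(100)
        expected = 0.5 * math.log(100) * (2 - 1) * 2
        assert mdl_node_score("g1", ["g0"], data) == pytest.approx(expected, abs=1e-9)


class TestParentBound:
    def _iid_data(self, n, n_genes=3, r=3, seed=0):
        rng = np.random.default_rng(seed)
        xt = rng.integers(0, r, size=(n, n_genes))
        xn = rng.integers(0, r, size=(n, n_genes))
        return make_data(xt, xn, [r] * n_genes)

    def test_tiny_n_forces_empty_network(self):
        data = self._iid_data(3, r=3)
        # one parent's minimal penalty chi2(0.999, 4) > 2*3*ln3
        assert max_parent_bound(data, 0.999, 3) == 0
        net = learn_network(data, MITConfig())
        assert net.edges == []

    def test_bound_monotone_in_n(self):
        bounds = [
            max_parent_bound(self._iid_data(n, r=3), 0.999, 3) for n in (5, 50, 500, 5000)
        ]
        assert bounds == sorted(bounds)

    def test_bound_never_excludes_optimum(self):
        # brute force over all sizes equals the bounded search on small data
        rng = np.random.default_rng(7)
        xt = rng.integers(0, 2, size=(60, 4))
        xn = np.column_stack([xt[:, 0], xt[:, 0], rng.integers(0, 2, 60), xt[:, 2]])
        data = make_data(xt, xn, [2] * 4)
        net = learn_network(data, MITConfig(max_parents_cap=4))
        for ti, gene in enumerate(data.genes):
            parents, score = brute_force_best_parents(data, ti, 0.999, "mit")
            assert net.parent_sets[gene].parents == parents
            assert net.parent_sets[gene].score == pytest.approx(score, abs=1e-6)


class TestLearnNetwork:
    def test_two_gene_copy_system(self):
        rng = np.random.default_rng(1)
        x1 = rng.integers(0, 2, 200)
        x2_next = x1.copy()
        x2 = rng.integers(0, 2, 200)
        data = make_data(np.column_stack([x1, x2]), np.column_stack([rng.integers(0, 2, 200), x2_next]), [2, 2])
        net = learn_network(data, MITConfig(allow_self_loops=False))
        assert net.parent_sets["g1"].parents == ("g0",)

    def test_mit_and_mdl_agree_on_copy_instance(self):
        rng = np.random.default_rng(2)
        x1 = rng.integers(0, 3, 300)
        data = make_data(
            np.column_stack([x1, rng.integers(0, 3, 300)]),
            np.column_stack([rng.integers(0, 3, 300), x1]),
            [3, 3],
        )
        mit_net = learn_network(data, MITConfig(metric="mit", allow_self_loops=False))
        mdl_net = learn_network(data, MITConfig(metric="mdl", allow_self_loops=False))
        assert mit_net.edges == mdl_net.edges == [("g0", "g1")]

    def test_independent_genes_yield_empty_network(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            xt = rng.integers(0, 3, size=(200, 4))
            xn = rng.integers(0, 3, size=(200, 4))
            net = learn_network(make_data(xt, xn, [3] * 4), MITConfig())
            empty += not net.edges
        assert empty >= 9

    def test_score_decomposability(self):
        truth = random_dbn_truth(n_genes=6, seed=3)
        disc = gen_discrete_dbn(truth, 150, 3, seed=3)
        net = learn_network(build_transitions(disc), MITConfig())
        assert net.total_score == pytest.approx(
            sum(ps.score for ps in net.parent_sets.values()), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=12)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_small_instances(self, seed):
        """Bounded search equals brute-force enumeration (n<=4, 3 states)."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 5))
        n = int(rng.integers(20, 120))
        truth = random_dbn_truth(n_genes=n_genes, n_states=3, seed=seed, n_roots=1)
        disc = gen_discrete_dbn(truth, n, 3, seed=seed + 1)
        data = build_transitions(disc)
        config = MITConfig(max_parents_cap=n_genes)
        net = learn_network(data, config)
        for ti, gene in enumerate(data.genes):
            if data.state_counts[ti] <= 1:
                continue
            parents, score = brute_force_best_parents(data, ti, 0.999, "mit")
            assert net.parent_sets[gene].parents == parents

    def test_mdl_search_equals_exhaustive_enumeration(self):
        """The MDL parent-count bound never changes the per-node optimum."""
        for seed in range(5):
            truth = random_dbn_truth(n_genes=4, n_states=3, seed=seed, n_roots=1)
            disc = gen_discrete_dbn(truth, 80, 3, seed=seed + 50)
            data = build_transitions(disc)
            net = learn_network(data, MITConfig(metric="mdl", max_parents_cap=4))
            order = sorted(range(4), key=lambda i: data.genes[i])
            for ti, gene in enumerate(data.genes):
                best, best_set = -mdl_node_score(ti, [], data), ()
                for size in range(1, 5):
                    for combo in itertools.combinations(order, size):
                        s = -mdl_node_score(ti, list(combo), data)
                        if s > best:
                            best, best_set = s, combo
                assert net.parent_sets[gene].parents == tuple(
                    data.genes[i] for i in best_set
                )

    def test_exports(self, tmp_path):
        rng = np.random.default_rng(4)
        x1 = rng.integers(0, 2, 200)
        data = make_data(
            np.column_stack([x1, rng.integers(0, 2, 200)]),
            np.column_stack([rng.integers(0, 2, 200), x1]),
            [2, 2],
        )
        net = learn_network(data, MITConfig(allow_self_loops=False))
        net.write_edge_tsv(tmp_path / "e.tsv")
        net.write_sif(tmp_path / "n.sif")
        net.write_dot(tmp_path / "n.dot")
        assert "g0\tg1" in (tmp_path / "e.tsv").read_text()
        assert "g0\tregulates\tg1" in (tmp_path / "n.sif").read_text()
        assert '"g0" -> "g1";' in (tmp_path / "n.dot").read_text()
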