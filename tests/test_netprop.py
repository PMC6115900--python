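"""Unit and property tests for network loading, RWR and the empirical null."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet.netprop import (
    GenePhenotypeMap,
    MolecularNetwork,
    NetworkParseError,
    PropagationResult,
    TargetProfile,
    build_pvp,
    build_transition,
    empirical_null,
    load_network,
    make_seed_vector,
    map_to_phenotypes,
    predict_pvp,
    run_rwr,
)


def write(tmp_path, text, name="net.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def triangle():
    return MolecularNetwork.from_edges({("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 1.0})


class TestLoadNetwork:
    def test_triangle(self, tmp_path):
        net = load_network(write(tmp_path, "A\tB\nB\tC\nC\tA\n"))
        assert net.n_nodes == 3 and net.n_edges == 3
        assert net.nodes == ("A", "B", "C")  # lexicographic order

    def test_self_loop_dropped_and_counted(self, tmp_path):
        net = load_network(write(tmp_path, "A\tA\nA\tB\n"))
        assert net.n_edges == 1
        assert net.n_self_loops_dropped == 1

    def test_duplicate_edges_collapse(self, tmp_path):
        net = load_network(write(tmp_path, "A\tB\nA\tB\nB\tA\n"))
        assert net.n_edges == 1
        assert net.n_duplicate_edges == 2

    def test_sif_multi_target_row(self, tmp_path):
        net = load_network(write(tmp_path, "A pp B C\n"))
        assert net.n_edges == 2

    def test_weighted_tsv(self, tmp_path):
        net = load_network(write(tmp_path, "A\tB\t2.5\n"))
        assert net.adjacency[0, 1] == 2.5

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(NetworkParseError, match="line 2"):
            load_network(write(tmp_path, "A\tB\nonlyone\n"))

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(NetworkParseError):
            load_network(write(tmp_path, ""))


class TestTransition:
    def test_triangle_half_everywhere(self):
        W = build_transition(triangle()).toarray()
        offdiag = W[~np.eye(3, dtype=bool)]
        assert np.allclose(offdiag, 0.5)

    def test_two_node_path(self):
        net = MolecularNetwork.from_edges({("A", "B"): 1.0})
        W = build_transition(net).toarray()
        assert W[0, 1] == 1.0 and W[1, 0] == 1.0

    def test_star_hub_row(self):
        net = MolecularNetwork.from_edges(
            {("H", "A"): 1.0, ("H", "B"): 1.0, ("H", "C"): 1.0}
        )
        W = build_transition(net).toarray()
        hub = net.index["H"]
        assert np.allclose(W[hub, [0, 1, 2]], 1 / 3)

    def test_isolated_node_self_transition(self):
        adj = sp.csr_matrix(np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        net = MolecularNetwork(("A", "B", "Z"), adj)
        W = build_transition(net).toarray()
        assert W[2, 2] == 1.0
        assert np.allclose(W.sum(axis=1), 1.0)  # row-stochastic everywhere


class TestSeedVector:
    def test_direct_indirect_normalisation(self):
        net = MolecularNetwork.from_edges({("A", "B"): 1.0})
        prof = TargetProfile("x", frozenset({"A"}), frozenset({"B"}))
        p0 = make_seed_vector(prof, net)
        assert np.allclose(p0, [1 / 1.3, 0.3 / 1.3])

    def test_two_direct_targets(self):
        net = triangle()
        prof = TargetProfile("x", frozenset({"A", "B"}), frozenset())
        p0 = make_seed_vector(prof, net)
        assert np.allclose(sorted(p0), [0.0, 0.5, 0.5])

    def test_all_targets_off_network_errors(self):
        net = triangle()
        prof = TargetProfile("mycompound", frozenset({"Q"}), frozenset())
        with pytest.raises(ValueError, match="mycompound"):
            make_seed_vector(prof, net)

    def test_overlapping_target_kept_as_direct(self):
        prof = TargetProfile("x", frozenset({"A"}), frozenset({"A", "B"}))
        assert prof.direct_targets == {"A"}
        assert prof.indirect_targets == {"B"}

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            TargetProfile("x", frozenset(), frozenset())


class TestRWR:
    def test_restart_one_returns_seed(self):
        net = triangle()
        W = build_transition(net)
        p0 = np.array([1.0, 0.0, 0.0])
        res = run_rwr(W, p0, restart=1.0)
        assert np.allclose(res.node_scores, p0)
        assert res.converged

    def test_two_node_closed_form(self):
        # p_A = 0.3*p_B + 0.7, p_B = 0.3*p_A  =>  p_A = 0.7/(1-0.09)
        net = MolecularNetwork.from_edges({("A", "B"): 1.0})
        W = build_transition(net)
        res = run_rwr(W, np.array([1.0, 0.0]), restart=0.7)
        pa = 0.7 / (1 - 0.09)
        assert np.allclose(res.node_scores, [pa, 0.3 * pa], atol=1e-7)

    def test_agrees_with_direct_linear_solve(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            dense = (rng.random((n, n)) < 0.6).astype(float)
            dense = np.triu(dense, 1)
            dense += dense.T
            if dense.sum() == 0:
                dense[0, 1] = dense[1, 0] = 1.0
            nodes = tuple(f"N{i}" for i in range(n))
            net = MolecularNetwork(nodes, sp.csr_matrix(dense))
            W = build_transition(net)
            p0 = rng.random(n)
            p0 /= p0.sum()
            res = run_rwr(W, p0, restart=0.7)
            expected = 0.7 * np.linalg.solve(
                np.eye(n) - 0.3 * W.toarray().T, p0
            )
            assert np.allclose(res.node_scores, expected, atol=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6), st.floats(0.05, 1.0))
    def test_mass_conservation(self, graph_seed, restart):
        rng = np.random.default_rng(graph_seed)
        n = int(rng.integers(2, 12))
        dense = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
        dense += dense.T
        net = MolecularNetwork(
            tuple(f"N{i}" for i in range(n)), sp.csr_matrix(dense)
        )
        W = build_transition(net)
        p0 = rng.random(n)
        p0 /= p0.sum()
        res = run_rwr(W, p0, restart=restart)
        assert abs(res.node_scores.sum() - 1.0) < 1e-6

    def test_restart_limit_approaches_seed(self):
        net = triangle()
        W = build_transition(net)
        p0 = np.array([1.0, 0.0, 0.0])
        dists = [
            np.abs(run_rwr(W, p0, restart=r).node_scores - p0).sum()
            for r in (0.7, 0.9, 0.99)
        ]
        assert dists[0] > dists[1] > dists[2]

    def test_invalid_restart(self):
        with pytest.raises(ValueError):
            run_rwr(build_transition(triangle()), np.array([1.0, 0, 0]), restart=0.0)


class TestPhenotypeMapping:
    def test_sum_over_genes(self):
        res = PropagationResult("x", np.array([0.2, 0.3, 0.5]), 5, True, ("A", "B", "C"))
        gp = GenePhenotypeMap({"phi": frozenset({"A", "B"})})
        assert map_to_phenotypes(res, gp)["phi"] == pytest.approx(0.5)

    def test_off_network_genes_score_zero(self):
        res = PropagationResult("x", np.array([1.0]), 1, True, ("A",))
        gp = GenePhenotypeMap({"phi": frozenset({"ZZZ"})})
        assert map_to_phenotypes(res, gp)["phi"] == 0.0

    def test_shared_gene_counted_in_both(self):
        res = PropagationResult("x", np.array([0.4, 0.6]), 1, True, ("A", "B"))
        gp = GenePhenotypeMap(
            {"p1": frozenset({"A"}), "p2": frozenset({"A", "B"})}
        )
        scores = map_to_phenotypes(res, gp)
        # independent bookkeeping: naive per-phenotype loop
        naive = {
            phen: sum(
                {"A": 0.4, "B": 0.6}[g] for g in genes
            )
            for phen, genes in gp.items()
        }
        assert scores == pytest.approx(naive)

    def test_empty_map_errors(self):
        res = PropagationResult("x", np.array([1.0]), 1, True, ("A",))
        with pytest.raises(ValueError):
            map_to_phenotypes(res, GenePhenotypeMap({}))


def _random_network(rng, n):
    dense = np.triu((rng.random((n, n)) < 0.35).astype(float), 1)
    dense += dense.T
    return MolecularNetwork(tuple(f"N{i:02d}" for i in range(n)), sp.csr_matrix(dense))


class TestEmpiricalNull:
    def test_replay_oracle(self):
        """p-values match a brute-force recomputation replaying the
        documented RNG stream with an independent dense linear solve."""
        rng = np.random.default_rng(3)
        net = _random_network(rng, 12)
        gp = GenePhenotypeMap(
            {
                "p1": frozenset({"N00", "N03", "N07"}),
                "p2": frozenset({"N01", "N05"}),
                "p3": frozenset({"N02", "N09", "N11"}),
            }
        )
        prof = TargetProfile("x", frozenset({"N00", "N04"}), frozenset({"N08"}))
        seed, n_random, r = 11, 20, 0.7
        got = empirical_null(prof, net, gp, n_random=n_random, rng_seed=seed)

        W = build_transition(net).toarray()
        solve = lambda p0: r * np.linalg.solve(np.eye(12) - (1 - r) * W.T, p0)

        def score(p0):
            s = solve(p0)
            idx = {n: i for i, n in enumerate(net.nodes)}
            return {p: sum(s[idx[g]] for g in genes) for p, genes in gp.items()}

        obs = score(make_seed_vector(prof, net))
        stream = np.random.default_rng(seed)
        exceed = {p: 0 for p in obs}
        for _ in range(n_random):
            pick = stream.choice(12, size=3, replace=False)
            v = np.zeros(12)
            v[pick[:2]] = 1.0
            v[pick[2:]] = 0.3
            rand = score(v / v.sum())
            for p in obs:
                if rand[p] > obs[p]:
                    exceed[p] += 1
        expected = {p: (exceed[p] + 1) / (n_random + 1) for p in obs}
        assert got == pytest.approx(expected)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(4)
        net = _random_network(rng, 10)
        gp = GenePhenotypeMap({"p1": frozenset({"N00"})})
        prof = TargetProfile("x", frozenset({"N00"}), frozenset())
        p = empirical_null(prof, net, gp, n_random=50, rng_seed=0)
        assert 1 / 51 <= p["p1"] <= 1.0

    def test_n_random_validation(self):
        net = triangle()
        gp = GenePhenotypeMap({"p1": frozenset({"A"})})
        prof = TargetProfile("x", frozenset({"A"}), frozenset())
        with pytest.raises(ValueError):
            empirical_null(prof, net, gp, n_random=0, rng_seed=0)

    def test_null_calibration_super_uniform(self):
        """Profiles drawn from the null give p-values with fraction < alpha
        bounded near alpha (small-scale version of the full calibration)."""
        rng = np.random.default_rng(9)
        net = _random_network(rng, 30)
        gp = GenePhenotypeMap(
            {
                f"p{k}": frozenset(
                    net.nodes[i] for i in rng.choice(30, size=4, replace=False)
                )
                for k in range(5)
            }
        )
        pooled = []
        for i in range(40):
            pick = rng.choice(30, size=4, replace=False)
            prof = TargetProfile(
                f"null{i}",
                frozenset(net.nodes[j] for j in pick[:2]),
                frozenset(net.nodes[j] for j in pick[2:]),
            )
            p = empirical_null(prof, net, gp, n_random=49, rng_seed=100 + i)
            pooled.extend(p.values())
        pooled = np.array(pooled)
        # super-uniform: empirical CDF never far above the diagonal
        for a in (0.1, 0.25, 0.5):
            assert (pooled < a).mean() <= a + 3 * np.sqrt(a * (1 - a) / 40)


class TestBuildPVP:
    def test_strict_alpha_boundary(self):
        pvp = build_pvp({"a": 1.0, "b": 1.0}, {"a": 0.0099, "b": 0.01}, alpha=0.01)
        assert pvp.binary == {"a": 1, "b": 0}

    def test_all_ones_p_gives_empty_vector(self):
        pvp = build_pvp({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 1.0})
        assert pvp.selected() == frozenset()

    def test_mismatched_keys_error_lists_difference(self):
        with pytest.raises(ValueError, match="b"):
            build_pvp({"a": 1.0}, {"a": 0.5, "b": 0.5})

    def test_selected_count_matches_p_below_alpha(self):
        rng = np.random.default_rng(6)
        net = _random_network(rng, 15)
        gp = GenePhenotypeMap(
            {
                f"p{k}": frozenset(
                    net.nodes[i] for i in rng.choice(15, size=3, replace=False)
                )
                for k in range(4)
            }
        )
        prof = TargetProfile("x", frozenset({"N00", "N01"}), frozenset({"N02"}))
        pvp = predict_pvp(prof, net, gp, n_random=30, rng_seed=5, alpha=0.2)
        assert len(pvp.selected()) == sum(
            1 for v in pvp.empirical_p.values() if v < 0.2
        )

    def test_bit_identical_for_same_seed(self):
        rng = np.random.default_rng(7)
        net = _random_network(rng, 15)
        gp = GenePhenotypeMap({"p1": frozenset({"N00", "N05"})})
        prof = TargetProfile("x", frozenset({"N01"}), frozenset({"N02"}))
        a = predict_pvp(prof, net, gp, n_random=25, rng_seed=42)
        b = predict_pvp(prof, net, gp, n_random=25, rng_seed=42)
        assert a == b  # bit-identical raw scores, p-values and binaries
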