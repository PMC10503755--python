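import itertools

import numpy as np
import pytest

from maxweb import (
    FoodWeb,
    JointDegreeSequence,
    cannibalism,
    diameter,
    joint_degree_sequence,
    kl_divergence_in_out,
    max_similarity,
    max_trophic_level,
    measure_panel,
    motif_catalog,
    motif_profile,
    nestedness_rho,
    omnivory,
    standardized_mean_difference,
    trophic_levels,
)
from conftest import random_webs


def spectral_radius_power(a: np.ndarray, squarings: int = 45) -> float:
    """Gelfand power method: rho = lim ||B^k||^(1/k), via repeated squaring.

    Uses B = A + I (keeps the iteration aperiodic for non-negative A;
    rho(B) = rho(A) + 1) and the Frobenius norm, with log-scale
    renormalization. Independent of LAPACK eigenvalue routines.
    """
    B = a.astype(float) + np.eye(a.shape[0])
    f = np.sqrt((B * B).sum())
    B /= f
    t = np.log(f)
    for _ in range(squarings):
        B = B @ B
        f = np.sqrt((B * B).sum())
        B /= f
        t = 2 * t + np.log(f)
    return float(np.exp(t / 2.0**squarings) - 1.0)


def classify_triad_oracle(sub: np.ndarray, catalog) -> str | None:
    """Brute-force motif classifier: try all 6 permutations vs all 13 reps."""
    for label, rep in catalog:
        for perm in itertools.permutations(range(3)):
            p = np.asarray(perm)
            if np.array_equal(sub[np.ix_(p, p)], rep):
                return label
    return None


def floyd_warshall_diameter(adj: np.ndarray) -> int:
    n = adj.shape[0]
    INF = 10**9
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0
    for i, j in zip(*np.nonzero(adj)):
        if i != j:
            d[i, j] = 1
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    finite = d[(d > 0) & (d < INF)]
    return int(finite.max()) if finite.size else 0


class TestMotifCatalog:
    def test_thirteen_classes_five_single_eight_double(self):
        cat = motif_catalog()
        assert len(cat) == 13
        singles = [m for _, m in cat if not (m & m.T).any()]
        doubles = [m for _, m in cat if (m & m.T).any()]
        assert len(singles) == 5 and len(doubles) == 8

    def test_representatives_connected_and_non_isomorphic(self):
        cat = motif_catalog()
        for _, m in cat:
            u = m | m.T
            assert u.any(axis=0).all() or u.any(axis=1).all()  # no isolated node
        for (la, a), (lb, b) in itertools.combinations(cat, 2):
            iso = any(
                np.array_equal(a[np.ix_(p, p)], b)
                for p in map(np.asarray, itertools.permutations(range(3)))
            )
            assert not iso, f"{la} and {lb} are isomorphic"

    def test_every_connected_digraph_classified(self):
        # exhaustive: each of the 64 labeled 3-node digraphs is either
        # disconnected or isomorphic to exactly one representative
        cat = motif_catalog()
        n_connected = 0
        for bits in range(64):
            m = np.zeros((3, 3), dtype=bool)
            slots = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
            for b, (i, j) in enumerate(slots):
                m[i, j] = bool(bits >> b & 1)
            u = m | m.T
            reach, frontier = {0}, [0]
            while frontier:
                x = frontier.pop()
                for y in range(3):
                    if u[x, y] and y not in reach:
                        reach.add(y)
                        frontier.append(y)
            if len(reach) < 3:
                continue
            n_connected += 1
            matches = [
                lab
                for lab, rep in cat
                if any(
                    np.array_equal(m[np.ix_(p, p)], rep)
                    for p in map(np.asarray, itertools.permutations(range(3)))
                )
            ]
            assert len(matches) == 1
        assert n_connected == 54  # 64 minus the 10 disconnected digraphs


class TestMotifProfile:
    def test_chain_is_tritrophic_s1(self, chain_web):
        prof = motif_profile(chain_web)
        assert prof.counts["S1"] == 1
        assert sum(prof.counts.values()) == 1
        assert prof.proportions["S1"] == 1.0

    def test_one_predator_two_prey_is_s4(self):
        adj = np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=bool)
        prof = motif_profile(FoodWeb(["A", "B", "C"], adj))
        assert prof.counts["S4"] == 1

    def test_two_predators_one_prey_is_s5(self):
        adj = np.array([[0, 0, 1], [0, 0, 1], [0, 0, 0]], dtype=bool)
        prof = motif_profile(FoodWeb(["A", "B", "C"], adj))
        assert prof.counts["S5"] == 1

    def test_small_webs_return_zero_counts(self):
        web = FoodWeb(["A", "B"], np.eye(2, dtype=bool))
        prof = motif_profile(web)
        assert sum(prof.counts.values()) == 0
        assert all(v == 0.0 for v in prof.proportions.values())

    @pytest.mark.parametrize("web", random_webs(6, s_lo=8, s_hi=8, seed=17))
    def test_matches_brute_force_classifier(self, web):
        cat = motif_catalog()
        expected = {lab: 0 for lab, _ in cat}
        for tri in itertools.combinations(range(web.S), 3):
            sub = web.adjacency[np.ix_(tri, tri)].copy()
            np.fill_diagonal(sub, False)
            lab = classify_triad_oracle(sub, cat)
            if lab is not None:
                expected[lab] += 1
        assert motif_profile(web).counts == expected

    def test_invariant_under_relabeling(self):
        web = random_webs(1, s_lo=7, s_hi=7, seed=23)[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(web.S)
        shuffled = FoodWeb(
            [web.species[i] for i in perm],
            web.adjacency[np.ix_(perm, perm)],
        )
        assert motif_profile(shuffled).counts == motif_profile(web).counts


class TestNestedness:
    def test_single_cannibal_raw_one(self):
        web = FoodWeb(["A"], np.ones((1, 1), dtype=bool))
        assert nestedness_rho(web, normalized=False) == pytest.approx(1.0)

    def test_complete_web_normalized_one(self):
        web = FoodWeb(["a", "b", "c"], np.ones((3, 3), dtype=bool))
        assert nestedness_rho(web, normalized=False) == pytest.approx(3.0)
        assert nestedness_rho(web) == pytest.approx(1.0)

    @pytest.mark.parametrize("web", random_webs(8, s_lo=6, s_hi=6, seed=31))
    def test_matches_power_iteration_oracle(self, web):
        raw = nestedness_rho(web, normalized=False)
        assert raw == pytest.approx(spectral_radius_power(web.adjacency), abs=1e-8)

    def test_empty_web_errors(self):
        with pytest.raises(ValueError):
            nestedness_rho(FoodWeb(["a"], np.zeros((1, 1), dtype=bool)))


class TestTrophicLevels:
    def test_chain(self, chain_web):
        np.testing.assert_allclose(trophic_levels(chain_web), [3.0, 2.0, 1.0])

    def test_pure_cannibal_is_basal(self):
        web = FoodWeb(["A"], np.ones((1, 1), dtype=bool))
        np.testing.assert_allclose(trophic_levels(web), [1.0])

    def test_omnivore_prey_average(self, fork_web):
        tl = trophic_levels(fork_web)
        assert tl[0] == pytest.approx(2.5)  # 1 + (2 + 1)/2
        assert tl[1] == pytest.approx(2.0) and tl[2] == pytest.approx(1.0)

    def test_closed_cycle_reported(self):
        adj = np.array([[0, 1], [1, 0]], dtype=bool)  # mutual predation only
        with pytest.raises(RuntimeError, match="cyclic"):
            trophic_levels(FoodWeb(["A", "B"], adj))

    def test_cycle_with_basal_pathway_solvable(self):
        # A <-> B, and B also eats basal C: finite prey-averaged levels
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 0]], dtype=bool)
        tl = trophic_levels(FoodWeb(["A", "B", "C"], adj))
        assert tl[1] == pytest.approx(1 + (tl[0] + tl[2]) / 2, abs=1e-8)
        assert tl[0] == pytest.approx(1 + tl[1], abs=1e-8)


class TestPanelMeasures:
    def test_chain_panel_values(self, chain_web):
        assert max_trophic_level(chain_web) == pytest.approx(3.0)
        assert diameter(chain_web) == 2
        assert cannibalism(chain_web) == 0.0
        assert omnivory(chain_web) == 0.0

    def test_fork_omnivory(self, fork_web):
        assert omnivory(fork_web) == pytest.approx(1 / 3)

    def test_directed_path_diameter(self):
        n = 5
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = True
        assert diameter(FoodWeb([f"s{i}" for i in range(n)], adj)) == n - 1

    @pytest.mark.parametrize("web", random_webs(8, seed=41))
    def test_diameter_matches_floyd_warshall(self, web):
        a = web.adjacency.copy()
        np.fill_diagonal(a, False)
        if not a.any():
            pytest.skip("loops only")
        assert diameter(web) == floyd_warshall_diameter(web.adjacency)

    def test_diameter_no_edges_errors(self):
        web = FoodWeb(["a", "b"], np.eye(2, dtype=bool))  # self-loops ignored
        with pytest.raises(ValueError):
            diameter(web)

    def test_cannibalism_counts_diagonal(self):
        adj = np.eye(4, dtype=bool)
        adj[0, 1] = True
        assert cannibalism(FoodWeb(list("abcd"), adj)) == 1.0

    def test_twins_have_similarity_one(self):
        # two predators with identical prey and predator sets
        adj = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0]], dtype=bool
        )
        web = FoodWeb(list("abcd"), adj)
        assert max_similarity(web) == pytest.approx(1.0)

    def test_panel_assembles(self, fork_web):
        panel = measure_panel(fork_web)
        assert 0 <= panel.entropy <= 1
        assert panel.diam == 1
        assert panel.maxtl == pytest.approx(2.5)
        d = panel.as_dict()
        assert set(d) == {"rho", "maxtl", "diam", "mxsim", "cannib", "omniv", "entropy"}


class TestKLDivergence:
    def test_symmetric_sequence_near_zero(self):
        seq = JointDegreeSequence.from_pairs([(2, 0), (0, 2), (1, 1), (1, 1)])
        assert kl_divergence_in_out(seq) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("web", random_webs(5, seed=53))
    def test_nonnegative(self, web):
        seq = joint_degree_sequence(web)
        assert kl_divergence_in_out(seq, "in_vs_out") >= 0
        assert kl_divergence_in_out(seq, "out_vs_in") >= 0

    def test_hand_built_example(self):
        seq = JointDegreeSequence.from_pairs([(0, 1), (0, 1), (1, 2), (3, 0)])
        eps = 1e-10
        f_in = np.array([2, 1, 0, 1, 0]) / 4
        f_out = np.array([1, 2, 1, 0, 0]) / 4
        P = (f_in + eps) / (f_in + eps).sum()
        Q = (f_out + eps) / (f_out + eps).sum()
        expected = float((P * np.log(P / Q)).sum())
        assert kl_divergence_in_out(seq) == pytest.approx(expected, abs=1e-10)


class TestStandardizedMeanDifference:
    def test_identical_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert standardized_mean_difference(x, x) == 0.0

    def test_one_sd_shift_is_one(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=30)
        p = e + e.std(ddof=1)
        assert standardized_mean_difference(p, e) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        p, e = rng.normal(size=20), rng.normal(size=20)
        expected = (p - e).mean() / e.std(ddof=1)
        assert standardized_mean_difference(p, e) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            standardized_mean_difference(np.ones(3), np.ones(3))
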