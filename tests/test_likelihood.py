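"""Pruning likelihoods against enumeration oracles, fit behavior, and
ancestral reconstruction."""

import numpy as np
import pytest

from codonsel.genetics import genetic_code
from codonsel.likelihood import (
    FitResult,
    LikelihoodEngine,
    ancestral_posteriors,
    column_likelihood,
    fit,
    map_ancestral_codons,
    mixture_loglik,
)
from codonsel.model import estimate_frequencies
from codonsel.seqio import codon_alignment_from_rows
from codonsel.simulate import SimulationSpec, simulate_alignment
from codonsel.siteclass import get_model
from codonsel.tree import parse_newick, reroot

GC = genetic_code(1)


@pytest.fixture(scope="module")
def four_taxon_setup(four_taxon_tree, small_m0_data):
    aln, _, spec = small_m0_data
    sub = aln.take_columns(range(5))
    pi = estimate_frequencies(aln, "F3x4")
    eng = LikelihoodEngine(sub, four_taxon_tree, pi)
    omega_cb = np.full((1, eng.n_branches), 0.3)
    scales = eng.branch_scales(2.0, omega_cb, np.array([1.0]))
    P = eng.transition_stack(2.0, omega_cb, eng.lengths0, scales)[0]
    return sub, eng, pi, {v: P[b] for v, b in eng.branch_index.items()}


class TestPruning:
    def test_single_leaf_likelihood_is_pi(self):
        # a one-taxon tree is a degenerate rooted tree with just the leaf
        aln = codon_alignment_from_rows(["A"], ["AAA"])
        from codonsel.tree import LabeledTree, Node

        tree = LabeledTree([Node(0, "A", None, 0, None, [])], 0)
        pi = np.full(61, 1 / 61)
        eng = LikelihoodEngine(aln, tree, pi)
        ll = eng.class_site_logliks(2.0, np.zeros((1, 0)), np.zeros(0),
                                    weights=np.array([1.0]))
        assert ll[0, 0] == pytest.approx(np.log(pi[GC.codon_index["AAA"]]))

    def test_two_identical_leaves_zero_branches(self):
        aln = codon_alignment_from_rows(["A", "B"], ["ACG", "ACG"])
        tree = parse_newick("(A:0.0,B:0.0);")
        pi = np.full(61, 1 / 61)
        eng = LikelihoodEngine(aln, tree, pi)
        om = np.full((1, 2), 0.5)
        ll = eng.class_site_logliks(2.0, om, np.zeros(2), weights=np.array([1.0]))
        assert ll[0, 0] == pytest.approx(np.log(pi[GC.codon_index["ACG"]]))

    def test_matches_enumeration_oracle(self, four_taxon_setup, four_taxon_tree):
        sub, eng, pi, P_by_node = four_taxon_setup
        codes = sub.encode()
        oracle = enumeration_loglik_simple(
            four_taxon_tree, P_by_node, pi, codes, sub.ids
        )
        om = np.full((1, eng.n_branches), 0.3)
        scales = eng.branch_scales(2.0, om, np.array([1.0]))
        got = eng.class_site_logliks(2.0, om, eng.lengths0, scales=scales)[0]
        assert np.abs(got - oracle).max() < 1e-8

    def test_column_likelihood_matches_engine(self, four_taxon_setup, four_taxon_tree):
        sub, eng, pi, P_by_node = four_taxon_setup
        codes = sub.encode()
        states = {
            sid: (int(codes[i, 0]) if codes[i, 0] >= 0 else None)
            for i, sid in enumerate(sub.ids)
        }
        lik = column_likelihood(four_taxon_tree, states, P_by_node, pi)
        om = np.full((1, eng.n_branches), 0.3)
        scales = eng.branch_scales(2.0, om, np.array([1.0]))
        got = eng.class_site_logliks(2.0, om, eng.lengths0, scales=scales)[0, 0]
        assert np.log(lik) == pytest.approx(got, abs=1e-10)

    def test_gap_states_contribute_ones(self, four_taxon_tree):
        aln = codon_alignment_from_rows(
            ["A", "B", "C", "D"], ["ATG", "---", "ATG", "NNN"]
        )
        pi = np.full(61, 1 / 61)
        eng = LikelihoodEngine(aln, four_taxon_tree, pi)
        om = np.full((1, 4 + 2), 0.5)
        ll = eng.class_site_logliks(2.0, om, weights=np.array([1.0]))
        assert np.isfinite(ll).all()


def enumeration_loglik_simple(tree, P_by_node, pi, codes, ids):
    """Brute-force likelihood for the balanced 4-taxon tree: explicit sum
    over the two internal states and the root."""
    m = len(pi)
    row = {sid: i for i, sid in enumerate(ids)}
    A, B = tree.find("A"), tree.find("B")
    C, D = tree.find("C"), tree.find("D")
    u = tree.nodes[A].parent
    w = tree.nodes[C].parent

    def leaf_vec(node, col):
        s = codes[row[tree.nodes[node].name], col]
        return np.ones(m) if s < 0 else np.eye(m)[s]

    out = []
    for col in range(codes.shape[1]):
        eA, eB = P_by_node[A] @ leaf_vec(A, col), P_by_node[B] @ leaf_vec(B, col)
        eC, eD = P_by_node[C] @ leaf_vec(C, col), P_by_node[D] @ leaf_vec(D, col)
        total = 0.0
        for r in range(m):
            su_sum = 0.0
            for su in range(m):
                su_sum += P_by_node[u][r, su] * eA[su] * eB[su]
            sw_sum = 0.0
            for sw in range(m):
                sw_sum += P_by_node[w][r, sw] * eC[sw] * eD[sw]
            total += pi[r] * su_sum * sw_sum
        out.append(np.log(total))
    return np.array(out)


class TestMixture:
    def test_degenerate_mixture_equals_single_model(self, small_m0_data, four_taxon_tree):
        aln, _, _ = small_m0_data
        pi = estimate_frequencies(aln, "F3x4")
        theta = {"kappa": 2.0, "omega": 0.3}
        single = mixture_loglik(aln, four_taxon_tree, "M0", theta, freqs=pi)
        # M2a_rel squeezed onto one class: p0 ~ 1
        theta_m = {
            "kappa": 2.0,
            "q0": 1 - 1e-9,
            "q1": 0.5,
            "omega0": 0.3,
            "omega2": 5.0,
        }
        mixed = mixture_loglik(aln, four_taxon_tree, "M2a_rel", theta_m, freqs=pi)
        assert mixed == pytest.approx(single, abs=1e-3)

    def test_cmc_collapses_to_m2arel(self, cmc_sim_200):
        aln, _, spec = cmc_sim_200
        pi = estimate_frequencies(aln, "F3x4")
        base = {"kappa": 2.3, "q0": 0.8, "q1": 0.3, "omega0": 0.06,
                "omega2": 0.7}
        lnl_null = mixture_loglik(aln, spec.tree, "M2a_rel", base, freqs=pi)
        cmc = dict(base, omega3=base["omega2"])
        lnl_cmc = mixture_loglik(aln, spec.tree, "CmC", cmc, freqs=pi)
        assert lnl_cmc == pytest.approx(lnl_null, abs=1e-6)

    def test_invariant_to_rerooting(self, small_m0_data, four_taxon_tree):
        aln, _, _ = small_m0_data
        pi = estimate_frequencies(aln, "F3x4")
        theta = {"kappa": 2.0, "omega": 0.3}
        base = mixture_loglik(aln, four_taxon_tree, "M0", theta, freqs=pi)
        for node in four_taxon_tree.branch_nodes():
            r = reroot(four_taxon_tree, node)
            assert mixture_loglik(aln, r, "M0", theta, freqs=pi) == pytest.approx(
                base, abs=1e-8
            )

    def test_invariant_to_taxon_and_column_order(self, small_m0_data, four_taxon_tree):
        aln, _, _ = small_m0_data
        pi = estimate_frequencies(aln, "F3x4")
        theta = {"kappa": 2.0, "omega": 0.3}
        base = mixture_loglik(aln, four_taxon_tree, "M0", theta, freqs=pi)
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_sites)
        shuffled_cols = aln.take_columns(perm)
        order = [3, 1, 0, 2]
        from codonsel.seqio import CodonAlignment

        shuffled_taxa = CodonAlignment(
            ids=tuple(aln.ids[i] for i in order),
            codons=tuple(aln.codons[i] for i in order),
        )
        assert mixture_loglik(
            aln.__class__(aln.ids, shuffled_cols.codons), four_taxon_tree,
            "M0", theta, freqs=pi,
        ) == pytest.approx(base, abs=1e-8)
        assert mixture_loglik(
            shuffled_taxa, four_taxon_tree, "M0", theta, freqs=pi
        ) == pytest.approx(base, abs=1e-8)


class TestFit:
    def test_m0_parameter_recovery(self):
        """1,000 codons, 8 taxa, omega = 0.2: the MLE lands within 0.05."""
        from codonsel.simulate import STUDY_TREE

        tree = parse_newick(STUDY_TREE)
        spec = SimulationSpec(
            tree=tree,
            model=get_model("M0"),
            theta={"kappa": 2.0, "omega": 0.2},
            n_sites=1000,
            seed=5,
        )
        aln, _ = simulate_alignment(spec)
        res = fit(aln, tree, "M0", restarts=1, seed=0)
        assert res.converged
        assert abs(res.theta["omega"] - 0.2) < 0.05

    def test_refit_from_optimum_is_fixed_point(self, small_m0_fit, small_m0_data, four_taxon_tree):
        aln, _, _ = small_m0_data
        again = fit(
            aln, four_taxon_tree, "M0", restarts=1, seed=1,
            start={"kappa": small_m0_fit.kappa, **small_m0_fit.theta},
        )
        assert abs(again.lnL - small_m0_fit.lnL) < 1e-5

    def test_estimates_respect_bounds(self, small_m0_fit):
        assert 1e-6 <= small_m0_fit.theta["omega"] <= 999
        assert small_m0_fit.kappa > 0
        assert np.isfinite(small_m0_fit.lnL)

    def test_report_round_trip(self, small_m0_fit):
        text = small_m0_fit.to_report()
        parsed = FitResult.parse_report(text)
        assert parsed["model"] == "M0"
        assert parsed["lnL"] == pytest.approx(small_m0_fit.lnL, abs=1e-8)
        assert parsed["params"]["omega"] == pytest.approx(
            small_m0_fit.theta["omega"], rel=1e-8
        )


class TestAncestral:
    def test_leaf_posterior_is_point_mass(self, small_m0_fit):
        tree = small_m0_fit.tree
        leaf = tree.leaves()[0]
        post = ancestral_posteriors(small_m0_fit, leaf)
        codes = small_m0_fit.aln.encode()
        row = list(small_m0_fit.aln.ids).index(tree.nodes[leaf].name)
        for s in range(small_m0_fit.n_sites):
            if codes[row, s] >= 0:
                assert post[s, codes[row, s]] == pytest.approx(1.0, abs=1e-9)

    def test_star_tree_identical_leaves(self):
        aln = codon_alignment_from_rows(
            ["A", "B", "C"], ["AAA", "AAA", "AAA"]
        )
        tree = parse_newick("(A:0.01,B:0.01,C:0.01);")
        res = fit(aln, tree, "M0", restarts=1, branch_mode="fixed", maxiter=60)
        rows = map_ancestral_codons(res, tree.root)
        codon, aa, p = rows[0]
        assert codon == "AAA" and aa == "K"
        assert p > 0.99

    def test_matches_enumeration_bayes_oracle(self, small_m0_data, four_taxon_tree):
        """Marginal posterior at an internal node of the 4-taxon tree vs a
        direct Bayes computation over all joint internal assignments."""
        aln, _, _ = small_m0_data
        sub = aln.take_columns(range(4))
        res = fit(sub, four_taxon_tree, "M0", restarts=1,
                  branch_mode="fixed", maxiter=80)
        tree = res.tree
        A = tree.find("A")
        u = tree.nodes[A].parent  # internal node above (A,B)
        post = ancestral_posteriors(res, u)

        eng = LikelihoodEngine(sub, tree, res.freqs)
        om = np.full((1, eng.n_branches), res.theta["omega"])
        scales = eng.branch_scales(res.kappa, om, np.array([1.0]))
        P = eng.transition_stack(res.kappa, om, res.branch_lengths, scales)[0]
        P_by_node = {v: P[b] for v, b in eng.branch_index.items()}
        codes = sub.encode()
        m = 61
        row = {sid: i for i, sid in enumerate(sub.ids)}
        B, C, D = tree.find("B"), tree.find("C"), tree.find("D")
        w = tree.nodes[C].parent
        for col in range(sub.n_sites):
            def lv(node):
                s = codes[row[tree.nodes[node].name], col]
                return np.ones(m) if s < 0 else np.eye(m)[s]

            eA, eB = P_by_node[A] @ lv(A), P_by_node[B] @ lv(B)
            eC, eD = P_by_node[C] @ lv(C), P_by_node[D] @ lv(D)
            joint_u = np.zeros(m)
            for r in range(m):
                for su in range(m):
                    contrib = (
                        res.freqs[r]
                        * P_by_node[u][r, su]
                        * eA[su]
                        * eB[su]
                    )
                    sw_total = 0.0
                    for sw in range(m):
                        sw_total += P_by_node[w][r, sw] * eC[sw] * eD[sw]
                    joint_u[su] += contrib * sw_total
            oracle = joint_u / joint_u.sum()
            assert np.abs(post[col] - oracle).max() < 1e-9

    def test_unknown_node_rejected(self, small_m0_fit):
        with pytest.raises(KeyError):
            ancestral_posteriors(small_m0_fit, "no_such_node")

    def test_posteriors_sum_to_one(self, small_m0_fit):
        tree = small_m0_fit.tree
        post = ancestral_posteriors(small_m0_fit, tree.root)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
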