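"""Selection inference: chi-square tails, free-ratio rates, LRTs,
empirical-Bayes posteriors, site-wise omega."""

import numpy as np
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from codonsel.likelihood import fit, mixture_loglik
from codonsel.model import estimate_frequencies
from codonsel.selection import (
    branch_site_test,
    chisq_pvalue,
    clade_model_test,
    free_ratio,
    mixture_null_pvalue,
    results_table,
    site_class_posteriors,
    sitewise_omega,
)
from codonsel.seqio import codon_alignment_from_rows
from codonsel.simulate import (
    SimulationSpec,
    make_study_like_fixture,
    simulate_alignment,
)
from codonsel.siteclass import get_model
from codonsel.tree import parse_newick


class TestChisqPvalue:
    @pytest.mark.parametrize(
        "lrt, expected",
        [
            (5.3, 0.02),
            (4.7, 0.03),
            (4.1, 0.04),
            (2.8, 0.09),
            (1.6, 0.2),
            (0.7, 0.4),
        ],
    )
    def test_reported_pvalues_at_printed_rounding(self, lrt, expected):
        p = chisq_pvalue(lrt, 1)
        decimals = len(str(expected).split(".")[1])
        assert round(p, decimals) == expected

    def test_zero_statistic(self):
        assert chisq_pvalue(0.0, 1) == 1.0

    def test_critical_value(self):
        assert round(chisq_pvalue(3.841, 1), 2) == 0.05

    def test_matches_numerical_integration(self):
        """Upper tail vs direct integration of the chi2(1) density."""
        for lrt in (0.5, 1.0, 3.841, 10.0, 25.0, 50.0):
            tail, _ = scipy.integrate.quad(
                lambda x: scipy.stats.chi2.pdf(x, 1), lrt, np.inf
            )
            assert abs(chisq_pvalue(lrt, 1) - tail) < 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 49.0), st.floats(0.01, 1.0))
    def test_strictly_decreasing(self, lrt, delta):
        assert chisq_pvalue(lrt + delta, 1) < chisq_pvalue(lrt, 1)

    def test_small_negative_clamped_large_negative_raises(self):
        assert chisq_pvalue(-1e-8, 1) == 1.0
        with pytest.raises(ValueError):
            chisq_pvalue(-0.5, 1)

    def test_mixture_null_halves_tail(self):
        assert mixture_null_pvalue(3.0) == pytest.approx(
            0.5 * chisq_pvalue(3.0, 1)
        )
        assert mixture_null_pvalue(0.0) == 1.0


@pytest.fixture(scope="module")
def free_ratio_neutral():
    """Free-ratio fit on data simulated with omega = 1 on all branches."""
    tree = parse_newick(
        "((a:0.15,b:0.2):0.1,(c:0.25,d:0.1):0.08,e:0.3);"
    )
    spec = SimulationSpec(
        tree=tree,
        model=get_model("M0"),
        theta={"kappa": 2.0, "omega": 1.0},
        n_sites=1000,
        seed=17,
    )
    aln, _ = simulate_alignment(spec)
    rates, fr = free_ratio(aln, tree, seed=0)
    return rates, fr


class TestFreeRatio:
    def test_omega_recovery_under_neutrality(self, free_ratio_neutral):
        rates, _ = free_ratio_neutral
        med = np.median([r.omega for r in rates])
        assert 0.7 <= med <= 1.4

    def test_omega_equals_dn_over_ds(self, free_ratio_neutral):
        rates, _ = free_ratio_neutral
        for r in rates:
            if r.dS > 0:
                assert r.dN / r.dS == pytest.approx(r.omega, rel=1e-6)

    def test_identical_sequences_zero_rates(self):
        tree = parse_newick("((a:0.1,b:0.1):0.05,c:0.1);")
        aln = codon_alignment_from_rows(
            ["a", "b", "c"], ["ATGGCGAAA"] * 3
        )
        rates, _ = free_ratio(aln, tree, seed=0)
        for r in rates:
            assert r.dN == pytest.approx(0.0, abs=1e-4)
            assert r.dS == pytest.approx(0.0, abs=1e-4)

    def test_requires_three_taxa(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = codon_alignment_from_rows(["a", "b"], ["ATG", "ATG"])
        with pytest.raises(ValueError):
            free_ratio(aln, tree)


@pytest.fixture(scope="module")
def cmc_test_result(cmc_sim_200):
    aln, truth, spec = cmc_sim_200
    res, post = clade_model_test(aln, spec.tree, restarts=2, seed=0)
    return res, post, truth


class TestCladeModelTest:
    def test_nesting_alt_at_least_null(self, cmc_test_result):
        res, _, _ = cmc_test_result
        assert res.lnL_alt >= res.lnL_null - 1e-6
        assert res.lrt >= -1e-6
        assert 0.0 <= res.pvalue <= 1.0

    def test_detects_divergence_on_preset_data(self, cmc_test_result):
        res, _, _ = cmc_test_result
        w2, w3 = res.fit_alt.omegas[2]
        assert res.pvalue < 0.05
        assert w3 > w2

    def test_flagged_sites_enriched_for_true_divergent(self, cmc_test_result):
        res, post, truth = cmc_test_result
        flagged = post.flagged_sites
        assert len(flagged) > 0
        frac_flagged = np.mean(truth.site_class[flagged] == 2)
        frac_overall = np.mean(truth.site_class == 2)
        assert frac_flagged > frac_overall

    def test_threshold_monotonicity(self, cmc_test_result):
        _, post, _ = cmc_test_result
        lower = set(np.flatnonzero(post.posteriors > 0.75))
        higher = set(np.flatnonzero(post.posteriors > 0.9))
        assert higher <= lower

    def test_forcing_equal_omegas_zeroes_lrt(self, cmc_sim_200):
        """CmC evaluated with omega3 = omega2 reproduces M2a_rel exactly."""
        aln, _, spec = cmc_sim_200
        pi = estimate_frequencies(aln, "F3x4")
        theta = {"kappa": 2.1, "q0": 0.85, "q1": 0.4, "omega0": 0.05,
                 "omega2": 0.8}
        lnl_null = mixture_loglik(aln, spec.tree, "M2a_rel", theta, freqs=pi)
        lnl_alt = mixture_loglik(
            aln, spec.tree, "CmC", dict(theta, omega3=0.8), freqs=pi
        )
        assert abs(2 * (lnl_alt - lnl_null)) < 1e-6

    def test_requires_foreground(self, cmc_sim_200):
        aln, _, _ = cmc_sim_200
        bare = parse_newick(
            "(((fg_taxon:0.15,sister:0.12):0.10,(cousin1:0.14,cousin2:0.18)"
            ":0.08):0.12,((out1:0.25,out2:0.20):0.10,out3:0.30):0.08,"
            "out4:0.45);"
        )
        with pytest.raises(ValueError, match="foreground"):
            clade_model_test(aln, bare)

    def test_report_table_layout(self, cmc_test_result):
        res, _, _ = cmc_test_result
        df = results_table([res], adjust=True)
        for col in ("gene", "model_alt", "model_null", "lnL_alt", "lnL_null",
                    "LRT", "df", "p", "significant", "omega2", "omega3",
                    "p_BH"):
            assert col in df.columns
        assert df.loc[0, "df"] == 1


@pytest.fixture(scope="module")
def bs_result():
    spec = make_study_like_fixture("branchsite-positive", seed=77)
    spec.n_sites = 400
    aln, truth = simulate_alignment(spec)
    res, post = branch_site_test(aln, spec.tree, restarts=2, seed=0)
    return res, post, truth


class TestBranchSiteTest:
    def test_detects_positive_selection(self, bs_result):
        res, _, _ = bs_result
        assert res.pvalue < 0.05
        assert res.fit_alt.theta["omega2"] > 1.0

    def test_nesting(self, bs_result):
        res, _, _ = bs_result
        assert res.lnL_alt >= res.lnL_null - 1e-6

    def test_posteriors_point_at_selected_sites(self, bs_result):
        res, post, truth = bs_result
        selected = np.isin(truth.site_class, (2, 3))
        assert post.posteriors[selected].mean() > post.posteriors[~selected].mean()

    def test_mixture_null_option_halves_p(self):
        spec = make_study_like_fixture("branchsite-positive", seed=78)
        spec.n_sites = 150
        aln, _ = simulate_alignment(spec)
        res, _ = branch_site_test(aln, spec.tree, restarts=1, seed=0)
        res_mix, _ = branch_site_test(
            aln, spec.tree, restarts=1, seed=0, mixture_null=True
        )
        if res.lrt > 1e-6:
            assert res_mix.pvalue == pytest.approx(res.pvalue / 2, rel=1e-6)


class TestSitePosteriors:
    def test_single_class_model_posterior_is_one(self, small_m0_fit):
        post = site_class_posteriors(small_m0_fit, mode="neb")
        assert np.allclose(post.class_posteriors, 1.0)

    def test_neb_matches_hand_computed_bayes_ratios(self, cmc_test_result):
        res, _, _ = cmc_test_result
        f = res.fit_alt
        post = site_class_posteriors(f, mode="neb")
        # hand computation from the cached per-class site log-likelihoods
        lik = np.exp(f.class_site_loglik - f.class_site_loglik.max(axis=0))
        num = f.proportions[:, None] * lik
        hand = (num / num.sum(axis=0)).T
        assert np.allclose(post.class_posteriors, hand, atol=1e-12)
        assert np.allclose(post.posteriors, hand[:, 2], atol=1e-12)

    def test_posteriors_normalized(self, cmc_test_result):
        res, post, _ = cmc_test_result
        assert np.allclose(post.class_posteriors.sum(axis=1), 1.0)
        assert np.all((post.posteriors >= 0) & (post.posteriors <= 1))

    def test_beb_grid_mode_is_valid_distribution(self, cmc_test_result):
        res, _, _ = cmc_test_result
        beb = site_class_posteriors(res.fit_alt, mode="beb-grid",
                                    grid_points=4)
        assert np.all((beb.posteriors >= 0) & (beb.posteriors <= 1))
        neb = site_class_posteriors(res.fit_alt, mode="neb")
        # grid averaging should broadly agree with NEB on rank ordering
        corr = np.corrcoef(beb.posteriors, neb.posteriors)[0, 1]
        assert corr > 0.8

    def test_unknown_mode(self, small_m0_fit):
        with pytest.raises(ValueError):
            site_class_posteriors(small_m0_fit, mode="bogus")


N_CONS = 40  # purifying block: omega 0.05
N_POS = 30  # positively selected block: omega 5


@pytest.fixture(scope="module")
def sitewise_toy():
    """A long-branch 4-taxon toy: a purifying block followed by a
    positively selected block (some selected sites stay invariant by
    chance, so block-level comparisons use the variable sites)."""
    tree = parse_newick("((a:1.2,b:1.0):0.5,(c:1.0,d:1.2):0.5);")
    spec_cons = SimulationSpec(
        tree=tree, model=get_model("M0"),
        theta={"kappa": 2.0, "omega": 0.05}, n_sites=N_CONS, seed=21,
    )
    spec_pos = SimulationSpec(
        tree=tree, model=get_model("M0"),
        theta={"kappa": 2.0, "omega": 5.0}, n_sites=N_POS, seed=22,
    )
    a1, _ = simulate_alignment(spec_cons)
    a2, _ = simulate_alignment(spec_pos)
    rows = {
        sid: a1.row(sid) + a2.row(sid) for sid in a1.ids
    }
    aln = codon_alignment_from_rows(
        list(rows), ["".join(r) for r in rows.values()]
    )
    m0 = fit(aln, tree, "M0", restarts=1, seed=0)
    df = sitewise_omega(aln, tree, m0_fit=m0)
    return df, aln, tree, m0


class TestSitewiseOmega:
    def test_selected_sites_estimated_above_one(self, sitewise_toy):
        df, aln, *_ = sitewise_toy
        codes = aln.encode()
        variable = np.array(
            [len(set(codes[:, s])) > 1 for s in range(aln.n_sites)]
        )
        pos = np.zeros(aln.n_sites, dtype=bool)
        pos[N_CONS:] = True
        assert df["omega"][pos & variable].median() > 1.0
        assert df["omega"][~pos].median() < 0.5

    def test_invariant_site_at_lower_bound(self, sitewise_toy):
        df, aln, *_ = sitewise_toy
        codes = aln.encode()
        invariant = [
            s for s in range(aln.n_sites)
            if len(set(codes[:, s])) == 1 and codes[0, s] >= 0
        ]
        if invariant:
            assert df["omega"].iloc[invariant].max() < 0.01

    def test_duplicating_a_site_leaves_estimate_unchanged(self, sitewise_toy):
        df, aln, tree, m0 = sitewise_toy
        dup = aln.take_columns(list(range(aln.n_sites)) + [45])
        df2 = sitewise_omega(dup, tree, m0_fit=m0)
        assert df2["omega"].iloc[-1] == pytest.approx(
            df["omega"].iloc[45], rel=1e-9
        )
        assert df2["omega"].iloc[45] == pytest.approx(
            df["omega"].iloc[45], rel=1e-9
        )

    def test_all_gap_site_reported_missing(self, sitewise_toy):
        _, aln, tree, m0 = sitewise_toy
        rows = ["".join(r) + "---" for r in aln.codons]
        with_gap = codon_alignment_from_rows(list(aln.ids), rows)
        df = sitewise_omega(with_gap, tree, m0_fit=m0)
        assert np.isnan(df["omega"].iloc[-1])
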