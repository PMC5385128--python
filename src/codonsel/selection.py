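"""Selection inference: free-ratio dN/dS, the branch-site test of positive
selection, the Clade Model C vs M2a_rel test of selection divergence,
empirical-Bayes site posteriors, and site-wise omega.

Both likelihood-ratio tests use df = 1 against the chi-squared upper tail,
the conventional procedure for these model pairs (for the branch-site test
this is conservative, since the null fixes a parameter on the boundary; a
flag switches to the 50:50 point-mass/chi2 mixture null if wanted).
Significance defaults to alpha = 0.05 per gene with raw p-values reported;
Benjamini-Hochberg adjustment across genes is available but clearly
labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp

from .genetics import genetic_code
from .likelihood import FitResult, LikelihoodEngine, fit, omega_class_branch
from .model import estimate_frequencies, raw_rate_matrix, substitution_proportions
from .seqio import CodonAlignment
from .siteclass import OMEGA_MAX, OMEGA_MIN, get_model
from .tree import LabeledTree

#: LRT statistics more negative than this indicate a real optimizer failure
LRT_TOLERANCE = 1e-6


def chisq_pvalue(lrt: float, df: int = 1) -> float:
    """Upper-tail chi-squared probability of an LRT statistic.

    Values in [-LRT_TOLERANCE, 0) — optimizer noise on nested fits — are
    clamped to 0; more negative values raise.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if lrt < -LRT_TOLERANCE:
        raise ValueError(f"negative LRT statistic {lrt}")
    return float(scipy.stats.chi2.sf(max(lrt, 0.0), df))


def mixture_null_pvalue(lrt: float) -> float:
    """p-value under the 50:50 mixture of a point mass at 0 and chi2(1),
    the boundary-correct null for the branch-site test."""
    if lrt < -LRT_TOLERANCE:
        raise ValueError(f"negative LRT statistic {lrt}")
    lrt = max(lrt, 0.0)
    return float(0.5 * scipy.stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0


@dataclass
class TestResult:
    """One likelihood-ratio comparison of nested codon models."""

    gene: str
    model_alt: str
    model_null: str
    lnL_alt: float
    lnL_null: float
    df: int
    alpha: float = 0.05
    fit_alt: FitResult | None = field(default=None, repr=False)
    fit_null: FitResult | None = field(default=None, repr=False)
    mixture_null: bool = False

    @property
    def lrt(self) -> float:
        return 2.0 * (self.lnL_alt - self.lnL_null)

    @property
    def pvalue(self) -> float:
        if self.mixture_null:
            return mixture_null_pvalue(self.lrt)
        return chisq_pvalue(self.lrt, self.df)

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def to_row(self) -> dict:
        row = {
            "gene": self.gene,
            "model_alt": self.model_alt,
            "model_null": self.model_null,
            "lnL_alt": self.lnL_alt,
            "lnL_null": self.lnL_null,
            "LRT": max(self.lrt, 0.0),
            "df": self.df,
            "p": self.pvalue,
            "significant": int(self.significant),
        }
        if self.fit_alt is not None:
            desc = self.fit_alt
            for k in range(len(desc.proportions)):
                row[f"p{k}"] = desc.proportions[k]
            om = desc.omegas
            row["omega0"] = om[0, 0]
            if om.shape[0] > 1:
                row["omega1"] = om[1, 0]
            if om.shape[0] > 2:
                row["omega2"] = om[2, 0]
                row["omega3"] = om[2, 1]
        return row


@dataclass
class SitePosterior:
    """Per-site posterior membership in the selected/divergent class."""

    posteriors: np.ndarray  # (n_sites,) posterior of the focal class(es)
    class_posteriors: np.ndarray  # (n_sites, n_classes)
    threshold: float
    mode: str = "neb"

    @property
    def flagged_sites(self) -> np.ndarray:
        """0-based indices of sites above the flag threshold."""
        return np.flatnonzero(self.posteriors > self.threshold)

    def to_frame(self) -> pd.DataFrame:
        n_class = self.class_posteriors.shape[1]
        data = {"site": np.arange(1, len(self.posteriors) + 1)}
        for k in range(n_class):
            data[f"class{k}"] = self.class_posteriors[:, k]
        data["focal_posterior"] = self.posteriors
        data["flagged"] = (self.posteriors > self.threshold).astype(int)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# free-ratio model
# ---------------------------------------------------------------------------

@dataclass
class BranchRates:
    """Per-branch dN, dS and omega from the free-ratio model."""

    branch: str
    omega: float
    t: float
    dN: float
    dS: float
    foreground: bool
    converged: bool

    def to_row(self) -> dict:
        return {
            "branch": self.branch,
            "t": self.t,
            "omega": self.omega,
            "dN": self.dN,
            "dS": self.dS,
            "foreground": int(self.foreground),
        }


def branch_rates_from_fit(fr_fit: FitResult) -> list[BranchRates]:
    """Decompose a free-ratio fit into per-branch dN and dS.

    Mutational-opportunity convention: with Q scaled to one expected
    substitution per codon per unit length, a branch of length t at ratio
    omega_b accrues t*rho_N nonsynonymous and t*rho_S synonymous
    substitutions per codon, where (rho_N, rho_S) are the flux proportions
    at omega_b. The numbers of nonsynonymous/synonymous sites per codon are
    3*f_N and 3*f_S with (f_N, f_S) the flux proportions at omega = 1, so
    dN = t*rho_N/(3*f_N) and dS = t*rho_S/(3*f_S).
    """
    gc = genetic_code(fr_fit.code_id)
    f_n, f_s = substitution_proportions(fr_fit.kappa, 1.0, fr_fit.freqs, gc)
    tree = fr_fit.tree
    out = []
    for b, v in enumerate(tree.branch_nodes()):
        w = float(fr_fit.omegas[0, b])
        t = float(fr_fit.branch_lengths[b])
        rho_n, rho_s = substitution_proportions(fr_fit.kappa, w, fr_fit.freqs, gc)
        dn = t * rho_n / (3 * f_n) if f_n > 0 else 0.0
        ds = t * rho_s / (3 * f_s) if f_s > 0 else 0.0
        out.append(
            BranchRates(
                branch=tree.node_name(v),
                omega=w,
                t=t,
                dN=dn,
                dS=ds,
                foreground=tree.nodes[v].label == 1,
                converged=fr_fit.converged,
            )
        )
    return out


def free_ratio(
    aln: CodonAlignment,
    tree: LabeledTree,
    *,
    restarts: int = 1,
    seed: int = 0,
    m0_fit: FitResult | None = None,
    **fit_kw,
) -> tuple[list[BranchRates], FitResult]:
    """Fit the free-ratio model (independent omega per branch, shared
    kappa) and return per-branch rates."""
    if tree.n_leaves < 3:
        raise ValueError("free-ratio model needs >= 3 taxa")
    fr = fit(
        aln, tree, "free-ratio", restarts=restarts, seed=seed, m0_fit=m0_fit,
        **fit_kw,
    )
    return branch_rates_from_fit(fr), fr


# ---------------------------------------------------------------------------
# empirical-Bayes site posteriors
# ---------------------------------------------------------------------------

_FOCAL_CLASSES = {
    "branch-site-A-alt": (2, 3),  # classes 2a + 2b
    "branch-site-A-null": (2, 3),
    "CmC": (2,),
    "M2a_rel": (2,),
}


def site_class_posteriors(
    fit_result: FitResult,
    mode: str = "neb",
    threshold: float = 0.75,
    grid_points: int = 10,
) -> SitePosterior:
    """Posterior probability per site of the selected/divergent class.

    'neb' evaluates posteriors at the MLEs (exactly checkable by hand from
    the cached per-class site likelihoods). 'beb-grid' averages them over a
    discrete grid on the mixture proportions and the focal-class omega with
    a uniform prior over grid points, weighting each point by its data
    likelihood — a grid-averaged empirical-Bayes scheme that accounts for
    parameter uncertainty.
    """
    focal = _FOCAL_CLASSES.get(fit_result.model_name)
    if focal is None:
        focal = tuple(range(len(fit_result.proportions)))
    if mode == "neb":
        cp = fit_result.class_posteriors()
        return SitePosterior(
            posteriors=cp[:, list(focal)].sum(axis=1),
            class_posteriors=cp,
            threshold=threshold,
            mode="neb",
        )
    if mode != "beb-grid":
        raise ValueError(f"unknown posterior mode {mode!r}")
    return _beb_grid(fit_result, focal, threshold, grid_points)


def _beb_grid(fit_result, focal, threshold, grid_points):
    """Grid-averaged posteriors: stick-breaking proportion coordinates on a
    uniform grid in (0,1)^2 and the focal-class omega on a log grid, other
    parameters held at their MLEs."""
    if fit_result.aln is None:
        raise ValueError("fit result does not retain its alignment")
    model = get_model(fit_result.model_name)
    theta0 = dict(fit_result.theta)
    theta0["kappa"] = fit_result.kappa
    eng = LikelihoodEngine(fit_result.aln, fit_result.tree, fit_result.freqs)

    omega_name = "omega2" if "omega2" in theta0 else None
    if fit_result.model_name == "CmC":
        omega_name = "omega3"  # the foreground/divergent ratio
    lo = 1.0 if fit_result.model_name.startswith("branch-site") else OMEGA_MIN
    omega_grid = (
        np.exp(np.linspace(np.log(max(lo, 1e-3)), np.log(50.0), grid_points))
        if omega_name
        else [None]
    )
    q_grid = (np.arange(grid_points) + 0.5) / grid_points

    # branch-rate normalization held at the MLE throughout the grid, so the
    # cached per-class site likelihoods stay valid as proportions vary
    om0 = omega_class_branch(model, theta0, eng.labels, eng.n_branches)
    scales0 = eng.branch_scales(
        theta0["kappa"], om0, fit_result.proportions
    )
    cache: dict[float, np.ndarray] = {}

    def class_ll(omega_val):
        key = -1.0 if omega_val is None else float(omega_val)
        if key not in cache:
            th = dict(theta0)
            if omega_val is not None:
                th[omega_name] = float(omega_val)
            om = omega_class_branch(model, th, eng.labels, eng.n_branches)
            cache[key] = eng.class_site_logliks(
                th["kappa"], om, fit_result.branch_lengths, scales=scales0
            )
        return cache[key]

    n_sites = fit_result.n_sites
    n_class = len(fit_result.proportions)
    log_marg = []
    post_stack = []
    for w in omega_grid:
        cl = class_ll(w)
        for q0 in q_grid:
            for q1 in q_grid:
                th = dict(theta0)
                th["q0"], th["q1"] = q0, q1
                p = model.proportions(th)
                with np.errstate(divide="ignore"):
                    joint = cl + np.log(p)[:, None]
                site_log = logsumexp(joint, axis=0)
                log_marg.append(site_log.sum())
                cp = np.exp(joint - site_log[None, :])
                post_stack.append(cp[list(focal), :].sum(axis=0))
    log_marg = np.asarray(log_marg)
    wts = np.exp(log_marg - logsumexp(log_marg))
    posteriors = (wts[:, None] * np.asarray(post_stack)).sum(axis=0)
    # class-level posteriors averaged the same way, for the report
    cp_full = np.zeros((n_class, n_sites))
    i = 0
    for w in omega_grid:
        cl = class_ll(w)
        for q0 in q_grid:
            for q1 in q_grid:
                th = dict(theta0)
                th["q0"], th["q1"] = q0, q1
                p = model.proportions(th)
                with np.errstate(divide="ignore"):
                    joint = cl + np.log(p)[:, None]
                cp_full += wts[i] * np.exp(
                    joint - logsumexp(joint, axis=0, keepdims=True)
                )
                i += 1
    return SitePosterior(
        posteriors=posteriors,
        class_posteriors=cp_full.T,
        threshold=threshold,
        mode="beb-grid",
    )


# ---------------------------------------------------------------------------
# the two hypothesis tests
# ---------------------------------------------------------------------------

def _require_foreground(tree: LabeledTree):
    if not tree.foreground_nodes():
        raise ValueError(
            "tree has no foreground branch; label one with '#1' or "
            "set_foreground()"
        )


def branch_site_test(
    aln: CodonAlignment,
    tree: LabeledTree,
    *,
    gene: str = "gene",
    alpha: float = 0.05,
    posterior_mode: str = "neb",
    posterior_threshold: float = 0.75,
    mixture_null: bool = False,
    restarts: int = 2,
    seed: int = 0,
    m0_fit: FitResult | None = None,
    **fit_kw,
) -> tuple[TestResult, SitePosterior]:
    """Branch-site test of positive selection on the foreground lineage.

    Fits branch-site model A alternative (omega2 >= 1 free) and null
    (omega2 = 1); LRT with df = 1. Site posteriors are the summed
    membership of the positively selected classes (2a + 2b) under the
    alternative fit.
    """
    _require_foreground(tree)
    if m0_fit is None:
        m0_fit = fit(aln, tree, "M0", restarts=1, seed=seed, **fit_kw)
    null = fit(
        aln, tree, "branch-site-A-null",
        m0_fit=m0_fit, restarts=restarts, seed=seed + 1, **fit_kw,
    )
    # fit the alternative from two start regimes: the null optimum (a valid
    # alt point with omega2 at its bound of 1, guaranteeing nesting up to
    # optimizer noise) and the default dispersed starts (which can escape
    # the omega2 = 1 boundary when the null optimum is a trap)
    alt_start = dict(null.theta)
    alt_start["omega2"] = 1.0
    alt_a = fit(
        aln, tree, "branch-site-A-alt",
        m0_fit=m0_fit, restarts=1, seed=seed, start=alt_start, **fit_kw,
    )
    alt_b = fit(
        aln, tree, "branch-site-A-alt",
        m0_fit=m0_fit, restarts=max(1, restarts - 1), seed=seed + 7,
        **fit_kw,
    )
    alt = alt_a if alt_a.lnL >= alt_b.lnL else alt_b
    res = TestResult(
        gene=gene,
        model_alt=alt.model_name,
        model_null=null.model_name,
        lnL_alt=max(alt.lnL, null.lnL),
        lnL_null=null.lnL,
        df=1,
        alpha=alpha,
        fit_alt=alt,
        fit_null=null,
        mixture_null=mixture_null,
    )
    post = site_class_posteriors(
        alt, mode=posterior_mode, threshold=posterior_threshold
    )
    return res, post


def clade_model_test(
    aln: CodonAlignment,
    tree: LabeledTree,
    *,
    gene: str = "gene",
    alpha: float = 0.05,
    posterior_mode: str = "neb",
    posterior_threshold: float = 0.75,
    restarts: int = 2,
    seed: int = 0,
    m0_fit: FitResult | None = None,
    **fit_kw,
) -> tuple[TestResult, SitePosterior]:
    """Clade Model C vs M2a_rel test of selection divergence between the
    foreground and background clades; LRT with df = 1. Sites whose
    divergent-class posterior exceeds the threshold (default 0.75) are
    flagged."""
    _require_foreground(tree)
    if m0_fit is None:
        m0_fit = fit(aln, tree, "M0", restarts=1, seed=seed, **fit_kw)
    null = fit(
        aln, tree, "M2a_rel", m0_fit=m0_fit, restarts=restarts, seed=seed,
        **fit_kw,
    )
    # fit CmC from two start regimes: the null optimum with omega3 = omega2
    # (a valid CmC point, guaranteeing lnL_alt >= lnL_null) and the default
    # dispersed starts, which can escape degenerate null optima
    cmc_start = dict(null.theta)
    cmc_start["omega3"] = cmc_start.get("omega2", 1.0)
    alt_a = fit(
        aln, tree, "CmC",
        m0_fit=m0_fit, restarts=1, seed=seed + 1, start=cmc_start, **fit_kw,
    )
    alt_b = fit(
        aln, tree, "CmC",
        m0_fit=m0_fit, restarts=max(1, restarts - 1), seed=seed + 7, **fit_kw,
    )
    alt = alt_a if alt_a.lnL >= alt_b.lnL else alt_b
    res = TestResult(
        gene=gene,
        model_alt=alt.model_name,
        model_null=null.model_name,
        lnL_alt=max(alt.lnL, null.lnL),
        lnL_null=null.lnL,
        df=1,
        alpha=alpha,
        fit_alt=alt,
        fit_null=null,
    )
    post = site_class_posteriors(
        alt, mode=posterior_mode, threshold=posterior_threshold
    )
    return res, post


# ---------------------------------------------------------------------------
# site-wise omega
# ---------------------------------------------------------------------------

def sitewise_omega(
    aln: CodonAlignment,
    tree: LabeledTree,
    m0_fit: FitResult | None = None,
    *,
    coarse: int = 25,
    refine: int = 17,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site ML omega with kappa and branch lengths fixed from M0, and
    the per-site LRT against omega = 1.

    The 1-D profile over omega is maximized on a two-stage log grid
    (a coarse sweep over [1e-6, 999] then a finer sweep bracketing the
    coarse optimum), which shares the expensive transition matrices across
    all sites. All-gap sites are reported as missing (NaN).
    """
    if m0_fit is None:
        m0_fit = fit(aln, tree, "M0", restarts=1, seed=seed)
    eng = LikelihoodEngine(aln, m0_fit.tree, m0_fit.freqs)
    # calibrate every candidate-omega matrix at the M0 rate, so branch
    # lengths keep their M0 meaning and omega > 1 sites genuinely run fast
    _, mu0 = raw_rate_matrix(
        m0_fit.kappa, m0_fit.theta["omega"], m0_fit.freqs,
        genetic_code(m0_fit.code_id),
    )
    scales = np.full(eng.n_branches, mu0)

    def logliks_at(omegas: np.ndarray) -> np.ndarray:
        """(n_omega, n_sites) log likelihood of each site at each omega."""
        om_cb = np.repeat(
            np.asarray(omegas)[:, None], eng.n_branches, axis=1
        )
        return eng.class_site_logliks(
            m0_fit.kappa, om_cb, m0_fit.branch_lengths, scales=scales
        )

    grid1 = np.exp(np.linspace(np.log(OMEGA_MIN), np.log(OMEGA_MAX), coarse))
    ll1 = logliks_at(grid1)
    best1 = ll1.argmax(axis=0)
    # bracket and refine per distinct bracket
    lo = grid1[np.maximum(best1 - 1, 0)]
    hi = grid1[np.minimum(best1 + 1, coarse - 1)]
    n_sites = aln.n_sites
    omega_hat = np.empty(n_sites)
    lnl_hat = np.empty(n_sites)
    for bracket in np.unique(best1):
        sites = np.flatnonzero(best1 == bracket)
        g = np.exp(
            np.linspace(
                np.log(lo[sites[0]]), np.log(hi[sites[0]]), refine
            )
        )
        ll2 = logliks_at(g)[:, sites]
        arg = ll2.argmax(axis=0)
        omega_hat[sites] = g[arg]
        lnl_hat[sites] = ll2[arg, np.arange(len(sites))]
    lnl_neutral = logliks_at(np.array([1.0]))[0]
    lrt = np.maximum(2.0 * (lnl_hat - lnl_neutral), 0.0)
    pvals = scipy.stats.chi2.sf(lrt, 1)

    codes = aln.encode()
    all_gap = (codes < 0).all(axis=0)
    df = pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "omega": omega_hat,
            "lnL": lnl_hat,
            "LRT_vs_neutral": lrt,
            "p": pvals,
        }
    )
    df.loc[all_gap, ["omega", "lnL", "LRT_vs_neutral", "p"]] = np.nan
    return df


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def results_table(results: list[TestResult], adjust: bool = False) -> pd.DataFrame:
    """Per-gene report mirroring the standard selection-table layout.

    With adjust=True a Benjamini-Hochberg adjusted p column (clearly
    labeled 'p_BH') is appended across the listed genes.
    """
    df = pd.DataFrame([r.to_row() for r in results])
    if adjust and len(df):
        p = df["p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.clip(adj, 0, 1)
        df["p_BH"] = out
    return df
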