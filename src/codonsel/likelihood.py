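"""Phylogenetic likelihood engine for site-class codon models.

Site likelihoods are computed by Felsenstein pruning, vectorized over
alignment columns and site classes, with per-node rescaling to avoid
underflow. Maximum-likelihood fitting runs bounded quasi-Newton (L-BFGS-B)
on transformed parameters: log scale for kappa, omegas and branch lengths,
logit scale for stick-breaking mixture coordinates. Mixture likelihoods are
multimodal, so fits restart from dispersed seeded starting points and keep
the best.

Branch-length strategy: M0 (one-ratio) fits optimize branch lengths jointly
with kappa and omega; site-class models then hold those branch lengths
fixed by default (optionally with a single multiplicative rescale, or full
joint optimization on request). This two-stage scheme is a documented,
cheaper approximation to re-optimizing every length under every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import logsumexp

from .genetics import genetic_code
from .model import EigenRateMatrix, estimate_frequencies, raw_rate_matrix
from .seqio import CodonAlignment
from .siteclass import Param, SiteClassModel, get_model
from .tree import LabeledTree

_TINY = 1e-300
_BL_MIN, _BL_MAX = 1e-8, 60.0


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Binds an encoded alignment to a tree topology and evaluates
    per-class site log-likelihoods for arbitrary (kappa, omega, lengths)."""

    def __init__(self, aln: CodonAlignment, tree: LabeledTree, freqs: np.ndarray):
        self.code = genetic_code(aln.code_id)
        self.n_states = self.code.n_states
        self.tree = tree
        self.pi = np.asarray(freqs, dtype=float)
        # data nodes are nodes named after alignment rows; normally the
        # leaves, but a rerooted tree may place an observed taxon at the root
        row_of = {sid: i for i, sid in enumerate(aln.ids)}
        data_nodes = [n.index for n in tree.nodes if n.name in row_of]
        named = {tree.nodes[v].name for v in data_nodes}
        if named != set(aln.ids) or any(
            not tree.nodes[v].children and tree.nodes[v].name not in row_of
            for v in tree.postorder()
        ):
            raise ValueError(
                "tree leaves and alignment ids differ: "
                f"{sorted(named ^ set(aln.ids))}"
            )
        codes = aln.encode()
        self.n_sites = aln.n_sites
        self.postorder = tree.postorder()
        self.branch_nodes = tree.branch_nodes()
        self.branch_index = {v: b for b, v in enumerate(self.branch_nodes)}
        self.labels = np.array(
            [tree.nodes[v].label for v in self.branch_nodes], dtype=np.intp
        )
        self.lengths0 = np.array(
            [tree.nodes[v].length or 0.0 for v in self.branch_nodes]
        )
        # observed-state partial vectors (n_sites, n_states); unknown -> ones
        self.leaf_partials: dict[int, np.ndarray] = {}
        for v in data_nodes:
            states = codes[row_of[tree.nodes[v].name]]
            part = np.zeros((self.n_sites, self.n_states))
            known = states >= 0
            part[known, states[known]] = 1.0
            part[~known, :] = 1.0
            self.leaf_partials[v] = part

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def _eigen_systems(self, kappa: float, omegas) -> dict:
        """Raw-matrix eigen systems and expected rates, per unique omega."""
        out = {}
        for w in set(float(x) for x in np.ravel(omegas)):
            Q, mu = raw_rate_matrix(kappa, w, self.pi, self.code)
            out[w] = (EigenRateMatrix(Q, self.pi), mu)
        return out

    def branch_scales(
        self, kappa: float, omega_cb: np.ndarray, weights: np.ndarray
    ) -> np.ndarray:
        """Per-branch rate normalizer: the mixture-weighted expected rate
        of the raw matrices active on that branch, so a branch length is
        the expected number of substitutions per codon averaged over site
        classes (classes with higher omega evolve proportionally faster)."""
        eigs = self._eigen_systems(kappa, omega_cb)
        mus = np.empty(omega_cb.shape)
        for (k, b), w in np.ndenumerate(omega_cb):
            mus[k, b] = eigs[float(w)][1]
        return np.asarray(weights) @ mus

    def transition_stack(
        self,
        kappa: float,
        omega_cb: np.ndarray,
        lengths: np.ndarray,
        scales: np.ndarray,
    ) -> np.ndarray:
        """(n_class, n_branch, m, m) transition matrices
        P_kb = exp(Q_raw(omega_kb) * t_b / scale_b); eigen systems are
        shared across branches/classes with equal omega."""
        C, B = omega_cb.shape
        m = self.n_states
        P = np.empty((C, B, m, m))
        eigs = self._eigen_systems(kappa, omega_cb)
        cache: dict[tuple[float, float], np.ndarray] = {}
        for k in range(C):
            for b in range(B):
                t_eff = lengths[b] / scales[b]
                key = (float(omega_cb[k, b]), t_eff)
                mat = cache.get(key)
                if mat is None:
                    mat = cache[key] = eigs[key[0]][0].transition(t_eff)
                P[k, b] = mat
        return P

    def class_site_logliks(
        self,
        kappa: float,
        omega_cb: np.ndarray,
        lengths: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        scales: np.ndarray | None = None,
    ) -> np.ndarray:
        """Log site likelihoods per class: array (n_class, n_sites).

        `scales` divides branch lengths before exponentiation; by default
        it is the mixture-weighted expected rate per branch (see
        branch_scales), with uniform weights if none are given.
        """
        if lengths is None:
            lengths = self.lengths0
        lengths = np.asarray(lengths)
        if scales is None:
            if weights is None:
                weights = np.full(omega_cb.shape[0], 1.0 / omega_cb.shape[0])
            scales = self.branch_scales(kappa, omega_cb, weights)
        P = self.transition_stack(kappa, omega_cb, lengths, np.asarray(scales))
        Pt = np.swapaxes(P, -1, -2)
        C = P.shape[0]
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((C, self.n_sites))
        for v in self.postorder:
            node = self.tree.nodes[v]
            if not node.children:
                continue
            prod = None
            for c in node.children:
                child_part = partial.pop(c, None)
                if child_part is None:
                    child_part = self.leaf_partials[c]
                msg = np.matmul(child_part, Pt[:, self.branch_index[c]])
                prod = msg if prod is None else prod * msg
            if v in self.leaf_partials:  # observed taxon at an internal node
                prod = prod * self.leaf_partials[v]
            scale = prod.max(axis=-1, keepdims=True)
            np.clip(scale, _TINY, None, out=scale)
            prod = prod / scale
            logscale += np.log(scale[..., 0])
            partial[v] = prod
        root = self.postorder[-1]
        if root not in partial:  # single-taxon tree: root is the data leaf
            partial[root] = np.broadcast_to(
                self.leaf_partials[root], (C,) + self.leaf_partials[root].shape
            )
        root_part = partial[root]
        site_lik = root_part @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(np.clip(site_lik, _TINY, None)) + logscale

    def mixture_loglik_value(
        self,
        kappa: float,
        weights: np.ndarray,
        omega_cb: np.ndarray,
        lengths: np.ndarray | None = None,
    ) -> float:
        cl = self.class_site_logliks(kappa, omega_cb, lengths, weights=weights)
        with np.errstate(divide="ignore"):
            logw = np.log(weights)[:, None]
        return float(logsumexp(cl + logw, axis=0).sum())


def omega_class_branch(
    model: SiteClassModel, theta: dict, labels: np.ndarray, n_branch: int
) -> np.ndarray:
    """Expand a model's theta into the (n_class, n_branch) omega grid."""
    if model.per_branch:
        return np.array(
            [theta[f"omega_b{b}"] for b in range(n_branch)]
        )[None, :]
    return model.omegas(theta)[:, labels]


def mixture_loglik(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: SiteClassModel | str,
    theta: dict,
    freqs: np.ndarray | None = None,
    freq_scheme: str = "F3x4",
) -> float:
    """ln L = sum_sites log sum_classes p_k L_site(k), at the given theta.

    theta must contain 'kappa' plus the model's free parameters.
    """
    if isinstance(model, str):
        model = get_model(model)
    if freqs is None:
        freqs = estimate_frequencies(aln, freq_scheme)
    eng = LikelihoodEngine(aln, tree, freqs)
    omega_cb = omega_class_branch(model, theta, eng.labels, eng.n_branches)
    return eng.mixture_loglik_value(
        theta["kappa"], model.proportions(theta), omega_cb
    )


def column_likelihood(
    tree: LabeledTree,
    states: dict[str, int | None],
    P_by_node: dict[int, np.ndarray],
    pi: np.ndarray,
) -> float:
    """Likelihood of one alignment column by plain recursive pruning.

    `states` maps leaf names to codon state indices (None = gap/missing,
    contributing an all-ones partial vector); `P_by_node` maps each
    non-root node index to its branch transition matrix.
    """
    m = len(pi)

    def down(v: int) -> np.ndarray:
        node = tree.nodes[v]
        if not node.children:
            s = states[node.name]
            part = np.ones(m) if s is None else np.eye(m)[s]
            return part
        out = np.ones(m)
        for c in node.children:
            out = out * (P_by_node[c] @ down(c))
        return out

    return float(np.asarray(pi) @ down(tree.root))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one site-class model on one dataset."""

    model_name: str
    lnL: float
    theta: dict
    kappa: float
    proportions: np.ndarray
    omegas: np.ndarray  # (n_class, 2) bg/fg; free-ratio: (1, n_branch)
    branch_lengths: np.ndarray  # postorder branch order
    tree: LabeledTree
    freqs: np.ndarray
    converged: bool
    n_restarts: int
    class_site_loglik: np.ndarray  # (n_class, n_sites)
    code_id: int = 1
    aln: CodonAlignment | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return self.class_site_loglik.shape[1]

    def class_posteriors(self) -> np.ndarray:
        """(n_sites, n_class) posterior class membership at the MLEs."""
        with np.errstate(divide="ignore"):
            logw = np.log(self.proportions)[:, None]
        joint = self.class_site_loglik + logw
        joint -= logsumexp(joint, axis=0, keepdims=True)
        return np.exp(joint).T

    def to_report(self) -> str:
        """Tab-separated parameter report (round-trips via from_report)."""
        lines = ["key\tvalue", f"model\t{self.model_name}"]
        lines.append(f"lnL\t{self.lnL:.10f}")
        lines.append(f"kappa\t{self.kappa:.10g}")
        lines.append(f"converged\t{int(self.converged)}")
        lines.append(f"n_restarts\t{self.n_restarts}")
        for k, v in sorted(self.theta.items()):
            lines.append(f"param:{k}\t{v:.10g}")
        for b, t in enumerate(self.branch_lengths):
            name = self.tree.node_name(self.tree.branch_nodes()[b])
            lines.append(f"brlen:{name}\t{t:.10g}")
        return "\n".join(lines) + "\n"

    @staticmethod
    def parse_report(text: str) -> dict:
        out: dict = {"params": {}, "brlens": {}}
        for line in text.strip().splitlines()[1:]:
            key, val = line.split("\t")
            if key.startswith("param:"):
                out["params"][key[6:]] = float(val)
            elif key.startswith("brlen:"):
                out["brlens"][key[6:]] = float(val)
            elif key == "model":
                out["model"] = val
            elif key in ("lnL", "kappa"):
                out[key] = float(val)
            elif key in ("converged", "n_restarts"):
                out[key] = int(val)
        return out


def _to_internal(value: float, p: Param) -> float:
    if p.transform == "log":
        return float(np.log(np.clip(value, p.lower, p.upper)))
    v = np.clip(value, p.lower + 1e-12, p.upper - 1e-12)
    z = (v - p.lower) / (p.upper - p.lower)
    return float(np.log(z / (1 - z)))


def _from_internal(x: float, p: Param) -> float:
    if p.transform == "log":
        return float(np.exp(x))
    z = 1.0 / (1.0 + np.exp(-x))
    return float(p.lower + z * (p.upper - p.lower))


def _internal_bounds(p: Param) -> tuple[float, float]:
    if p.transform == "log":
        return (np.log(p.lower), np.log(p.upper))
    return (-16.0, 16.0)


def fit(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: SiteClassModel | str,
    *,
    freq_scheme: str = "F3x4",
    freqs: np.ndarray | None = None,
    branch_mode: str = "auto",
    m0_fit: FitResult | None = None,
    optimize_scale: bool = False,
    restarts: int = 3,
    seed: int = 0,
    maxiter: int = 400,
    start: dict | None = None,
) -> FitResult:
    """Maximize the mixture log-likelihood of a site-class model.

    branch_mode: 'joint' optimizes every branch length (always the case for
    M0), 'fixed' keeps the tree's lengths, 'auto' (default) fits M0 first
    and holds its branch lengths fixed for site-class models (pass
    `optimize_scale=True` to add a single multiplicative length rescale).
    Restarts perturb the starting point; the best optimum is returned, with
    non-convergence reported in the `converged` flag.
    """
    if isinstance(model, str):
        model = get_model(model)
    if freqs is None:
        freqs = estimate_frequencies(aln, freq_scheme)
    freqs = np.asarray(freqs, dtype=float)

    if branch_mode == "auto":
        branch_mode = "joint" if model.name == "M0" else "m0"
    work_tree = tree.copy()
    if branch_mode == "m0" and model.name != "M0":
        if m0_fit is None:
            m0_fit = fit(
                aln,
                tree,
                "M0",
                freqs=freqs,
                branch_mode="joint",
                restarts=1,
                seed=seed,
                maxiter=maxiter,
            )
        work_tree = m0_fit.tree.copy()
    eng = LikelihoodEngine(aln, work_tree, freqs)

    params: list[Param] = [Param("kappa", 2.0, 1e-3, 999.0)]
    params.extend(model.params())
    if model.per_branch:
        params.extend(
            Param(f"omega_b{b}", 0.2, 1e-6, 999.0)
            for b in range(eng.n_branches)
        )
    fit_lengths = branch_mode == "joint"
    if fit_lengths:
        for b in range(eng.n_branches):
            init = float(np.clip(eng.lengths0[b], 1e-3, _BL_MAX))
            params.append(Param(f"t{b}", init, _BL_MIN, _BL_MAX))
    elif optimize_scale:
        params.append(Param("blscale", 1.0, 0.02, 50.0))

    if start:
        params = [
            Param(p.name, start.get(p.name, p.init), p.lower, p.upper, p.transform)
            for p in params
        ]

    base_lengths = eng.lengths0.copy()

    def unpack(x: np.ndarray) -> tuple[dict, np.ndarray]:
        theta = {
            p.name: _from_internal(xi, p) for xi, p in zip(x, params)
        }
        if fit_lengths:
            lengths = np.array(
                [theta[f"t{b}"] for b in range(eng.n_branches)]
            )
        elif optimize_scale:
            lengths = base_lengths * theta["blscale"]
        else:
            lengths = base_lengths
        return theta, lengths

    def negloglik(x: np.ndarray) -> float:
        theta, lengths = unpack(x)
        try:
            omega_cb = omega_class_branch(model, theta, eng.labels, eng.n_branches)
            val = eng.mixture_loglik_value(
                theta["kappa"], model.proportions(theta), omega_cb, lengths
            )
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    x0 = np.array([_to_internal(p.init, p) for p in params])
    bounds = [_internal_bounds(p) for p in params]
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        xs = x0.copy()
        if r > 0:
            jitter = rng.normal(0.0, 0.6, size=xs.shape)
            xs = np.clip(
                xs + jitter,
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        res = scipy.optimize.minimize(
            negloglik,
            xs,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 100000},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta, lengths = unpack(best.x)
    omega_cb = omega_class_branch(model, theta, eng.labels, eng.n_branches)
    class_ll = eng.class_site_logliks(
        theta["kappa"], omega_cb, lengths, weights=model.proportions(theta)
    )
    out_tree = work_tree.copy()
    for b, v in enumerate(out_tree.branch_nodes()):
        out_tree.nodes[v].length = float(lengths[b])
    model_theta = {
        k: v
        for k, v in theta.items()
        if not k.startswith("t") or not k[1:].isdigit()
    }
    omegas = (
        omega_cb
        if model.per_branch
        else model.omegas(theta)
    )
    return FitResult(
        model_name=model.name,
        lnL=float(-best.fun),
        theta=model_theta,
        kappa=theta["kappa"],
        proportions=model.proportions(theta),
        omegas=np.asarray(omegas, dtype=float),
        branch_lengths=np.asarray(lengths, dtype=float),
        tree=out_tree,
        freqs=freqs,
        converged=bool(best.success),
        n_restarts=max(1, restarts),
        class_site_loglik=class_ll,
        code_id=aln.code_id,
        aln=aln,
    )


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------

def ancestral_posteriors(fit_result: FitResult, node: int | str) -> np.ndarray:
    """Marginal posterior P(codon state at `node` | data, theta-hat), one
    row per site (rows sum to 1).

    Computed by the up-down algorithm per site class, then averaged over
    classes with the per-site class posteriors. For a leaf with an observed
    codon this is a point mass on the observed state.
    """
    if not fit_result.converged:
        warnings.warn("ancestral reconstruction from a non-converged fit")
    aln, tree = fit_result.aln, fit_result.tree
    if aln is None:
        raise ValueError("fit result does not retain its alignment")
    eng = LikelihoodEngine(aln, tree, fit_result.freqs)
    v = tree.find(node) if isinstance(node, str) else int(node)
    if v < 0 or v >= len(tree.nodes):
        raise KeyError(f"unknown node {node!r}")

    model = get_model(fit_result.model_name)
    theta = dict(fit_result.theta)
    theta["kappa"] = fit_result.kappa
    omega_cb = omega_class_branch(model, theta, eng.labels, eng.n_branches)
    scales = eng.branch_scales(
        fit_result.kappa, omega_cb, fit_result.proportions
    )
    P = eng.transition_stack(
        fit_result.kappa, omega_cb, fit_result.branch_lengths, scales
    )
    Pt = np.swapaxes(P, -1, -2)
    C = P.shape[0]
    m = eng.n_states
    S = eng.n_sites

    # downward (tip-side) partials for every node, per class
    down: dict[int, np.ndarray] = {}
    for u in eng.postorder:
        nd = tree.nodes[u]
        if not nd.children:
            down[u] = np.broadcast_to(
                eng.leaf_partials[u], (C, S, m)
            ).copy()
            continue
        prod = None
        for c in nd.children:
            msg = np.matmul(down[c], Pt[:, eng.branch_index[c]])
            prod = msg if prod is None else prod * msg
        if u in eng.leaf_partials:
            prod = prod * eng.leaf_partials[u]
        scale = np.clip(prod.max(axis=-1, keepdims=True), _TINY, None)
        down[u] = prod / scale

    # upward (root-side) partials, preorder; root carries pi
    up: dict[int, np.ndarray] = {
        tree.root: np.broadcast_to(eng.pi, (C, S, m)).copy()
    }
    for u in tree.preorder():
        nd = tree.nodes[u]
        for c in nd.children:
            prod = up[u]
            if u in eng.leaf_partials:  # parent itself carries observed data
                prod = prod * eng.leaf_partials[u]
            for sib in nd.children:
                if sib == c:
                    continue
                msg = np.matmul(down[sib], Pt[:, eng.branch_index[sib]])
                prod = prod * msg
            out = np.matmul(prod, P[:, eng.branch_index[c]])
            scale = np.clip(out.max(axis=-1, keepdims=True), _TINY, None)
            up[c] = out / scale

    joint = up[v] * down[v]  # (C, S, m), unnormalized within class
    class_w = fit_result.class_posteriors().T  # (C, S)
    per_class = joint / np.clip(joint.sum(axis=-1, keepdims=True), _TINY, None)
    post = (class_w[:, :, None] * per_class).sum(axis=0)
    return post / post.sum(axis=1, keepdims=True)


def map_ancestral_codons(
    fit_result: FitResult, node: int | str
) -> list[tuple[str, str, float]]:
    """Per site: (MAP codon, its amino-acid translation, posterior)."""
    gc = genetic_code(fit_result.code_id)
    post = ancestral_posteriors(fit_result, node)
    best = post.argmax(axis=1)
    return [
        (gc.sense_codons[b], gc.translate_codon(gc.sense_codons[b]), float(post[s, b]))
        for s, b in enumerate(best)
    ]
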