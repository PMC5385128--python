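"""Goldman–Yang-style codon rate matrices and transition probabilities.

The instantaneous rate from codon i to codon j is zero unless the codons
differ at exactly one nucleotide position and j is a sense codon; otherwise
it is proportional to the target frequency pi_j, multiplied by kappa for a
transition and by omega for a nonsynonymous change. Matrices are rescaled
to one expected substitution per codon per unit branch length, so branch
lengths are in expected substitutions per codon.

The chain is time-reversible (detailed balance pi_i q_ij = pi_j q_ji holds
by construction), which we exploit: P(t) = exp(Qt) is computed through the
eigen-decomposition of the symmetrized matrix D^{1/2} Q D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genetics import GeneticCode, genetic_code, neighbor_structure

#: floor applied to equilibrium frequencies before building Q, to keep the
#: symmetrization numerically sane when a codon is absent from the data
FREQ_FLOOR = 1e-10


@dataclass(frozen=True)
class CodonModelParams:
    """kappa (ts/tv rate ratio), omega (dN/dS), and equilibrium codon
    frequencies over the sense codons."""

    kappa: float
    omega: float
    freqs: np.ndarray

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be >= 0 and sum to 1")
        object.__setattr__(self, "freqs", f)


def _regularized(freqs: np.ndarray) -> np.ndarray:
    f = np.maximum(np.asarray(freqs, dtype=float), FREQ_FLOOR)
    return f / f.sum()


def raw_rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, code: int | GeneticCode = 1
) -> tuple[np.ndarray, float]:
    """Unnormalized codon rate matrix and its expected rate mu.

    mu = -sum_i pi_i q_ii is the expected number of substitutions per codon
    per unit time under the raw matrix; site-class mixtures are rescaled by
    a mixture-weighted mu so that classes with higher omega genuinely
    evolve faster (only the average rate is pinned to the branch length).
    """
    gc = code if isinstance(code, GeneticCode) else genetic_code(code)
    rows, cols, ts, nonsyn = neighbor_structure(gc.id)
    pi = _regularized(freqs)
    m = gc.n_states
    rate = pi[cols].copy()
    rate[ts] *= kappa
    rate[nonsyn] *= omega
    Q = np.zeros((m, m))
    Q[rows, cols] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = float(-(pi * np.diag(Q)).sum())
    return Q, mu


def build_rate_matrix(
    params: CodonModelParams, code: int | GeneticCode = 1
) -> np.ndarray:
    """Scaled codon rate matrix Q (rows sum to 0, -sum pi_i q_ii = 1)."""
    Q, mu = raw_rate_matrix(params.kappa, params.omega, params.freqs, code)
    if mu > 0:
        Q /= mu
    return Q


def substitution_proportions(
    kappa: float, omega: float, freqs: np.ndarray, code: int | GeneticCode = 1
) -> tuple[float, float]:
    """(rho_N, rho_S): proportions of the equilibrium substitution flux that
    are nonsynonymous and synonymous at the given parameters."""
    gc = code if isinstance(code, GeneticCode) else genetic_code(code)
    rows, cols, ts, nonsyn = neighbor_structure(gc.id)
    pi = _regularized(freqs)
    rate = pi[cols].copy()
    rate[ts] *= kappa
    rate[nonsyn] *= omega
    flux = pi[rows] * rate
    total = flux.sum()
    if total == 0:
        return 0.0, 0.0
    rho_n = flux[nonsyn].sum() / total
    return rho_n, 1.0 - rho_n


class EigenRateMatrix:
    """Eigen-decomposition of a reversible Q for fast P(t) evaluation.

    Using D = diag(pi), B = D^{1/2} Q D^{-1/2} is symmetric; with
    B = V diag(lam) V', P(t) = D^{-1/2} V diag(exp(lam t)) V' D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        pi = _regularized(freqs)
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        lam, V = np.linalg.eigh(B)
        self.eigenvalues = lam
        self.U = V / d[:, None]
        self.Uinv = V.T * d[None, :]
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        """P(t); rows sum to 1, tiny negative entries clipped to 0."""
        if t < 0:
            raise ValueError("branch length t must be >= 0")
        P = (self.U * np.exp(self.eigenvalues * t)) @ self.Uinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(
    Q: np.ndarray, t: float, freqs: np.ndarray | None = None
) -> np.ndarray:
    """P(t) = exp(Qt).

    With `freqs` given, uses the reversible eigen route; otherwise falls
    back to generic scaling-and-squaring (scipy expm). The two routes agree
    to ~1e-9 on any valid reversible Q.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if freqs is not None:
        return EigenRateMatrix(Q, freqs).transition(t)
    P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def estimate_frequencies(aln, scheme: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies from a codon alignment.

    Schemes: 'F3x4' (position-specific nucleotide frequencies, the codeml
    default), 'F1x4' (pooled nucleotide frequencies), 'equal' (1/61), and
    'empirical-codon' (observed codon proportions). All renormalized over
    the sense codons.
    """
    gc = genetic_code(aln.code_id)
    m = gc.n_states
    if aln.n_taxa == 0 or aln.n_sites == 0:
        raise ValueError("empty alignment")
    if scheme == "equal":
        return np.full(m, 1.0 / m)

    codes = aln.encode()
    observed = codes[codes >= 0]
    if observed.size == 0:
        raise ValueError("alignment contains no sense codons")
    if scheme == "empirical-codon":
        counts = np.bincount(observed, minlength=m).astype(float)
        return counts / counts.sum()

    # nucleotide counts by codon position over sense-codon states
    base_idx = {b: k for k, b in enumerate("ACGT")}
    pos_counts = np.zeros((3, 4))
    for state in observed:
        codon = gc.sense_codons[state]
        for p, b in enumerate(codon):
            pos_counts[p, base_idx[b]] += 1
    if scheme == "F1x4":
        pooled = pos_counts.sum(axis=0)
        pos_freqs = np.tile(pooled / pooled.sum(), (3, 1))
    elif scheme == "F3x4":
        pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown frequency scheme {scheme!r}")
    pi = np.array(
        [
            pos_freqs[0, base_idx[c[0]]]
            * pos_freqs[1, base_idx[c[1]]]
            * pos_freqs[2, base_idx[c[2]]]
            for c in gc.sense_codons
        ]
    )
    total = pi.sum()
    if total == 0:
        raise ValueError("degenerate frequency estimate")
    return pi / total
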