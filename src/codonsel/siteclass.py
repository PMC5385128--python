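"""Site-class codon model parameterizations.

Each model describes a mixture of site classes; every class assigns one
omega to background branches and one to foreground branches (identical for
single-partition models). Free parameters carry box bounds and a transform
('log' or 'unit') used by the optimizer; mixture proportions are
parameterized by stick-breaking coordinates in (0, 1) so that the simplex
constraint is automatic.

Models provided:

M0            one ratio: a single omega for all sites and branches.
free-ratio    one class, but omega varies freely across branches.
M2a_rel       three classes: purifying (0 < w0 < 1), neutral (w1 = 1),
              and a free shared class (w2 > 0). Null for CmC.
CmC           as M2a_rel, but the third class has distinct background (w2)
              and foreground (w3) ratios — selection divergence.
branch-site A four classes: purifying and neutral classes shared, plus 2a
              (w0 background, w2 foreground) and 2b (1 background, w2
              foreground); the alternative lets w2 >= 1 vary, the null
              fixes w2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OMEGA_MIN = 1e-6
OMEGA_MAX = 999.0
KAPPA_MIN = 1e-3
KAPPA_MAX = 999.0


@dataclass(frozen=True)
class Param:
    name: str
    init: float
    lower: float
    upper: float
    transform: str = "log"  # 'log' or 'unit' (logit on (lower, upper))


def _sticks_to_simplex(sticks) -> np.ndarray:
    """Stick-breaking coordinates in (0,1)^{K-1} -> simplex point."""
    probs = []
    rest = 1.0
    for q in sticks:
        probs.append(rest * q)
        rest *= 1.0 - q
    probs.append(rest)
    return np.asarray(probs)


def _simplex_to_sticks(p) -> list[float]:
    sticks = []
    rest = 1.0
    for pk in p[:-1]:
        sticks.append(min(max(pk / rest, 1e-9), 1 - 1e-9))
        rest *= 1.0 - sticks[-1]
    return sticks


class SiteClassModel:
    """Base class: concrete models implement the parameter list and the
    mapping theta -> (class proportions, per-class background/foreground
    omegas)."""

    name: str = ""
    n_classes: int = 1
    #: True when omega varies per branch rather than per partition
    per_branch: bool = False

    def params(self) -> list[Param]:
        raise NotImplementedError

    def proportions(self, theta: dict) -> np.ndarray:
        raise NotImplementedError

    def omegas(self, theta: dict) -> np.ndarray:
        """(n_classes, 2) array; columns = (background, foreground)."""
        raise NotImplementedError

    def param_names(self) -> list[str]:
        return [p.name for p in self.params()]

    def describe(self, theta: dict) -> dict:
        p = self.proportions(theta)
        om = self.omegas(theta)
        out = {"model": self.name}
        for k in range(self.n_classes):
            out[f"p{k}"] = p[k]
        for k in range(self.n_classes):
            out[f"omega{k}_bg"] = om[k, 0]
            out[f"omega{k}_fg"] = om[k, 1]
        return out


class M0(SiteClassModel):
    name = "M0"
    n_classes = 1

    def params(self):
        return [Param("omega", 0.2, OMEGA_MIN, OMEGA_MAX)]

    def proportions(self, theta):
        return np.array([1.0])

    def omegas(self, theta):
        w = theta["omega"]
        return np.array([[w, w]])


class FreeRatio(SiteClassModel):
    """Single site class, independent omega on every branch. The per-branch
    parameters are synthesized by the fitting engine from the tree."""

    name = "free-ratio"
    n_classes = 1
    per_branch = True

    def params(self):
        return []  # per-branch omegas added by the engine

    def proportions(self, theta):
        return np.array([1.0])

    def omegas(self, theta):  # pragma: no cover - engine bypasses this
        raise RuntimeError("free-ratio omegas are per branch")


class M2aRel(SiteClassModel):
    name = "M2a_rel"
    n_classes = 3

    def params(self):
        return [
            Param("q0", 0.7, 1e-6, 1 - 1e-6, "unit"),
            Param("q1", 0.3, 1e-6, 1 - 1e-6, "unit"),
            Param("omega0", 0.05, OMEGA_MIN, 1 - 1e-6),
            Param("omega2", 1.5, OMEGA_MIN, OMEGA_MAX),
        ]

    def proportions(self, theta):
        return _sticks_to_simplex([theta["q0"], theta["q1"]])

    def omegas(self, theta):
        w0, w2 = theta["omega0"], theta["omega2"]
        return np.array([[w0, w0], [1.0, 1.0], [w2, w2]])


class CmC(SiteClassModel):
    name = "CmC"
    n_classes = 3

    def params(self):
        return [
            Param("q0", 0.7, 1e-6, 1 - 1e-6, "unit"),
            Param("q1", 0.3, 1e-6, 1 - 1e-6, "unit"),
            Param("omega0", 0.05, OMEGA_MIN, 1 - 1e-6),
            Param("omega2", 0.5, OMEGA_MIN, OMEGA_MAX),
            Param("omega3", 1.5, OMEGA_MIN, OMEGA_MAX),
        ]

    def proportions(self, theta):
        return _sticks_to_simplex([theta["q0"], theta["q1"]])

    def omegas(self, theta):
        w0, w2, w3 = theta["omega0"], theta["omega2"], theta["omega3"]
        return np.array([[w0, w0], [1.0, 1.0], [w2, w3]])


class BranchSiteA(SiteClassModel):
    """Branch-site model A. Proportions: free p0, p1; the remainder
    1-p0-p1 splits over classes 2a/2b proportionally to p0:p1 (the
    standard parameterization). Class order: 0, 1, 2a, 2b."""

    name_alt = "branch-site-A-alt"
    name_null = "branch-site-A-null"
    n_classes = 4

    def __init__(self, alternative: bool = True):
        self.alternative = alternative
        self.name = self.name_alt if alternative else self.name_null

    def params(self):
        ps = [
            Param("q0", 0.8, 1e-6, 1 - 1e-6, "unit"),
            Param("q1", 0.5, 1e-6, 1 - 1e-6, "unit"),
            Param("omega0", 0.05, OMEGA_MIN, 1 - 1e-6),
        ]
        if self.alternative:
            ps.append(Param("omega2", 2.0, 1.0, OMEGA_MAX))
        return ps

    def proportions(self, theta):
        # sticks: q0 -> p0+p1 vs p2a+p2b is implicit; use q0=p0, q1 split
        p0, p1, p2 = _sticks_to_simplex([theta["q0"], theta["q1"]])
        denom = p0 + p1
        if denom <= 0:
            denom = 1.0
        return np.array(
            [p0, p1, p2 * p0 / denom, p2 * p1 / denom]
        )

    def omegas(self, theta):
        w0 = theta["omega0"]
        w2 = theta["omega2"] if self.alternative else 1.0
        return np.array([[w0, w0], [1.0, 1.0], [w0, w2], [1.0, w2]])


_MODELS = {
    "M0": M0,
    "free-ratio": FreeRatio,
    "M2a_rel": M2aRel,
    "CmC": CmC,
    "branch-site-A-alt": lambda: BranchSiteA(True),
    "branch-site-A-null": lambda: BranchSiteA(False),
}


def get_model(name: str) -> SiteClassModel:
    try:
        return _MODELS[name]()
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_MODELS)}"
        ) from None
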