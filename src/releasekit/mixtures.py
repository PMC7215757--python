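"""Mixture superposition: forward prediction and inverse design.

A blend of n microparticle formulations with mass fractions Cn (percent,
summing to 100) releases, under the independence assumption,

    Cr(t) = Σ Cn · an(1 - e^(-bn t)) / Σ Cn

i.e. the Cn-weighted average of the component first-order curves.  The same
rule on the mass scale gives the blend's released µg as the weighted average
of the per-formulation released µg for equal total particle mass.

Inverse design exploits that Cr is linear in the weights: finding fractions
that best match a target profile is a convex, simplex-constrained linear
least-squares problem in the component basis curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinetics import FirstOrderParams, ReleaseCurve, eval_first_order

__all__ = [
    "Formulation",
    "MixtureSpec",
    "DesignResult",
    "DegenerateComponentsWarning",
    "predict_mixture_percent",
    "predict_mixture_mass",
    "design_mixture",
]

WEIGHT_SUM_TOL = 1e-9

#: Condition number of the basis Gram matrix above which the inverse design
#: is flagged non-identifiable (components too similar to resolve).
DEGENERACY_COND = 1e10


class DegenerateComponentsWarning(UserWarning):
    """Component curves are (near-)identical; designed weights are not unique."""


@dataclass(frozen=True)
class Formulation:
    """A named microparticle formulation with fitted release kinetics.

    ``params`` are on ``scale``: percent (a = asymptotic % of loaded drug) or
    mass_ug (a = asymptotic µg released from the reference aliquot, used when
    per-mg drug loading is unknown).  ``loading`` is µg drug per mg particles;
    it is required for mass-scale predictions from percent-scale params.
    ``ee_percent`` is the encapsulation efficiency, carried as metadata.
    """

    name: str
    params: FirstOrderParams
    scale: str = "percent"
    loading: Optional[float] = None
    ee_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale not in ("percent", "mass_ug"):
            raise ValueError(f"scale must be 'percent' or 'mass_ug', got {self.scale!r}")
        if self.loading is not None and self.loading <= 0:
            raise ValueError("loading (µg drug / mg particles) must be > 0")

    def mass_release(self, t, aliquot_mass_mg: Optional[float] = None):
        """µg released at time t by this formulation alone.

        For mass-scale params the curve is already in µg (its reference
        aliquot); for percent-scale params an aliquot mass and the drug
        loading are required.
        """
        if self.scale == "mass_ug":
            return eval_first_order(self.params, t)
        if self.loading is None:
            raise ValueError(
                f"formulation {self.name!r}: loading required for mass-scale prediction"
            )
        if aliquot_mass_mg is None or aliquot_mass_mg <= 0:
            raise ValueError("aliquot_mass_mg > 0 required for percent-scale components")
        return aliquot_mass_mg * self.loading * eval_first_order(self.params, t) / 100.0


@dataclass(frozen=True)
class MixtureSpec:
    """Non-negative mass-percent weights Cn over a set of formulations.

    Weights must sum to 100 within 1e-9; component names must be unique.
    """

    components: tuple
    weights: tuple

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", tuple(float(x) for x in w))
        if len(comps) == 0:
            raise ValueError("mixture needs at least one component")
        if len(comps) != len(w):
            raise ValueError("one weight per component required")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 100.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 100, got {w.sum()!r}")

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def predict_mixture_percent(mix: MixtureSpec, t):
    """Percent released by the blend at time(s) t (hours).

    Weighted average of component percent curves: lies between the pointwise
    min and max of the components at every t.
    """
    for c in mix.components:
        if c.scale != "percent":
            raise ValueError(f"component {c.name!r} is not on the percent scale")
    w = mix.weight_array
    curves = np.stack([np.atleast_1d(eval_first_order(c.params, t)) for c in mix.components])
    out = (w[:, None] * curves).sum(axis=0) / w.sum()
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def predict_mixture_mass(mix: MixtureSpec, t, total_mp_mass: Optional[float] = None):
    """µg released by the blend at time(s) t, for total particle mass split
    among the components according to the weights.

    Each component contributes (Cn/100) × its own released µg at full mass —
    equivalently the Cn-weighted average of the per-formulation mass curves
    for equal total mass.  Mass-scale components use their reference-aliquot
    curve directly; percent-scale components need ``total_mp_mass`` (mg) and
    a drug loading.
    """
    w = mix.weight_array / 100.0
    total = np.zeros_like(np.atleast_1d(np.asarray(t, dtype=float)))
    for wn, c in zip(w, mix.components):
        total = total + wn * np.atleast_1d(c.mass_release(t, aliquot_mass_mg=total_mp_mass))
    return float(total[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else total


@dataclass
class DesignResult:
    """Inverse-design outcome: best mixture, its residual, and diagnostics."""

    mixture: MixtureSpec
    rss: float
    degenerate: bool


def _simplex_lstsq(B: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """argmin ||Bx - y||² + ridge||x||²  s.t.  x ≥ 0, Σx = 1 (convex QP)."""
    n = B.shape[1]
    G = B.T @ B + ridge * np.eye(n)
    c = B.T @ y

    def f(x):
        return float(x @ G @ x - 2 * c @ x)

    def grad(x):
        return 2 * (G @ x - c)

    x0 = np.full(n, 1.0 / n)
    sol = minimize(
        f,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(n)}],
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    x = np.clip(sol.x, 0.0, None)
    x = x / x.sum()
    # Polish: exact equality-constrained solve on the active support (KKT
    # system); keeps the result only if it stays feasible.
    support = x > 1e-9
    k = int(support.sum())
    if 0 < k:
        Gs = G[np.ix_(support, support)]
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2 * Gs
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([2 * c[support], [1.0]])
        try:
            xs = np.linalg.solve(kkt, rhs)[:k]
            if np.all(xs >= -1e-12):
                cand = np.zeros(n)
                cand[support] = np.clip(xs, 0.0, None)
                cand = cand / cand.sum()
                if f(cand) <= f(x) + 1e-12:
                    x = cand
        except np.linalg.LinAlgError:
            pass
    return x


def design_mixture(
    components: Sequence[Formulation],
    target: ReleaseCurve,
    *,
    ridge: float = 0.0,
) -> DesignResult:
    """Find mass-percent weights whose mixture best matches ``target``.

    Minimises Σ_t (target(t) - Cr_mix(t))² over the simplex {w ≥ 0, Σw = 100}.
    The problem is linear in the weights, hence convex with a unique optimum
    whenever the component curves are linearly independent on the target's
    time grid.  Near-identical components are flagged ``degenerate`` (with a
    ``DegenerateComponentsWarning``) and re-solved with a small ridge so the
    returned weights approximate the minimal-norm solution.
    """
    components = list(components)
    if len(components) < 2:
        raise ValueError("inverse design needs at least 2 components")
    if len(target) < 1:
        raise ValueError("target curve needs at least 1 time point")
    if any(c.scale != "percent" for c in components):
        raise ValueError("inverse design operates on percent-scale components")

    B = np.column_stack([eval_first_order(c.params, target.times) for c in components])
    gram = B.T @ B
    cond = float(np.linalg.cond(gram))
    degenerate = not np.isfinite(cond) or cond > DEGENERACY_COND
    if degenerate:
        warnings.warn(
            "component curves are nearly identical on the target grid; "
            "designed weights are not uniquely determined",
            DegenerateComponentsWarning,
            stacklevel=2,
        )
    x = _simplex_lstsq(B, target.values, ridge=ridge if not degenerate else max(ridge, 1e-8))
    resid = B @ x - target.values
    mix = MixtureSpec(components=tuple(components), weights=tuple(100.0 * x))
    return DesignResult(mixture=mix, rss=float(resid @ resid), degenerate=degenerate)
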