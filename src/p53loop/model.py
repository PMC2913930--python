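"""Dynamical core: right-hand side, Jacobian and equilibria.

State ordering is (p, m_m, m, c):

* ``p``   free nuclear p53, nM
* ``m_m`` mdm2 mRNA, nM
* ``m``   free Mdm2, nM
* ``c``   p53-Mdm2 complex, nM

Default ("release") degradation convention for the complex: degradation
of the p53 moiety (rate delta) releases free Mdm2; degradation of the
Mdm2 moiety (rate gamma) releases free p53, so the half-life of Mdm2 is
the same whether free or bound.  The alternative "codegradation"
variant, in which the gamma event destroys the whole complex, is
available through ``variant="codegradation"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters

__all__ = [
    "SPECIES",
    "SystemState",
    "Equilibrium",
    "NoEquilibriumError",
    "rhs",
    "jacobian",
    "steady_states",
]

SPECIES = ("p", "m_m", "m", "c")

_VARIANTS = ("release", "codegradation")


class NoEquilibriumError(RuntimeError):
    """No admissible equilibrium found in the search bracket."""


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the four species, nM."""

    p: float
    m_m: float
    m: float
    c: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"state must be finite, got {arr}")
        if np.any(arr < 0):
            raise ValueError(f"state must be non-negative, got {arr}")

    @property
    def total_p53(self) -> float:
        return self.p + self.c

    @property
    def total_mdm2(self) -> float:
        return self.m + self.c

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.m_m, self.m, self.c], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "SystemState":
        p, m_m, m, c = np.asarray(arr, dtype=float)
        return cls(p=float(p), m_m=float(m_m), m=float(m), c=float(c))


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium with its linear-stability classification."""

    state: SystemState
    stable: bool
    leading_eigenvalues: tuple[complex, ...]


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; choose from {_VARIANTS}")


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, SystemState):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state must be finite, got {arr}")
    if np.any(arr < 0):
        raise ValueError(f"state must be non-negative, got {arr}")
    return arr


def rhs(state, params: ModelParameters, variant: str = "release") -> np.ndarray:
    """Instantaneous rates (dp, dm_m, dm, dc)/dt in nM/h.

    Mass bookkeeping in the release variant: a delta event on the complex
    removes one p53 and returns one free Mdm2; a gamma event removes one
    Mdm2 and returns one free p53.
    """
    _check_variant(variant)
    p, m_m, m, c = _as_state_array(state)
    return _rhs_unchecked(p, m_m, m, c, params, variant)


def _rhs_unchecked(p, m_m, m, c, params: ModelParameters, variant: str) -> np.ndarray:
    pr = params
    form = pr.k_f * p * m
    dp = pr.sigma - pr.alpha * p - form + pr.k_b * c
    if variant == "release":
        dp += pr.gamma * c
    dm_m = pr.k_t * p**pr.hill - pr.beta * m_m
    dm = pr.k_tl * m_m - pr.gamma * m - form + (pr.k_b + pr.delta) * c
    dc = form - (pr.k_b + pr.delta + pr.gamma) * c
    return np.array([dp, dm_m, dm, dc])


def jacobian(state, params: ModelParameters, variant: str = "release") -> np.ndarray:
    """Analytic 4x4 Jacobian of :func:`rhs` at ``state``."""
    _check_variant(variant)
    p, m_m, m, c = _as_state_array(state)
    pr = params
    gamma_on_p = pr.gamma if variant == "release" else 0.0
    # transcription term k_t * p**hill; derivative hill*k_t*p**(hill-1)
    dtrans_dp = pr.hill * pr.k_t * p ** (pr.hill - 1.0) if p > 0 or pr.hill >= 1 else 0.0
    if p == 0.0 and pr.hill < 1.0:
        dtrans_dp = 0.0
    return np.array(
        [
            [-pr.alpha - pr.k_f * m, 0.0, -pr.k_f * p, pr.k_b + gamma_on_p],
            [dtrans_dp, -pr.beta, 0.0, 0.0],
            [-pr.k_f * m, pr.k_tl, -pr.gamma - pr.k_f * p, pr.k_b + pr.delta],
            [pr.k_f * m, 0.0, pr.k_f * p, -(pr.k_b + pr.delta + pr.gamma)],
        ]
    )


def _equilibrium_pieces(p: float, params: ModelParameters) -> tuple[float, float, float]:
    """(m_m, m, c) at equilibrium as functions of the p53 level ``p``.

    Uses the exact reduction: m_m = (k_t/beta) p^hill,
    m + c = (k_tl/gamma) m_m and c = k_f p m / (k_b + delta + gamma).
    The total-Mdm2 relation holds for both degradation variants.
    """
    pr = params
    m_m = pr.k_t * p**pr.hill / pr.beta
    total_m = pr.k_tl * m_m / pr.gamma
    D = pr.k_b + pr.delta + pr.gamma
    ratio = pr.k_f * p / D  # c/m at equilibrium
    m = total_m / (1.0 + ratio)
    c = total_m - m
    return m_m, m, c


def _p_residual(p: float, params: ModelParameters, variant: str) -> float:
    """Residual of the p53 balance sigma = alpha*p + delta_eff*c."""
    _, _, c = _equilibrium_pieces(p, params)
    delta_eff = params.delta if variant == "release" else params.delta + params.gamma
    return params.sigma - params.alpha * p - delta_eff * c


def steady_states(
    params: ModelParameters,
    variant: str = "release",
    bracket: tuple[float, float] = (1e-6, 1e4),
    rtol: float = 1e-10,
    stability_tol: float = 1e-8,
) -> list[Equilibrium]:
    """Equilibria of the loop with linear-stability flags.

    The 4-species equilibrium system reduces exactly to a scalar
    root-find in the free-p53 level p; the residual
    sigma - alpha*p - delta_eff*c(p) is strictly decreasing, so the
    admissible equilibrium is unique (the origin when sigma = 0).

    Raises
    ------
    NoEquilibriumError
        If no admissible root lies in ``bracket``.
    """
    _check_variant(variant)
    if params.sigma == 0.0:
        state = SystemState(0.0, 0.0, 0.0, 0.0)
        return [_classify(state, params, variant, stability_tol)]

    lo, hi = bracket
    f_lo = _p_residual(lo, params, variant)
    f_hi = _p_residual(hi, params, variant)
    if f_lo < 0.0 or f_hi > 0.0:
        raise NoEquilibriumError(
            f"no equilibrium found: residual has no sign change on p in "
            f"[{lo:g}, {hi:g}] nM (f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g})"
        )
    p_star = brentq(_p_residual, lo, hi, args=(params, variant), rtol=rtol, maxiter=200)
    m_m, m, c = _equilibrium_pieces(p_star, params)
    state = SystemState(p=p_star, m_m=m_m, m=m, c=c)
    return [_classify(state, params, variant, stability_tol)]


def _classify(
    state: SystemState, params: ModelParameters, variant: str, tol: float
) -> Equilibrium:
    eigvals = np.linalg.eigvals(jacobian(state, params, variant))
    order = np.argsort(-eigvals.real)
    leading = tuple(complex(eigvals[i]) for i in order[:2])
    stable = bool(np.max(eigvals.real) < tol)
    return Equilibrium(state=state, stable=stable, leading_eigenvalues=leading)
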