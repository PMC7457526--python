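"""Group SCAD penalty machinery.

The SCAD (smoothly clipped absolute deviation) penalty is applied to the
L1 norm of each coefficient group, so a whole group of covariates enters
or leaves the model together.  What the estimating equations need is the
penalty *derivative*

    q_lambda(theta) = lambda                          for theta <= lambda
                    = (a*lambda - theta)_+ / (a - 1)  for theta >  lambda

for theta >= 0 and a > 2 (a = 3.7 throughout, the standard choice): flat
at rate lambda near zero, decaying linearly, and exactly zero beyond
a*lambda so large signals are left essentially unpenalized.  At
theta = lambda both branches equal lambda, so the continuous closed form
is used.

For the Newton iteration the nonsmooth penalty is handled by a
minorization-maximization (MM) surrogate: the diagonal weight matrix
E_n with entries q_lambda(||beta_g||_1) / (eps + |beta_j|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GroupStructure

__all__ = [
    "PenaltyError",
    "ScadPenalty",
    "group_l1_norms",
    "group_penalty_vector",
    "mm_penalty_matrix",
    "scad_derivative",
]

#: MM smoothing constant in the denominator eps + |beta_j|.
DEFAULT_EPSILON = 1.0e-6


class PenaltyError(ValueError):
    """Invalid penalty parameter or argument."""


@dataclass(frozen=True)
class ScadPenalty:
    """SCAD tuning parameters: penalty level ``lam`` and shape ``a``."""

    lam: float
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise PenaltyError(f"lambda must be nonnegative, got {self.lam}")
        if self.a <= 2:
            raise PenaltyError(f"SCAD shape parameter must exceed 2, got {self.a}")


def scad_derivative(theta, penalty: ScadPenalty):
    """Derivative q_lambda(theta) of the SCAD penalty, vectorized in theta.

    Continuous on [0, inf): equals lambda on [0, lambda], decays linearly
    on (lambda, a*lambda), and is 0 on [a*lambda, inf).
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise PenaltyError("theta must be nonnegative")
    lam, a = penalty.lam, penalty.a
    if lam == 0:
        out = np.zeros_like(th)
        return out if out.ndim else float(out)
    decay = np.maximum(a * lam - th, 0.0) / (a - 1.0)
    out = np.where(th <= lam, lam, decay)
    return out if out.ndim else float(out)


def group_l1_norms(beta: np.ndarray, groups: GroupStructure) -> np.ndarray:
    """L1 norm of each coefficient group, in group order."""
    b = np.abs(np.asarray(beta, dtype=float))
    return np.array([b[list(g)].sum() for g in groups.groups])


def group_penalty_vector(
    beta: np.ndarray, groups: GroupStructure, penalty: ScadPenalty
) -> np.ndarray:
    """Per-coefficient penalty rates q_lambda^G(beta).

    Every coefficient in group g receives the scalar
    ``scad_derivative(||beta_g||_1)``; unpenalized coefficients receive 0.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    if groups.n_coefficients != p:
        raise PenaltyError(
            f"group structure covers {groups.n_coefficients} coefficients, "
            f"beta has {p}"
        )
    out = np.zeros(p)
    rates = scad_derivative(group_l1_norms(beta, groups), penalty)
    rates = np.atleast_1d(rates)
    for g, rate in zip(groups.groups, rates):
        out[list(g)] = rate
    return out


def mm_penalty_matrix(
    beta: np.ndarray,
    groups: GroupStructure,
    penalty: ScadPenalty,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Diagonal of the MM surrogate matrix E_n.

    Entry j is ``q_lambda(||beta_g(j)||_1) / (epsilon + |beta_j|)`` for
    penalized coefficients and 0 for unpenalized ones.  Returned as the
    1-D diagonal; callers form ``np.diag`` if the full matrix is needed.
    """
    if epsilon <= 0:
        raise PenaltyError(f"epsilon must be positive, got {epsilon}")
    beta = np.asarray(beta, dtype=float)
    return group_penalty_vector(beta, groups, penalty) / (epsilon + np.abs(beta))
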