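"""Admissible-rate domain for the checkpoint.

Two requirements bracket the production rate lambda*S and the
inhibition rate k_minus1:

C1 (inhibition): the probability of no premature activation over the
    whole chromosome-congression window tau1 (~20 min) stays above a
    threshold (default 0.95).
C2 (timing): once the checkpoint lifts, the mean time to activate all N
    targets must not exceed tau_prime (~10 min).

The admissible domain Omega is the intersection of both truth sets in
the (lambda*S, k_minus1) plane.  Survival is monotone in lambda
(decreasing) and tau as well, so along a fixed-k_minus1 line each
constraint flips truth value at most once and Omega cuts an interval
out of the lambda*S axis; the boundaries are level curves P(tau1) =
threshold and tau = tau_prime, located by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .activation import mean_activation_time
from .errors import (
    BracketError,
    DivergentMeanTimeError,
    InvalidParameterError,
)
from .inhibition import survival_probability
from .parameters import RateParameters

__all__ = [
    "ConstraintSpec",
    "DomainGrid",
    "ConstraintEvaluation",
    "evaluate_constraints",
    "scan_domain",
    "boundary_lambdaS",
    "rho",
]


@dataclass(frozen=True)
class ConstraintSpec:
    """Thresholds defining C1 and C2.

    tau1: checkpoint duration (s); p_threshold: minimum survival over
    tau1; tau_prime: maximum admissible mean activation time (s).
    """

    tau1: float = 1200.0
    p_threshold: float = 0.95
    tau_prime: float = 600.0

    def __post_init__(self):
        if not self.tau1 > 0:
            raise InvalidParameterError("tau1 must be > 0")
        if not 0.0 < self.p_threshold < 1.0:
            raise InvalidParameterError("p_threshold must lie in (0, 1)")
        if not self.tau_prime > 0:
            raise InvalidParameterError("tau_prime must be > 0")


@dataclass(frozen=True)
class ConstraintEvaluation:
    """Outcome of both constraints at one parameter point."""

    c1: bool
    c2: bool
    survival: float
    tau: float

    @property
    def in_omega(self) -> bool:
        return self.c1 and self.c2


@dataclass(frozen=True)
class DomainGrid:
    """2-D scan of the constraints over (lambda*S, k_minus1)."""

    lambdaS_axis: np.ndarray
    k_minus1_axis: np.ndarray
    survival_values: np.ndarray
    tau_values: np.ndarray
    c1_mask: np.ndarray
    c2_mask: np.ndarray
    omega_mask: np.ndarray
    rho: np.ndarray


def evaluate_constraints(
    params: RateParameters, spec: ConstraintSpec = ConstraintSpec()
) -> ConstraintEvaluation:
    """Evaluate C1 and C2 at one parameter point.

    A divergent mean activation time (lambda = 0) reports c2 = False
    with tau = inf rather than raising.
    """
    survival = float(survival_probability(params, spec.tau1))
    try:
        tau = mean_activation_time(params)
    except DivergentMeanTimeError:
        tau = math.inf
    return ConstraintEvaluation(
        c1=survival >= spec.p_threshold,
        c2=tau <= spec.tau_prime,
        survival=survival,
        tau=tau,
    )


def scan_domain(
    lambdaS_axis,
    k_minus1_axis,
    base_params: RateParameters,
    spec: ConstraintSpec = ConstraintSpec(),
) -> DomainGrid:
    """Evaluate both constraints on a (lambda*S, k_minus1) grid.

    mu, N and S are held at ``base_params``; lambda = lambdaS/S at each
    node.  Matrices are indexed [i_k_minus1, j_lambdaS].
    """
    lS = np.asarray(lambdaS_axis, dtype=float)
    k1 = np.asarray(k_minus1_axis, dtype=float)
    for name, ax in (("lambdaS_axis", lS), ("k_minus1_axis", k1)):
        if ax.ndim != 1 or ax.size == 0:
            raise InvalidParameterError(f"{name} must be a non-empty 1-D grid")
        if np.any(ax < 0) or np.any(np.diff(ax) <= 0):
            raise InvalidParameterError(f"{name} must be strictly increasing, >= 0")
    nr, nc = k1.size, lS.size
    survival = np.empty((nr, nc))
    tau = np.empty((nr, nc))
    for i, kk in enumerate(k1):
        for j, ls in enumerate(lS):
            params = base_params.with_(lambda_=ls / base_params.S, k_minus1=kk)
            ev = evaluate_constraints(params, spec)
            survival[i, j] = ev.survival
            tau[i, j] = ev.tau
    c1 = survival >= spec.p_threshold
    c2 = tau <= spec.tau_prime
    with np.errstate(divide="ignore"):
        rho_mat = np.where(lS > 0, k1[:, None] / lS[None, :], np.inf)
    return DomainGrid(
        lambdaS_axis=lS,
        k_minus1_axis=k1,
        survival_values=survival,
        tau_values=tau,
        c1_mask=c1,
        c2_mask=c2,
        omega_mask=c1 & c2,
        rho=rho_mat,
    )


#: default scan grids, covering the physiologically plausible decades
DEFAULT_LAMBDAS_AXIS = np.geomspace(0.01, 2.0, 41)
DEFAULT_K_MINUS1_AXIS = np.geomspace(0.1, 100.0, 41)


def boundary_lambdaS(
    k_minus1: float,
    which: str,
    spec: ConstraintSpec = ConstraintSpec(),
    base_params: RateParameters | None = None,
    bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-4,
) -> float:
    """Locate by bisection the lambda*S level curve of one constraint.

    ``which`` selects 'c1' (survival P(tau1) = p_threshold) or 'c2'
    (tau = tau_prime) at fixed ``k_minus1``.  The constraint must change
    truth value across ``bracket``; the returned value is accurate to
    ``tol`` in lambda*S.
    """
    from .parameters import default_ptk2_parameters

    if which not in ("c1", "c2"):
        raise InvalidParameterError("which must be 'c1' or 'c2'")
    if base_params is None:
        base_params = default_ptk2_parameters()

    def indicator(lambdaS: float) -> float:
        params = base_params.with_(
            lambda_=lambdaS / base_params.S, k_minus1=k_minus1
        )
        if which == "c1":
            return float(survival_probability(params, spec.tau1)) - spec.p_threshold
        try:
            tau = mean_activation_time(params)
        except DivergentMeanTimeError:
            tau = math.inf
        if math.isinf(tau):
            raise BracketError(
                "tau is infinite inside the bracket; shrink the bracket"
            )
        return spec.tau_prime - tau

    lo, hi = bracket
    f_lo, f_hi = indicator(lo), indicator(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise BracketError(
            f"constraint {which} does not change truth value on "
            f"[{lo}, {hi}] at k_minus1={k_minus1}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = indicator(mid)
        if f_mid == 0.0:
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def rho(params: RateParameters) -> float:
    """Inhibition-to-production ratio k_minus1/(lambda*S), dimensionless."""
    if params.lambdaS == 0.0:
        raise InvalidParameterError("rho is undefined at lambda*S = 0")
    return params.k_minus1 / params.lambdaS
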