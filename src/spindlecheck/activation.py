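"""Mean time to full APC/C activation after checkpoint shutdown.

Once every kinetochore is attached the inhibition rate collapses to
zero and the state is (k, m): k Cdc20 molecules produced (bound ones
included), m of the N targets activated.  Transitions:

    (k, m) -> (k+1, m)   at lambda*(S-k)        (production)
    (k, m) -> (k, m+1)   at mu*(N-m)*(k-m)      (activation; free
                                                 Cdc20 = k - m)

Both coordinates are non-decreasing, so the chain is acyclic and the
expected occupation times a(k, m) = integral of p_{k,m}(t) solve a
linear system in a single topological sweep:

    out(k,m) a(k,m) = init[k]*[m=0]
                      + lambda*(S-k+1) a(k-1,m)
                      + mu*(N-m+1)*(k-m+1) a(k,m-1)

with out(k,m) = lambda*(S-k) + mu*(N-m)*(k-m).  The mean activation
time is tau = sum of a over all transient states (m < N).  The initial
Cdc20 law is by default the checkpoint equilibrium binomial.

Two independent oracles are provided for small instances: the dense
fundamental-matrix solve and time integration of the transient master
equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .equilibrium import equilibrium_distribution
from .errors import (
    DivergentMeanTimeError,
    InvalidParameterError,
    NumericalIntegrationError,
)
from .parameters import RateParameters

__all__ = [
    "ActivationChainSpec",
    "OccupationTable",
    "occupation_times",
    "mean_activation_time",
    "transient_distribution",
    "dense_occupation_oracle",
    "pure_production_time",
]


@dataclass(frozen=True)
class ActivationChainSpec:
    """Activation-phase chain: rates plus the initial Cdc20 law at m = 0.

    ``k_minus1`` enters only through the default initial law (the
    checkpoint equilibrium binomial); the activation dynamics itself has
    no inhibition channel.
    """

    params: RateParameters
    initial_pmf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.initial_pmf is None:
            pmf = equilibrium_distribution(self.params).pmf
            object.__setattr__(self, "initial_pmf", pmf)
        else:
            pmf = np.asarray(self.initial_pmf, dtype=float)
            if pmf.shape != (self.params.S + 1,):
                raise InvalidParameterError(
                    f"initial_pmf must have length S+1={self.params.S + 1}"
                )
            if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-12:
                raise InvalidParameterError(
                    "initial_pmf must be a probability vector (sum 1 within 1e-12)"
                )
            object.__setattr__(self, "initial_pmf", pmf)


@dataclass(frozen=True)
class OccupationTable:
    """Occupation times a(k, m) of the activation chain and the mean tau.

    ``a`` has shape (S+1, N): rows index the Cdc20 count k, columns the
    activated-target count m over the transient layers m = 0..N-1.
    Entries with k < m are structurally zero.  tau = a.sum().
    """

    a: np.ndarray
    tau: float


def _check_reachability(spec: ActivationChainSpec) -> None:
    params = spec.params
    if params.mu <= 0:
        raise DivergentMeanTimeError("mu = 0: targets can never be activated")
    if params.lambda_ == 0.0:
        mass_below = spec.initial_pmf[: params.N].sum()
        if mass_below > 0:
            raise DivergentMeanTimeError(
                "lambda = 0 with initial mass below k = N: "
                "full activation is unreachable, tau is infinite"
            )


def occupation_times(spec: ActivationChainSpec) -> OccupationTable:
    """Solve the occupation-time system in one topological sweep.

    k and m never decrease along transitions, so sweeping m outward and
    k inward visits every state after its predecessors; no iteration to
    convergence is involved.  Runs in O(S*N) time.
    """
    _check_reachability(spec)
    params = spec.params
    lam, mu, N, S = params.lambda_, params.mu, params.N, params.S
    init = spec.initial_pmf
    a = np.zeros((S + 1, N))
    prev_col = None
    for m in range(N):
        col = a[:, m]
        nm = N - m
        for k in range(m, S + 1):
            out = lam * (S - k) + mu * nm * (k - m)
            inflow = init[k] if m == 0 else 0.0
            if k > m:
                inflow += lam * (S - k + 1) * col[k - 1]
            if m > 0:
                inflow += mu * (nm + 1) * (k - m + 1) * prev_col[k]
            if out > 0.0:
                col[k] = inflow / out
            elif inflow > 0.0:
                # absorbing transient state with mass: tau diverges
                raise DivergentMeanTimeError(
                    f"state (k={k}, m={m}) has zero outflow but positive inflow"
                )
        prev_col = col
    return OccupationTable(a=a, tau=float(a.sum()))


def mean_activation_time(params: RateParameters, initial_pmf=None) -> float:
    """Mean time tau for all N targets to be activated (seconds).

    Convenience wrapper: the initial Cdc20 law defaults to the
    checkpoint equilibrium binomial.
    """
    spec = ActivationChainSpec(params=params, initial_pmf=initial_pmf)
    return occupation_times(spec).tau


def pure_production_time(params: RateParameters) -> float:
    """Large-mu limit of tau: binding is instantaneous and only the
    production of the first N Cdc20 molecules takes time,
    sum_{j<N} 1/(lambda*(S-j))."""
    if params.lambda_ == 0.0:
        raise DivergentMeanTimeError("lambda = 0: production never happens")
    lam, S, N = params.lambda_, params.S, params.N
    return sum(1.0 / (lam * (S - j)) for j in range(N))


# ---------------------------------------------------------------------------
# small-instance oracles


def _wedge_states(S: int, N: int, transient_only: bool):
    """Enumerate (k, m) with m <= min(k, N) in topological order."""
    m_max = N - 1 if transient_only else N
    states = [(k, m) for m in range(m_max + 1) for k in range(m, S + 1)]
    index = {s: i for i, s in enumerate(states)}
    return states, index


def dense_occupation_oracle(spec: ActivationChainSpec) -> OccupationTable:
    """Fundamental-matrix reference solve for small chains.

    Builds the full transient generator Q over the wedge of states with
    m < N and solves (-Q)^T a = p0 for the occupation-time vector;
    intended for instances with at most a few thousand states.
    """
    _check_reachability(spec)
    params = spec.params
    lam, mu, N, S = params.lambda_, params.mu, params.N, params.S
    states, index = _wedge_states(S, N, transient_only=True)
    n = len(states)
    Q = np.zeros((n, n))
    for i, (k, m) in enumerate(states):
        out = lam * (S - k) + mu * (N - m) * (k - m)
        Q[i, i] = -out
        if k + 1 <= S:
            Q[i, index[(k + 1, m)]] = lam * (S - k)
        if m + 1 < N and k >= m + 1:
            Q[i, index[(k, m + 1)]] = mu * (N - m) * (k - m)
        # m+1 == N transitions leave the transient set
    p0 = np.zeros(n)
    for k in range(S + 1):
        p0[index[(k, 0)]] = spec.initial_pmf[k]
    avec = np.linalg.solve(-Q.T, p0)
    a = np.zeros((S + 1, N))
    for i, (k, m) in enumerate(states):
        a[k, m] = avec[i]
    return OccupationTable(a=a, tau=float(avec.sum()))


def transient_distribution(spec: ActivationChainSpec, t_end: float) -> np.ndarray:
    """Joint law p(k, m) of the activation chain at time ``t_end``.

    Integrates the master equations over the wedge m <= min(k, N)
    (including the absorbing layer m = N) with the BDF method and exact
    sparse Jacobian.  Returns an (S+1, N+1) array; the total mass is
    conserved to integrator tolerance.
    """
    if t_end < 0:
        raise InvalidParameterError("t_end must be non-negative")
    params = spec.params
    lam, mu, N, S = params.lambda_, params.mu, params.N, params.S
    states, index = _wedge_states(S, N, transient_only=False)
    n = len(states)
    p0 = np.zeros(n)
    for k in range(S + 1):
        p0[index[(k, 0)]] = spec.initial_pmf[k]
    if t_end == 0.0:
        out = np.zeros((S + 1, N + 1))
        out[:, 0] = spec.initial_pmf
        return out

    rows, cols, vals = [], [], []
    for i, (k, m) in enumerate(states):
        act = mu * (N - m) * (k - m) if m < N else 0.0
        prod = lam * (S - k)
        rows.append(i), cols.append(i), vals.append(-(prod + act))
        if k + 1 <= S:
            rows.append(index[(k + 1, m)]), cols.append(i), vals.append(prod)
        if m < N and k >= m + 1:
            rows.append(index[(k, m + 1)]), cols.append(i), vals.append(act)
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    sol = solve_ivp(
        lambda t, p: A @ p,
        (0.0, t_end),
        p0,
        method="BDF",
        jac=A,
        t_eval=[t_end],
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise NumericalIntegrationError(
            f"transient integration failed: {sol.message}",
            diagnostics={"status": sol.status},
        )
    p = sol.y[:, -1]
    out = np.zeros((S + 1, N + 1))
    for i, (k, m) in enumerate(states):
        out[k, m] = p[i]
    return out
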