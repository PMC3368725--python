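"""Exact stochastic simulation of both checkpoint phases.

Direct-method Gillespie simulation: at each step the waiting time is
exponential with the total propensity and the channel is chosen with
probability proportional to its propensity.  Only two or three channels
exist per phase, so the direct method is both the simplest and the
fastest sensible choice.

Inhibition phase (checkpoint up), state k = free Cdc20:
    production  k -> k+1   at lambda*(S-k)
    inhibition  k -> k-1   at k_minus1*k
    activation  absorbing  at mu*N*k        (ends the trajectory)

Activation phase (checkpoint lifted), state (k, m):
    production  k -> k+1   at lambda*(S-k)
    activation  m -> m+1   at mu*(N-m)*(k-m); terminates at m = N.

Reproducibility: a trajectory is fully determined by (params, seed);
ensembles derive one child seed per run from the root seed through a
counter-keyed ``numpy.random.SeedSequence``, so results do not depend
on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .parameters import RateParameters

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "simulate_inhibition",
    "simulate_activation",
    "inhibition_ensemble",
    "activation_ensemble",
    "ensemble_summary",
]


@dataclass(frozen=True)
class Trajectory:
    """One exact SSA sample path.

    ``event_times`` are strictly increasing; ``k_values`` (and, for the
    activation phase, ``m_values``) give the state just after each
    event.  For the inhibition phase, ``absorbed`` flags that an
    activation event ended the run at ``absorption_time``; for the
    activation phase, ``absorption_time`` is the time m reached N.
    """

    phase: str
    seed: object
    initial_k: int
    event_times: np.ndarray
    k_values: np.ndarray
    m_values: np.ndarray | None
    absorbed: bool
    absorption_time: float | None
    t_max: float | None

    @property
    def states(self):
        """State tuples after each event: (k, absorbed) or (k, m)."""
        if self.phase == "inhibition":
            flags = [False] * len(self.k_values)
            if self.absorbed:
                flags[-1] = True
            return list(zip(self.k_values.tolist(), flags))
        return list(zip(self.k_values.tolist(), self.m_values.tolist()))

    def k_at(self, t: float) -> int:
        """Cdc20 count at time t (inhibition phase, piecewise constant)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        if idx == 0:
            return self.initial_k
        return int(self.k_values[idx - 1])


@dataclass(frozen=True)
class EnsembleSummary:
    """Monte-Carlo summary across trajectories of one phase."""

    phase: str
    n_runs: int
    checkpoint_times: np.ndarray | None
    empirical_survival: np.ndarray | None
    survival_se: np.ndarray | None
    mean_absorption_time: float | None
    absorption_time_se: float | None


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_inhibition(
    params: RateParameters, t_max: float, seed=None
) -> Trajectory:
    """Exact SSA of the inhibition phase from k = 0 up to absorption or t_max."""
    if not t_max > 0:
        raise InvalidParameterError("t_max must be > 0")
    rng = _rng_from(seed)
    lam, k1, muN, S = (
        params.lambda_,
        params.k_minus1,
        params.mu * params.N,
        params.S,
    )
    t, k = 0.0, 0
    times, ks = [], []
    absorbed = False
    absorption_time = None
    while True:
        a_prod = lam * (S - k)
        a_inh = k1 * k
        a_act = muN * k
        total = a_prod + a_inh + a_act
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        u = rng.random() * total
        if u < a_prod:
            k += 1
        elif u < a_prod + a_inh:
            k -= 1
        else:
            absorbed = True
            absorption_time = t
        times.append(t)
        ks.append(k)
        if absorbed:
            break
    return Trajectory(
        phase="inhibition",
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        initial_k=0,
        event_times=np.asarray(times, dtype=float),
        k_values=np.asarray(ks, dtype=np.int64),
        m_values=None,
        absorbed=absorbed,
        absorption_time=absorption_time,
        t_max=t_max,
    )


def simulate_activation(
    params: RateParameters, initial_k: int, seed=None
) -> Trajectory:
    """Exact SSA of the activation phase from (initial_k, m=0) to m = N."""
    if not 0 <= initial_k <= params.S:
        raise InvalidParameterError("initial_k must lie in [0, S]")
    if params.lambda_ == 0.0 and initial_k < params.N:
        raise InvalidParameterError(
            "lambda = 0 with initial_k < N can never reach full activation"
        )
    if params.mu == 0.0:
        raise InvalidParameterError("mu = 0: activation never happens")
    rng = _rng_from(seed)
    lam, mu, N, S = params.lambda_, params.mu, params.N, params.S
    t, k, m = 0.0, initial_k, 0
    times, ks, ms = [], [], []
    while m < N:
        a_prod = lam * (S - k)
        a_act = mu * (N - m) * (k - m)
        total = a_prod + a_act
        t += rng.exponential(1.0 / total)
        if rng.random() * total < a_prod:
            k += 1
        else:
            m += 1
        times.append(t)
        ks.append(k)
        ms.append(m)
    return Trajectory(
        phase="activation",
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        initial_k=initial_k,
        event_times=np.asarray(times, dtype=float),
        k_values=np.asarray(ks, dtype=np.int64),
        m_values=np.asarray(ms, dtype=np.int64),
        absorbed=True,
        absorption_time=t,
        t_max=None,
    )


def _child_rngs(root_seed: int, n: int):
    """Counter-keyed child generators: independent of execution order."""
    return [
        np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(i,)))
        for i in range(n)
    ]


def inhibition_ensemble(
    params: RateParameters, n_runs: int, t_max: float, seed: int
) -> list[Trajectory]:
    """n_runs independent inhibition-phase trajectories from one root seed."""
    return [
        simulate_inhibition(params, t_max, rng)
        for rng in _child_rngs(seed, n_runs)
    ]


def activation_ensemble(
    params: RateParameters,
    n_runs: int,
    seed: int,
    initial_k: int | None = None,
) -> list[Trajectory]:
    """n_runs activation-phase trajectories.

    When ``initial_k`` is None, each run draws its initial Cdc20 count
    from the checkpoint equilibrium binomial with its own child
    generator (the draw precedes the event loop, so the run remains a
    deterministic function of the root seed and its index).
    """
    p_eq = params.lambda_ / (params.lambda_ + params.k_minus1)
    out = []
    for rng in _child_rngs(seed, n_runs):
        k0 = (
            int(rng.binomial(params.S, p_eq)) if initial_k is None else initial_k
        )
        out.append(simulate_activation(params, k0, rng))
    return out


def ensemble_summary(trajectories, checkpoint_times=None) -> EnsembleSummary:
    """Summarize an ensemble: survival fractions or absorption-time mean.

    Inhibition phase: the empirical survival at each checkpoint time is
    the fraction of runs not yet absorbed, with the binomial standard
    error sqrt(p_hat (1-p_hat)/n).  Activation phase: sample mean and
    standard error of the absorption times.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise InvalidParameterError("need at least two trajectories")
    phases = {tr.phase for tr in trajectories}
    if len(phases) != 1:
        raise InvalidParameterError(f"mixed-phase ensemble: {sorted(phases)}")
    phase = phases.pop()
    n = len(trajectories)
    if phase == "inhibition":
        if checkpoint_times is None:
            raise InvalidParameterError(
                "checkpoint_times is required for the inhibition phase"
            )
        ct = np.asarray(checkpoint_times, dtype=float)
        abs_times = np.array(
            [
                tr.absorption_time if tr.absorbed else np.inf
                for tr in trajectories
            ]
        )
        surv = (abs_times[None, :] > ct[:, None]).mean(axis=1)
        se = np.sqrt(surv * (1.0 - surv) / n)
        return EnsembleSummary(
            phase=phase,
            n_runs=n,
            checkpoint_times=ct,
            empirical_survival=surv,
            survival_se=se,
            mean_absorption_time=None,
            absorption_time_se=None,
        )
    times = np.array([tr.absorption_time for tr in trajectories])
    return EnsembleSummary(
        phase=phase,
        n_runs=n,
        checkpoint_times=None,
        empirical_survival=None,
        survival_se=None,
        mean_absorption_time=float(times.mean()),
        absorption_time_se=float(times.std(ddof=1) / np.sqrt(n)),
    )
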