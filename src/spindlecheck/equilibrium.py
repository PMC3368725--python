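"""Stationary law of free Cdc20 under the checkpoint.

Conditioned on no activation having occurred, the Cdc20 count follows a
birth-death chain with birth rate lambda*(S-k) and death rate
k_minus1*k (the absorption channel drops out of the conditioned
dynamics).  Its stationary distribution is binomial with S trials and
success probability lambda/(lambda + k_minus1); the mean is
S*lambda/(lambda + k_minus1).  This law is the initial condition for
the activation phase at anaphase onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, NoStationaryDistributionError
from .parameters import RateParameters

__all__ = [
    "EquilibriumDistribution",
    "equilibrium_distribution",
    "stationarity_residual",
    "relaxation_time",
]


@dataclass(frozen=True)
class EquilibriumDistribution:
    """Binomial stationary law of the conditioned Cdc20 chain."""

    params: RateParameters
    pmf: np.ndarray
    mean: float


def equilibrium_distribution(
    params: RateParameters, allow_degenerate: bool = False
) -> EquilibriumDistribution:
    """Stationary distribution of free Cdc20 during the checkpoint.

    pmf[k] = C(S, k) (lambda/k_minus1)^k / (1 + lambda/k_minus1)^S,
    i.e. Binomial(S, lambda/(lambda+k_minus1)), evaluated through the
    log-gamma form so that S = 3000 does not overflow.

    Parameters
    ----------
    params : RateParameters
    allow_degenerate : bool
        When k_minus1 = 0 with lambda > 0 the chain has no proper
        stationary law (all mass escapes to k = S); pass True to obtain
        the degenerate point mass at S instead of an error.
    """
    lam, k1, S = params.lambda_, params.k_minus1, params.S
    if k1 == 0.0 and lam > 0.0:
        if not allow_degenerate:
            raise NoStationaryDistributionError(
                "k_minus1 = 0 with lambda > 0: mass escapes to k = S; "
                "pass allow_degenerate=True for the point mass at S"
            )
        p = 1.0
    else:
        p = lam / (lam + k1) if lam > 0.0 else 0.0
    pmf = stats.binom.pmf(np.arange(S + 1), S, p)
    mean = S * p
    return EquilibriumDistribution(params=params, pmf=pmf, mean=mean)


def stationarity_residual(dist: EquilibriumDistribution) -> float:
    """Largest violation of the stationary master equations, relative.

    Applies the generator of the conditioned birth-death chain (birth
    lambda*(S-k), death k_minus1*k) to the pmf and returns the largest
    row residual divided by the largest transition rate.  A correct
    closed form gives ~1e-16; the check is equivalent to detailed
    balance lambda*(S-k)*pmf[k] = k_minus1*(k+1)*pmf[k+1].
    """
    params = dist.params
    lam, k1, S = params.lambda_, params.k_minus1, params.S
    k = np.arange(S + 1, dtype=float)
    birth = lam * (S - k)
    death = k1 * k
    pmf = dist.pmf
    flux = np.zeros(S + 1)
    flux -= (birth + death) * pmf
    flux[1:] += birth[:-1] * pmf[:-1]
    flux[:-1] += death[1:] * pmf[1:]
    max_rate = max((birth + death).max(), 1.0)
    return float(np.abs(flux).max() / max_rate)


def relaxation_time(params: RateParameters) -> float:
    """Relaxation time 1/(lambda + k_minus1) of the conditioned chain (s).

    The binomial chain relaxes exponentially at rate lambda + k_minus1;
    the anaphase initial condition is meaningful only when the time the
    checkpoint has been in place is long compared with this scale.  No
    threshold is imposed here; this is a diagnostic.
    """
    total = params.lambda_ + params.k_minus1
    if total == 0.0:
        raise InvalidParameterError("lambda + k_minus1 = 0: chain does not relax")
    return 1.0 / total
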