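"""Model constants, kinetic rates, and unit conversions.

The checkpoint model is driven by five kinetic quantities:

``lambda_``
    per-free-complex Cdc20 production rate (1/s); the total production
    rate at the start of the checkpoint is ``lambda_ * S``.
``k_minus1``
    Cdc20 inhibition (ubiquitylation) rate per free Cdc20 molecule (1/s),
    set by the MCC concentration through the Smoluchowski rate.
``mu``
    arrival rate of one free Cdc20 molecule at one unattached
    kinetochore/APC/C target (1/s), set by diffusion-limited search.
``N``
    number of chromosomes, i.e. APC/C targets.
``S``
    size of the complex pool from which Cdc20 is released; the hard
    ceiling on the Cdc20 copy number.

Two of those rates can be derived from cell geometry: ``mu`` from the
narrow-target arrival formula 4*a*D/V and ``k_minus1`` from the
Smoluchowski rate 2*pi*b*D*[MCC].

A caveat on defaults: for the reference PTK2 cell the tabulated binding
rate is mu ~= 2e-4 1/s, although 4*a*D/V with the same tabulated a, D
and V evaluates to 8e-3 1/s.  The headline numbers of the analysis are
reproducible only with the tabulated value, so :func:`default_ptk2_parameters`
uses 2e-4 verbatim and :func:`mu_from_geometry` remains available (and
documented as inconsistent with the tabulated figure).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .errors import InvalidParameterError

#: Avogadro's number (1/mol).
AVOGADRO = 6.02214076e23

#: litres per cubic micrometre.
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class CellGeometry:
    """Physical inputs from which kinetic rates are derived.

    Parameters
    ----------
    V : float
        Cell volume (um^3).
    a : float
        APC/C target radius (um).
    b : float
        Cdc20 binding-site radius on MCC (um).
    D : float
        Cdc20 diffusion coefficient (um^2/s).
    mcc_copies : int, optional
        MCC molecule count.  Exactly one of ``mcc_copies`` and
        ``mcc_conc_nM`` must be given.
    mcc_conc_nM : float, optional
        MCC concentration in nM.
    """

    V: float
    a: float
    b: float
    D: float
    mcc_copies: int | None = None
    mcc_conc_nM: float | None = None

    def __post_init__(self):
        for name in ("V", "a", "b", "D"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"CellGeometry.{name} must be strictly positive, got {value!r}"
                )
        if (self.mcc_copies is None) == (self.mcc_conc_nM is None):
            raise InvalidParameterError(
                "exactly one of mcc_copies and mcc_conc_nM must be given"
            )
        if self.mcc_copies is not None and self.mcc_copies < 0:
            raise InvalidParameterError("mcc_copies must be non-negative")
        if self.mcc_conc_nM is not None and self.mcc_conc_nM < 0:
            raise InvalidParameterError("mcc_conc_nM must be non-negative")
        # Small-target regime sanity: target radii much smaller than the
        # linear cell size.  Violations only degrade the rate formulas,
        # so warn rather than fail.
        linear = self.V ** (1.0 / 3.0)
        if self.a > 0.1 * linear or self.b > 0.1 * linear:
            warnings.warn(
                "target radius is not small compared with the cell size; "
                "the narrow-target rate formulas may be inaccurate",
                stacklevel=2,
            )

    @property
    def mcc_density(self) -> float:
        """MCC number density (molecules/um^3)."""
        if self.mcc_copies is not None:
            return self.mcc_copies / self.V
        return self.mcc_conc_nM * 1e-9 * AVOGADRO * _L_PER_UM3


@dataclass(frozen=True)
class RateParameters:
    """The five kinetic quantities every checkpoint formula consumes.

    ``lambda_`` and ``k_minus1`` may be zero (useful limits); ``mu`` may
    be zero only to express the no-target limit in which the survival
    probability is identically one.
    """

    lambda_: float
    k_minus1: float
    mu: float
    N: int
    S: int

    def __post_init__(self):
        if self.lambda_ < 0:
            raise InvalidParameterError(f"lambda_ must be >= 0, got {self.lambda_}")
        if self.k_minus1 < 0:
            raise InvalidParameterError(f"k_minus1 must be >= 0, got {self.k_minus1}")
        if self.mu < 0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu}")
        if not (1 <= self.N <= self.S):
            raise InvalidParameterError(
                f"need 1 <= N <= S, got N={self.N}, S={self.S}"
            )

    @property
    def lambdaS(self) -> float:
        """Total production rate lambda*S at the start of the checkpoint (1/s)."""
        return self.lambda_ * self.S

    def with_(self, **kwargs) -> "RateParameters":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


def mu_from_geometry(geom: CellGeometry) -> float:
    """Per-kinetochore Cdc20 arrival rate 4*a*D/V (1/s).

    Equivalent to the spherical-cell form 3*a*D/(pi*R^3) when
    V = 4*pi*R^3/3.  Note this does *not* reproduce the tabulated PTK2
    default of 2e-4 1/s (see module docstring).
    """
    return 4.0 * geom.a * geom.D / geom.V


def k_minus1_smoluchowski(geom: CellGeometry) -> float:
    """Diffusion-limited Cdc20 inhibition rate 2*pi*b*D*[MCC] (1/s).

    [MCC] is the MCC number density in molecules/um^3, taken from the
    geometry's copy number or nM concentration.
    """
    return 2.0 * math.pi * geom.b * geom.D * geom.mcc_density


def nanomolar_to_copies(conc_nM: float, V_um3: float) -> int:
    """Convert a concentration (nM) in a volume (um^3) to a molecule count."""
    if conc_nM < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {conc_nM}")
    if not V_um3 > 0:
        raise InvalidParameterError(f"volume must be > 0, got {V_um3}")
    return round(conc_nM * 1e-9 * AVOGADRO * V_um3 * _L_PER_UM3)


def copies_to_nanomolar(copies: float, V_um3: float) -> float:
    """Inverse of :func:`nanomolar_to_copies` (exact, no rounding)."""
    if copies < 0:
        raise InvalidParameterError(f"copy number must be >= 0, got {copies}")
    if not V_um3 > 0:
        raise InvalidParameterError(f"volume must be > 0, got {V_um3}")
    return copies / (1e-9 * AVOGADRO * V_um3 * _L_PER_UM3)


#: Reference PTK2 (rat-kangaroo kidney) cell geometry: flat cell
#: ~10 x 10 x 1 um, ~1e4 MCC copies (200 nM Mad2 scale).
PTK2_GEOMETRY = CellGeometry(V=100.0, a=1e-2, b=2e-3, D=20.0, mcc_copies=10000)


def default_ptk2_parameters() -> RateParameters:
    """Reference kinetic parameters for a PTK2 cell.

    lambda*S = 0.3 1/s with S = 3000 (50 nM complex pool in 100 um^3),
    k_minus1 = 24 1/s (Smoluchowski estimate at ~1e4 MCC, rounded),
    mu = 2e-4 1/s (tabulated value, used verbatim), N = 13 chromosomes.
    """
    S = 3000
    return RateParameters(lambda_=0.3 / S, k_minus1=24.0, mu=2e-4, N=13, S=S)
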