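"""Configuration resolution: YAML/JSON -> RateParameters + ConstraintSpec.

Missing fields fall back to the PTK2 reference cell; contradictory
specifications (a rate both given and derived, or two encodings of the
same quantity) are rejected with field-level messages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .constraints import ConstraintSpec
from .errors import ConfigError, InvalidParameterError
from .parameters import (
    PTK2_GEOMETRY,
    CellGeometry,
    RateParameters,
    k_minus1_smoluchowski,
    mu_from_geometry,
)

__all__ = ["ResolvedConfig", "validate_config", "load_config"]

_GEOMETRY_KEYS = {
    "volume_um3",
    "apc_radius_um",
    "binding_site_radius_um",
    "diffusion_um2_s",
    "mcc_copies",
    "mcc_conc_nM",
}
_RATE_KEYS = {
    "n_chromosomes",
    "pool_size",
    "lambda_per_s",
    "lambdaS_per_s",
    "k_minus1_per_s",
    "derive_k_minus1",
    "mu_per_s",
    "derive_mu",
}
_CONSTRAINT_KEYS = {"tau1_s", "p_threshold", "tau_prime_s"}
_KNOWN_KEYS = _GEOMETRY_KEYS | _RATE_KEYS | _CONSTRAINT_KEYS


@dataclass(frozen=True)
class ResolvedConfig:
    params: RateParameters
    constraints: ConstraintSpec
    geometry: CellGeometry

    def __iter__(self):
        # allow ``params, spec = validate_config(...)``
        return iter((self.params, self.constraints))


def _positive(cfg, key, default):
    value = cfg.get(key, default)
    if not isinstance(value, (int, float)) or not value > 0:
        raise ConfigError(f"{key} must be a positive number, got {value!r}")
    return value


def validate_config(config: dict | None) -> ResolvedConfig:
    """Resolve a configuration mapping against the PTK2 defaults.

    An empty (or None) mapping yields the full reference parameter set.
    Raises :class:`ConfigError` naming the offending field on schema
    violations or contradictions.
    """
    cfg = dict(config or {})
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    V = _positive(cfg, "volume_um3", PTK2_GEOMETRY.V)
    a = _positive(cfg, "apc_radius_um", PTK2_GEOMETRY.a)
    b = _positive(cfg, "binding_site_radius_um", PTK2_GEOMETRY.b)
    D = _positive(cfg, "diffusion_um2_s", PTK2_GEOMETRY.D)
    if "mcc_copies" in cfg and "mcc_conc_nM" in cfg:
        raise ConfigError("give only one of mcc_copies and mcc_conc_nM")
    if "mcc_conc_nM" in cfg:
        mcc_kwargs = {"mcc_conc_nM": cfg["mcc_conc_nM"]}
    else:
        mcc_kwargs = {"mcc_copies": cfg.get("mcc_copies", PTK2_GEOMETRY.mcc_copies)}
    try:
        geometry = CellGeometry(V=V, a=a, b=b, D=D, **mcc_kwargs)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc

    N = cfg.get("n_chromosomes", 13)
    S = cfg.get("pool_size", 3000)
    if not isinstance(N, int) or N < 1:
        raise ConfigError(f"n_chromosomes must be a positive integer, got {N!r}")
    if not isinstance(S, int) or S <= N:
        raise ConfigError(f"pool_size must be an integer > n_chromosomes, got {S!r}")

    if "lambda_per_s" in cfg and "lambdaS_per_s" in cfg:
        raise ConfigError("give only one of lambda_per_s and lambdaS_per_s")
    if "lambdaS_per_s" in cfg:
        lam = cfg["lambdaS_per_s"] / S
    else:
        lam = cfg.get("lambda_per_s", 0.3 / S)

    if cfg.get("derive_mu", False):
        if "mu_per_s" in cfg:
            raise ConfigError("mu_per_s contradicts derive_mu")
        mu = mu_from_geometry(geometry)
    else:
        mu = cfg.get("mu_per_s", 2e-4)

    if cfg.get("derive_k_minus1", False):
        if "k_minus1_per_s" in cfg:
            raise ConfigError("k_minus1_per_s contradicts derive_k_minus1")
        k1 = k_minus1_smoluchowski(geometry)
    else:
        k1 = cfg.get("k_minus1_per_s", 24.0)

    try:
        params = RateParameters(lambda_=lam, k_minus1=k1, mu=mu, N=N, S=S)
        constraints = ConstraintSpec(
            tau1=cfg.get("tau1_s", 1200.0),
            p_threshold=cfg.get("p_threshold", 0.95),
            tau_prime=cfg.get("tau_prime_s", 600.0),
        )
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return ResolvedConfig(params=params, constraints=constraints, geometry=geometry)


def load_config(path: str | Path | None) -> ResolvedConfig:
    """Read a YAML or JSON configuration file and resolve it."""
    if path is None:
        return validate_config({})
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data)}")
    return validate_config(data)
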