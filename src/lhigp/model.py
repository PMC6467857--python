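"""Core bioenergetic model of a life-history intraguild predation (LHIGP) system.

The community has three species and four biomass compartments: a shared
basal resource ``R`` with semichemostat renewal, a specialist consumer
``C``, and a stage-structured intraguild predator split into juveniles
``Pj`` and adults ``Pa``.  Juvenile predators compete with the consumer
for the resource; adult predators prey on the consumer (and, with
cannibalistic preference ``beta > 0``, on conspecific juveniles) and may
also feed on the resource (``a_ar > 0``, "diet broadening").

An ontogenetic trade-off links the juvenile resource attack rate
``a_jr`` (the evolving trait) to the adult predation attack rate
``a_ac``::

    a_ac = (a_p - a_jr) / (1 + epsilon * a_jr / a_p)

so increased juvenile resource specialization comes at the cost of
reduced adult predation ability.  All rates are mass-specific and all
quantities are in dimensionless model units.

This module holds the parameter and state containers, every per-capita
rate expression (Holling type-II ingestion, net biomass production,
cannibalistic juvenile mortality, the stage-structured maturation
function) and the right-hand side of the four ordinary differential
equations.  Everything downstream (integration, continuation, adaptive
dynamics) is built on :func:`rhs` and :func:`rates`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "ModelParameters",
    "CommunityState",
    "RateBundle",
    "tradeoff_adult_attack",
    "ingestion_rates",
    "net_production",
    "juvenile_mortality",
    "maturation_rate",
    "rates",
    "rhs",
]

#: Order of the state vector everywhere in the package.
SPECIES = ("R", "C", "Pj", "Pa")


class ParameterError(ValueError):
    """A parameter set violates the model's domain constraints."""


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All constants of the LHIGP model.

    ``a_jr`` is the evolving trait; ``a_ar`` (adult resource feeding),
    ``beta`` (cannibalistic preference), ``epsilon`` (trade-off shape)
    and ``R_max`` (productivity) are the scenario axes.  The adult
    predation attack rate ``a_ac`` is always derived from the trade-off
    and never stored independently.

    Defaults are the standard parameterization: consumer constants from
    a half-saturation of 1 and quarter-power allometric scaling, and
    predator constants from a predator-prey body-mass ratio of 42 (see
    :func:`lhigp.scenarios.allometry_check`).
    """

    a_jr: float
    a_ar: float
    beta: float
    a_cr: float = 10.0
    a_p: float = 6.0
    epsilon: float = 0.0
    h_c: float = 0.1
    h_p: float = 0.25
    T_c: float = 1.0
    T_p: float = 0.4
    mu_c: float = 0.1
    mu_p: float = 0.04
    sigma: float = 0.5
    z: float = 0.01
    delta: float = 1.0
    R_max: float = 3.0

    def __post_init__(self) -> None:
        for name in ("a_jr", "a_ar", "beta", "a_cr", "a_p", "h_c", "h_p",
                     "T_c", "T_p", "mu_c", "mu_p", "delta", "R_max"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.epsilon <= -1:
            raise ParameterError(f"epsilon must exceed -1, got {self.epsilon}")
        if not 0 < self.z < 1:
            raise ParameterError(f"z must lie in (0, 1), got {self.z}")
        if not 0 < self.sigma <= 1:
            raise ParameterError(f"sigma must lie in (0, 1], got {self.sigma}")
        if self.a_jr > self.a_p:
            raise ParameterError(
                f"trait a_jr={self.a_jr} outside trade-off domain [0, a_p={self.a_p}]")

    @property
    def a_ac(self) -> float:
        """Adult predation attack rate implied by the trade-off."""
        return tradeoff_adult_attack(self.a_jr, self.a_p, self.epsilon)

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParameters":
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ParameterError("YAML parameter document must be a mapping")
        return cls.from_dict(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


@dataclasses.dataclass(frozen=True)
class CommunityState:
    """Biomass densities of resource, consumer and the two predator stages."""

    R: float
    C: float
    Pj: float
    Pa: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.C, self.Pj, self.Pa], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "CommunityState":
        R, C, Pj, Pa = (float(v) for v in y)
        return cls(R, C, Pj, Pa)


@dataclasses.dataclass(frozen=True)
class RateBundle:
    """All per-capita rates at one community state.

    ``I_*`` are mass-specific ingestion rates, ``nu_*`` the net biomass
    production rates (assimilation minus maintenance), ``D_j`` the total
    juvenile mortality including cannibalism, and ``gamma`` the
    juvenile-to-adult maturation rate.
    """

    I_c: float
    I_j: float
    I_a: float
    nu_c: float
    nu_j: float
    nu_a: float
    D_j: float
    gamma: float


def tradeoff_adult_attack(a_jr: float, a_p: float, epsilon: float) -> float:
    """Adult predation attack rate from the ontogenetic trade-off.

    ``a_ac = (a_p - a_jr) / (1 + epsilon * a_jr / a_p)``; strictly
    decreasing in the trait with endpoints ``a_ac(0) = a_p`` and
    ``a_ac(a_p) = 0`` for every admissible shape ``epsilon > -1``.
    """
    if epsilon <= -1:
        raise ParameterError(f"epsilon must exceed -1, got {epsilon}")
    if not 0 <= a_jr <= a_p:
        raise ParameterError(f"a_jr={a_jr} outside trade-off domain [0, {a_p}]")
    return (a_p - a_jr) / (1.0 + epsilon * a_jr / a_p)


def _as_array(state) -> np.ndarray:
    if isinstance(state, CommunityState):
        return state.as_array()
    return np.asarray(state, dtype=float)


def _adult_encounter(y: np.ndarray, p: ModelParameters) -> float:
    """Total prey encounter a_ar*R + a_ac*(C + beta*Pj) of adult predators."""
    R, C, Pj, _ = y
    return p.a_ar * R + p.a_ac * (C + p.beta * Pj)


def ingestion_rates(state, p: ModelParameters) -> tuple[float, float, float]:
    """Mass-specific ingestion (I_c, I_j, I_a), Holling type II.

    The adult functional response pools resource, consumer and
    beta-discounted conspecific juveniles in a single denominator.
    """
    y = _as_array(state)
    R = y[0]
    I_c = p.a_cr * R / (1.0 + p.h_c * p.a_cr * R)
    I_j = p.a_jr * R / (1.0 + p.h_p * p.a_jr * R)
    enc = _adult_encounter(y, p)
    I_a = enc / (1.0 + p.h_p * enc)
    return I_c, I_j, I_a


def net_production(I: float, p: ModelParameters, role: str) -> float:
    """Net biomass production nu = sigma * I - T for the given role.

    May be negative (starvation); the sign of ``nu`` decides whether a
    stage can grow/reproduce at all.
    """
    if role == "consumer":
        return p.sigma * I - p.T_c
    if role in ("juvenile", "adult"):
        return p.sigma * I - p.T_p
    raise ValueError(f"unknown role {role!r}")


def juvenile_mortality(state, p: ModelParameters) -> float:
    """Total juvenile mortality: background mu_p plus cannibalism.

    The cannibalism term shares the adult functional-response
    denominator, so it saturates together with adult feeding.
    """
    y = _as_array(state)
    Pa = y[3]
    enc = _adult_encounter(y, p)
    return p.mu_p + p.a_ac * p.beta * Pa / (1.0 + p.h_p * enc)


def maturation_rate(nu_j: float, D_j: float, z: float) -> float:
    """Stage-structured maturation rate gamma(nu_j, D_j).

    gamma = (nu_j - D_j) / (1 - z**(1 - D_j/nu_j)) for nu_j > 0, with the
    removable singularity at nu_j == D_j evaluated exactly as
    -nu_j / ln(z), and gamma = 0 for nu_j <= 0 (starving juveniles do
    not mature).  The form guarantees that the two-stage model has the
    same equilibria as a fully size-structured formulation with
    exponential growth from size z to 1.
    """
    if not 0 < z < 1:
        raise ParameterError(f"z must lie in (0, 1), got {z}")
    if nu_j <= 0:
        return 0.0
    lnz = math.log(z)
    t = (1.0 - D_j / nu_j) * lnz
    if t == 0.0:
        return -nu_j / lnz
    if t > 700.0:
        # mortality vastly exceeds growth: survival to maturation ~ e^{-t} -> 0
        return 0.0
    # gamma = nu_j * (1 - D_j/nu_j) / (1 - e^t) = -(nu_j/lnz) * t/expm1(t)
    return -(nu_j / lnz) * (t / math.expm1(t))


def rates(state, p: ModelParameters) -> RateBundle:
    """All per-capita rates of Table-style bookkeeping at one state."""
    y = _as_array(state)
    I_c, I_j, I_a = ingestion_rates(y, p)
    nu_c = net_production(I_c, p, "consumer")
    nu_j = net_production(I_j, p, "juvenile")
    nu_a = net_production(I_a, p, "adult")
    D_j = juvenile_mortality(y, p)
    gamma = maturation_rate(nu_j, D_j, p.z)
    return RateBundle(I_c, I_j, I_a, nu_c, nu_j, nu_a, D_j, gamma)


def rhs(state, p: ModelParameters) -> np.ndarray:
    """Time derivatives (dR, dC, dPj, dPa) of the four biomass ODEs.

    Resource follows semichemostat renewal delta*(R_max - R) minus all
    ingestion losses.  Reproduction and maturation are one-way fluxes:
    the reproduction flux into juveniles uses the positive part of adult
    net production, with a negative nu_a retained as biomass loss in the
    adult equation itself (and likewise gamma = 0 when nu_j <= 0, with
    the negative nu_j kept as juvenile biomass loss).  No clamping is
    performed here; keeping the state non-negative is the integrator's
    concern.
    """
    y = _as_array(state)
    R, C, Pj, Pa = y
    b = rates(y, p)
    enc = _adult_encounter(y, p)
    den = 1.0 + p.h_p * enc
    nu_a_pos = max(b.nu_a, 0.0)
    nu_a_neg = min(b.nu_a, 0.0)
    dR = p.delta * (p.R_max - R) - b.I_c * C - b.I_j * Pj - p.a_ar * R / den * Pa
    dC = b.nu_c * C - p.a_ac * Pa / den * C - p.mu_c * C
    dPj = nu_a_pos * Pa + b.nu_j * Pj - b.gamma * Pj - b.D_j * Pj
    dPa = b.gamma * Pj - p.mu_p * Pa + nu_a_neg * Pa
    return np.array([dR, dC, dPj, dPa])
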