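"""Closed-form competitive-hierarchy thresholds between consumer and predator.

Which of the two competitors can subsist on the lower resource level
decides the qualitative outcome of every scenario, so these thresholds
are computed analytically and used both to pre-classify parameter sets
and as independent anchors for the numerical machinery.

* ``consumer_min_resource`` — the resource density R*_C at which
  consumer net biomass production exactly covers background mortality;
  consumers invade any state with R > R*_C.
* ``juvenile_growth_threshold`` — the trait value below which juvenile
  predators cannot grow (nu_j <= 0) at a given resource density.
* ``predator_min_resource`` — the resource density R*_P at which a
  predator population subsisting on the resource alone (no consumers,
  no conspecifics) has lifetime reproductive success exactly one.

A threshold that does not exist (the species cannot persist at any
density) is reported as ``inf`` so that ordering comparisons remain
well defined.
"""

from __future__ import annotations

import dataclasses
import json
import math

from scipy.optimize import brentq

from .model import ModelParameters, tradeoff_adult_attack

__all__ = [
    "HierarchyReport",
    "consumer_min_resource",
    "juvenile_growth_threshold",
    "predator_min_resource",
    "resource_only_R0",
    "classify_hierarchy",
]


@dataclasses.dataclass(frozen=True)
class HierarchyReport:
    """Competitive-hierarchy summary at one parameter set."""

    R_star_consumer: float
    R_star_predator: float
    a_jr_growth_threshold: float
    hierarchy: str  # consumers_superior | juveniles_grow_consumers_superior | predators_superior

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def consumer_min_resource(p: ModelParameters) -> float:
    """Minimum resource density for consumer persistence, R*_C.

    Solves sigma*I_c(R) = T_c + mu_c:
    R*_C = (T_c + mu_c) / (a_cr * (sigma - h_c*(T_c + mu_c))).
    Returns ``inf`` when saturation can never cover the losses.
    """
    loss = p.T_c + p.mu_c
    denom = p.a_cr * (p.sigma - p.h_c * loss)
    if denom <= 0.0:
        return math.inf
    return loss / denom


def juvenile_growth_threshold(p: ModelParameters, R: float) -> float:
    """Trait value a_jr at which juvenile net production is zero at R.

    a_jr^grow = T_p / (R * (sigma - h_p*T_p)); juveniles with a smaller
    trait starve at resource level R.  ``inf`` when no trait allows
    growth.
    """
    denom = p.sigma - p.h_p * p.T_p
    if denom <= 0.0 or R <= 0.0:
        return math.inf
    return p.T_p / (R * denom)


def resource_only_R0(R: float, p: ModelParameters) -> float:
    """Predator lifetime reproductive success on the resource alone.

    C = 0 and no resident conspecifics, so juvenile mortality is just
    mu_p: R0(R) = z**(mu_p/nu_j(R) - 1) * max(nu_a(R), 0)/mu_p with
    nu_a from adult resource feeding only.
    """
    I_j = p.a_jr * R / (1.0 + p.h_p * p.a_jr * R)
    nu_j = p.sigma * I_j - p.T_p
    if nu_j <= 0.0:
        return 0.0
    I_a = p.a_ar * R / (1.0 + p.h_p * p.a_ar * R)
    nu_a = p.sigma * I_a - p.T_p
    return p.z ** (p.mu_p / nu_j - 1.0) * max(nu_a, 0.0) / p.mu_p


def predator_min_resource(p: ModelParameters, *, xtol: float = 1e-12) -> float:
    """Minimum resource density for predator persistence alone, R*_P.

    Root in R of resource-only R0 = 1 on (0, R_max]; ``inf`` when even
    R_max cannot sustain the population (e.g. the diet-shift scenario,
    where adults starve without consumers).
    """
    if p.a_ar <= 0.0 and p.a_jr <= 0.0:
        return math.inf
    f_top = resource_only_R0(p.R_max, p) - 1.0
    if f_top < 0.0:
        return math.inf
    lo, hi = 1e-12, p.R_max
    # R0 is monotone increasing in R; bisect on R0 - 1
    return brentq(lambda R: resource_only_R0(R, p) - 1.0, lo, hi, xtol=xtol)


def classify_hierarchy(p: ModelParameters) -> str:
    """Which competitor wins at the resource level set by the other.

    ``predators_superior`` when the predator persists on a lower
    resource level than the consumer needs; otherwise
    ``juveniles_grow_consumers_superior`` when juvenile predators can at
    least grow at the consumer's equilibrium resource density; else
    ``consumers_superior``.
    """
    R_C = consumer_min_resource(p)
    R_P = predator_min_resource(p)
    if math.isfinite(R_P) and R_P < R_C:
        return "predators_superior"
    thr = juvenile_growth_threshold(p, R_C) if math.isfinite(R_C) else math.inf
    if p.a_jr > thr:
        return "juveniles_grow_consumers_superior"
    return "consumers_superior"


def hierarchy_report(p: ModelParameters) -> HierarchyReport:
    R_C = consumer_min_resource(p)
    return HierarchyReport(
        R_star_consumer=R_C,
        R_star_predator=predator_min_resource(p),
        a_jr_growth_threshold=(juvenile_growth_threshold(p, R_C)
                               if math.isfinite(R_C) else math.inf),
        hierarchy=classify_hierarchy(p),
    )
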