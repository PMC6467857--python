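"""Adaptive dynamics of juvenile resource specialization.

The evolving trait is the juvenile resource attack rate ``a_jr``; the
adult predation attack rate follows from the ontogenetic trade-off.  A
rare mutant's fate in the environment set by a resident at its
ecological equilibrium is captured by its lifetime reproductive success

    R0(y', y) = z**(D_j'/nu_j' - 1) * max(nu_a', 0) / mu_p   (nu_j' > 0)

with R0 = 0 when mutant juveniles cannot grow (nu_j' <= 0).  The closed
form follows from the stage-structured bookkeeping: juveniles grow
exponentially at rate nu_j' from relative size z to 1, surviving with
probability z**(D_j'/nu_j'); adults live 1/mu_p on average and convert
their net production nu_a' into offspring of size z.  At any resident
equilibrium with predators present R0(y, y) = 1 identically, which the
test suite uses to validate the closed form against the ODE equilibria.

Selection follows the sign of dR0/dy' at y' = y.  Singular strategies
are roots of this gradient along a stable resident branch, classified
by convergence stability (does gradual evolution approach?) and
evolutionary stability (can nearby mutants invade?).  Gradual evolution
itself is modelled as deterministic trait steps in the gradient
direction with the resident equilibrium re-solved after each step;
when the resident equilibrium disappears (fold) or loses stability, the
post-transition community attractor is identified — the evolutionary
half of evolutionary suicide.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .continuation import (Equilibrium, EquilibriumError, solve_equilibrium)
from .model import ModelParameters, tradeoff_adult_attack

__all__ = [
    "SingularStrategy",
    "TraitTrajectory",
    "invasion_fitness_R0",
    "selection_gradient",
    "find_singular_strategy",
    "classify_singular_strategy",
    "trait_trajectory",
    "resident_equilibrium",
]


class ResidentError(RuntimeError):
    """No suitable (stable, predator-positive) resident equilibrium."""


def mutant_rates(mutant_a_jr: float, resident_eq: Equilibrium,
                 p: ModelParameters | None = None) -> tuple[float, float, float]:
    """(nu_j', D_j', nu_a') of a rare mutant in the resident environment.

    The mutant's juvenile feeds on the resident resource with its own
    trait; it suffers cannibalism from resident adults (resident attack
    rate, resident functional-response denominator).  The mutant adult
    feeds on resident resource, consumers and beta-discounted resident
    juveniles with its own trade-off attack rate in its own functional
    response.
    """
    if p is None:
        p = resident_eq.params
    R, C, Pj, Pa = resident_eq.state
    a_ac_mut = tradeoff_adult_attack(mutant_a_jr, p.a_p, p.epsilon)
    a_ac_res = p.a_ac
    # mutant juvenile
    I_j = mutant_a_jr * R / (1.0 + p.h_p * mutant_a_jr * R)
    nu_j = p.sigma * I_j - p.T_p
    # cannibalistic mortality from resident adults
    enc_res = p.a_ar * R + a_ac_res * (C + p.beta * Pj)
    D_j = p.mu_p + a_ac_res * p.beta * Pa / (1.0 + p.h_p * enc_res)
    # mutant adult feeding in the resident environment
    enc_mut = p.a_ar * R + a_ac_mut * (C + p.beta * Pj)
    I_a = enc_mut / (1.0 + p.h_p * enc_mut)
    nu_a = p.sigma * I_a - p.T_p
    return nu_j, D_j, nu_a


def invasion_fitness_R0(mutant_a_jr: float, resident_eq: Equilibrium,
                        p: ModelParameters | None = None, *,
                        check_resident: bool = False) -> float:
    """Lifetime reproductive success of a rare mutant, R0(y', y).

    ``resident_eq`` may be any equilibrium: a predator-positive resident
    or a CR/PR state for invasion-from-zero questions.  With
    ``check_resident=True`` an unstable or unresolved resident is
    rejected.
    """
    if check_resident:
        if resident_eq.residual_norm > 1e-8:
            raise ResidentError(
                f"resident residual {resident_eq.residual_norm:.2e} too large")
        if not resident_eq.stable:
            raise ResidentError("resident equilibrium is not stable")
    if p is None:
        p = resident_eq.params
    nu_j, D_j, nu_a = mutant_rates(mutant_a_jr, resident_eq, p)
    if nu_j <= 0.0:
        return 0.0
    return p.z ** (D_j / nu_j - 1.0) * max(nu_a, 0.0) / p.mu_p


def selection_gradient(resident_eq: Equilibrium, p: ModelParameters | None = None,
                       *, step: float | None = None) -> float:
    """dR0/dy' at y' = y: the direction of gradual trait evolution.

    Central finite difference; one-sided near the trait bounds 0 and
    a_p.
    """
    if p is None:
        p = resident_eq.params
    y = p.a_jr
    h = step if step is not None else 1e-6 * p.a_p
    lo, hi = 0.0, p.a_p
    if y - h < lo:
        return (invasion_fitness_R0(y + h, resident_eq, p)
                - invasion_fitness_R0(y, resident_eq, p)) / h
    if y + h > hi:
        return (invasion_fitness_R0(y, resident_eq, p)
                - invasion_fitness_R0(y - h, resident_eq, p)) / h
    return (invasion_fitness_R0(y + h, resident_eq, p)
            - invasion_fitness_R0(y - h, resident_eq, p)) / (2.0 * h)


# ---------------------------------------------------------------------------
# Resident tracking


def _acceptable_resident(eq: Equilibrium, require_stable: bool,
                         allow_oscillatory: bool) -> bool:
    if eq.stable or not require_stable:
        return True
    if allow_oscillatory:
        # tolerate a Hopf-type instability: every eigenvalue with positive
        # real part is part of a complex pair, so the equilibrium is
        # surrounded by a small-amplitude cycle rather than abandoned
        # (real instabilities -- folds, invasions -- are genuine exits)
        bad = eq.eigenvalues[eq.eigenvalues.real > 0]
        return bad.size > 0 and bool(np.all(np.abs(bad.imag) > 0))
    return False


def resident_equilibrium(p: ModelParameters, *, prev: Equilibrium | None = None,
                         require_stable: bool = True,
                         allow_oscillatory: bool = False,
                         presence_tol: float = 1e-8) -> Equilibrium:
    """Stable predator-positive equilibrium at parameters ``p``.

    Continues from ``prev`` by Newton when given; if the consumer (or
    another component) leaves the equilibrium the solve is retried on
    the reduced species set, which carries a branch smoothly through a
    transcritical (e.g. the coexistence state turning into a
    predator-resource state as consumers go extinct).  Without ``prev``
    the attractor is sought by time integration from canonical predator
    seeds.  With ``allow_oscillatory`` an equilibrium destabilized only
    by a complex eigenvalue pair (a Hopf bifurcation) still counts: the
    attractor is then a nearby small-amplitude cycle that the analysis
    treats as its enclosed equilibrium.
    """
    from .dynamics import find_attractor

    candidates: list[Equilibrium] = []
    if prev is not None:
        for absent in _absent_fallbacks(prev.absent):
            guess = prev.state.copy()
            try:
                eq = solve_equilibrium(guess, p, absent, presence_tol=presence_tol)
            except EquilibriumError:
                continue
            if eq.has_predators(presence_tol) and _acceptable_resident(
                    eq, require_stable, allow_oscillatory):
                return eq
            candidates.append(eq)
    # from scratch (also the fallback when continuation from prev strays,
    # e.g. after a large trait jump between root-finder iterates)
    for s0 in (np.array([0.5 * p.R_max, 0.5, 0.3, 0.3]),
               np.array([0.5 * p.R_max, 0.0, 0.5, 0.5]),
               np.array([p.R_max, 0.1, 0.1, 0.1])):
        rep = find_attractor(s0, p)
        if (rep.status == "equilibrium" and rep.equilibrium is not None
                and rep.equilibrium.has_predators(presence_tol)
                and (rep.equilibrium.stable or not require_stable)):
            return rep.equilibrium
    raise ResidentError(
        f"no stable predator-positive equilibrium at a_jr={p.a_jr}"
        + (f" (best: {candidates[-1].label}, stable={candidates[-1].stable})"
           if candidates else ""))


def _absent_fallbacks(absent: frozenset) -> list:
    """Species sets to try when continuing a resident: same set first,
    then with the consumer dropped/restored."""
    options = [absent]
    if "C" not in absent:
        options.append(absent | {"C"})
    else:
        options.append(absent - {"C"})
    return options


# ---------------------------------------------------------------------------
# Singular strategies


@dataclasses.dataclass(frozen=True)
class SingularStrategy:
    """A root of the selection gradient with its stability classification."""

    a_jr: float
    equilibrium: Equilibrium
    convergence_stable: bool
    evolutionarily_stable: bool
    gradient: float
    d2R0_dm2: float          # mutant-trait curvature of the fitness landscape
    dgrad_dres: float        # slope of the gradient along the resident branch
    degenerate: bool = False

    @property
    def is_css(self) -> bool:
        return self.convergence_stable and self.evolutionarily_stable


def _gradient_at(y: float, p: ModelParameters, cache: dict,
                 presence_tol: float = 1e-8) -> float:
    p_y = p.replace(a_jr=float(np.clip(y, 0.0, p.a_p)))
    eq = resident_equilibrium(p_y, prev=cache.get("eq"), presence_tol=presence_tol)
    if not eq.stable:
        raise ResidentError(f"resident branch loses stability at a_jr={y}")
    cache["eq"] = eq
    return selection_gradient(eq, p_y)


def find_singular_strategy(p: ModelParameters, trait_bracket: tuple[float, float],
                           *, xtol: float = 1e-8,
                           presence_tol: float = 1e-8) -> SingularStrategy | None:
    """Root of the selection gradient on the stable resident branch.

    The resident equilibrium is re-solved at every trial trait (tracked
    by continuation from the previous one).  Returns ``None`` when the
    gradient does not change sign over the bracket; raises
    :class:`ResidentError` if the branch loses stability inside it.
    """
    a, b = trait_bracket
    cache: dict = {}
    g_a = _gradient_at(a, p, cache, presence_tol)
    g_b = _gradient_at(b, p, cache, presence_tol)
    if g_a * g_b > 0:
        return None
    y_star = brentq(lambda y: _gradient_at(y, p, cache, presence_tol), a, b,
                    xtol=xtol)
    return classify_singular_strategy(float(y_star), p, presence_tol=presence_tol)


def classify_singular_strategy(y_star: float, p: ModelParameters, *,
                               h2: float | None = None,
                               presence_tol: float = 1e-8,
                               noise_floor: float = 1e-7) -> SingularStrategy:
    """Convergence and evolutionary stability of a singular trait value.

    Evolutionary stability from the sign of the mutant-trait curvature
    d2R0/dy'2 at the singular resident (negative: a fitness maximum, no
    nearby mutant invades).  Convergence stability from the slope of the
    selection gradient along the resident branch (negative: gradual
    evolution approaches).  Second differences below ``noise_floor``
    are flagged degenerate rather than silently classified.
    """
    h = h2 if h2 is not None else 1e-4 * p.a_p
    p_star = p.replace(a_jr=float(y_star))
    eq = resident_equilibrium(p_star, presence_tol=presence_tol)
    g_star = selection_gradient(eq, p_star)
    # fitness-landscape curvature in the mutant trait (resident fixed)
    r_plus = invasion_fitness_R0(min(y_star + h, p.a_p), eq, p_star)
    r_minus = invasion_fitness_R0(max(y_star - h, 0.0), eq, p_star)
    d2 = (r_plus + r_minus - 2.0 * invasion_fitness_R0(y_star, eq, p_star)) / h ** 2
    # gradient slope along the branch (resident re-solved)
    cache = {"eq": eq}
    g_hi = _gradient_at(min(y_star + h, p.a_p), p, cache, presence_tol)
    cache["eq"] = eq
    g_lo = _gradient_at(max(y_star - h, 0.0), p, cache, presence_tol)
    dgrad = (g_hi - g_lo) / (2.0 * h)
    degenerate = abs(d2) < noise_floor or abs(dgrad) < noise_floor
    return SingularStrategy(
        a_jr=float(y_star), equilibrium=eq,
        convergence_stable=bool(dgrad < 0.0),
        evolutionarily_stable=bool(d2 < 0.0),
        gradient=float(g_star), d2R0_dm2=float(d2), dgrad_dres=float(dgrad),
        degenerate=degenerate)


# ---------------------------------------------------------------------------
# Trait-substitution trajectories


@dataclasses.dataclass
class TraitTrajectory:
    """Gradient-driven trait evolution with its ecological bookkeeping."""

    records: list  # dicts per accepted step
    status: str  # singular_strategy | boundary_ap | fold_crossed_extinction | undecided
    singular: SingularStrategy | None = None
    post_collapse: object | None = None  # AttractorReport after a collapse
    last_R0_in_post: float | None = None  # re-invasion fitness after a collapse

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def final_trait(self) -> float:
        return self.records[-1]["a_jr"]


def _record(step: int, eq: Equilibrium, gradient: float, status: str) -> dict:
    p = eq.params
    return {
        "step": step, "a_jr": p.a_jr, "a_ac": p.a_ac, "class": eq.label,
        "R": eq.R, "C": eq.C, "Pj": eq.Pj, "Pa": eq.Pa,
        "gradient": gradient, "status": status,
    }


def trait_trajectory(y0: float, p: ModelParameters, *, eta: float | None = None,
                     eta_min: float | None = None, g_tol: float = 1e-6,
                     max_steps: int = 2000, inoculum: float = 1e-6,
                     presence_tol: float = 1e-8) -> TraitTrajectory:
    """Follow gradual evolution of the trait from ``y0``.

    The trait moves by ``eta`` (default 0.01*a_p) in the direction of
    the selection gradient, with the resident equilibrium re-solved by
    continuation after every step.  On a sign change of the gradient the
    singular strategy inside the bracket is located and classified.  If
    the resident equilibrium disappears (fold) or loses stability, the
    post-transition attractor is identified by time integration from the
    pre-collapse state, inoculating species absent from the resident (an
    invasion-driven collapse needs the invader present); predator
    extinction there is evolutionary suicide.  Termination at the upper
    trait bound with a persisting predator is ``boundary_ap`` (the
    predator has become a pure resource specialist, a_ac = 0).
    """
    from .dynamics import find_attractor

    eta = eta if eta is not None else 0.01 * p.a_p
    eta_min = eta_min if eta_min is not None else 1e-5 * p.a_p
    y = float(y0)
    p_y = p.replace(a_jr=y)
    eq = resident_equilibrium(p_y)
    records: list[dict] = []
    prev_sign = 0.0

    for step_i in range(max_steps):
        g = selection_gradient(eq, eq.params)
        records.append(_record(step_i, eq, g, "evolving"))
        if abs(g) < g_tol:
            ss = classify_singular_strategy(y, p, presence_tol=presence_tol)
            records[-1]["status"] = "singular_strategy"
            return TraitTrajectory(records, "singular_strategy", singular=ss)
        sign = math.copysign(1.0, g)
        if prev_sign and sign != prev_sign:
            # bracketed a gradient root: hand over to the root finder
            lo, hi = sorted((y, y_prev))
            try:
                ss = find_singular_strategy(p, (lo, hi), presence_tol=presence_tol)
            except ResidentError:
                ss = None
            if ss is not None:
                records[-1]["status"] = "singular_strategy"
                return TraitTrajectory(records, "singular_strategy", singular=ss)
            eta *= 0.5
            if eta < eta_min:
                return TraitTrajectory(records, "undecided")
        prev_sign, y_prev = sign, y

        y_new = float(np.clip(y + sign * eta, 0.0, p.a_p))
        if y_new == y:  # pinned at a bound
            records[-1]["status"] = "boundary_ap" if y >= p.a_p else "undecided"
            return TraitTrajectory(
                records, "boundary_ap" if y >= p.a_p else "undecided")
        p_new = p.replace(a_jr=y_new)
        try:
            eq_new = resident_equilibrium(p_new, prev=eq, allow_oscillatory=True,
                                          presence_tol=presence_tol)
        except ResidentError:
            eq_new = None
        if eq_new is None:
            # ecological transition: find the post-collapse attractor,
            # inoculating whatever species the resident lacked
            s0 = eq.state.copy()
            for i, name in enumerate(("C", "Pj", "Pa"), start=1):
                if s0[i] <= presence_tol:
                    s0[i] = inoculum
            rep = find_attractor(s0, p_new)
            if (rep.status == "equilibrium" and rep.equilibrium is not None
                    and rep.equilibrium.has_predators(presence_tol)):
                # the predator survived the transition on a different branch
                eq = rep.equilibrium
                y = y_new
                continue
            last_R0 = None
            if rep.status == "equilibrium" and rep.equilibrium is not None:
                last_R0 = invasion_fitness_R0(y, rep.equilibrium)
            records.append({
                "step": step_i + 1, "a_jr": y_new,
                "a_ac": tradeoff_adult_attack(y_new, p.a_p, p.epsilon),
                "class": rep.label or "?", "R": float(rep.final_state[0]),
                "C": float(rep.final_state[1]), "Pj": float(rep.final_state[2]),
                "Pa": float(rep.final_state[3]), "gradient": np.nan,
                "status": "fold_crossed_extinction",
            })
            return TraitTrajectory(records, "fold_crossed_extinction",
                                   post_collapse=rep, last_R0_in_post=last_R0)
        y, eq = y_new, eq_new
        if y >= p.a_p and selection_gradient(eq, eq.params) > 0:
            records.append(_record(step_i + 1, eq, np.nan, "boundary_ap"))
            return TraitTrajectory(records, "boundary_ap")
    return TraitTrajectory(records, "undecided")
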