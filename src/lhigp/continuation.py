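"""Equilibria, stability, and numerical continuation with bifurcation detection.

Steady states of the four-compartment LHIGP system come in four classes:
resource only (``R``), consumer-resource (``CR``), predator-resource
(``PR``) and the three-species coexistence state (``PCR``).  This module
solves them directly (Newton on the subsystem of present species),
assesses local stability from the eigenvalues of the full 4x4 Jacobian
(which automatically includes the invasion directions of absent
species), continues equilibrium branches in one parameter with a
secant-predictor / pseudo-arclength Newton corrector that follows
branches around folds, and locates fold and invasion (transcritical)
bifurcations by bracketing and refinement.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .model import (SPECIES, CommunityState, ModelParameters, ParameterError,
                    rates, rhs)

__all__ = [
    "Equilibrium",
    "Branch",
    "BifurcationPoint",
    "EquilibriumError",
    "solve_equilibrium",
    "jacobian",
    "jacobian_eigenvalues",
    "classify_equilibrium",
    "invasion_growth",
    "continue_branch",
    "two_parameter_map",
]

#: Continuable parameters.
SWEEPABLE = ("a_jr", "beta", "R_max", "a_ar", "epsilon")

_IDX = {name: i for i, name in enumerate(SPECIES)}


class EquilibriumError(RuntimeError):
    """Newton failed to converge or converged outside the positive cone."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InconsistentStageError(RuntimeError):
    """Only one predator stage present at a converged equilibrium."""


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    """A solved steady state with its stability diagnostics."""

    state: np.ndarray
    params: ModelParameters
    absent: frozenset
    residual_norm: float
    eigenvalues: np.ndarray
    stable: bool
    label: str

    @property
    def R(self) -> float:
        return float(self.state[0])

    @property
    def C(self) -> float:
        return float(self.state[1])

    @property
    def Pj(self) -> float:
        return float(self.state[2])

    @property
    def Pa(self) -> float:
        return float(self.state[3])

    @property
    def leading_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[0])

    def community_state(self) -> CommunityState:
        return CommunityState.from_array(np.maximum(self.state, 0.0))

    def has_predators(self, tol: float = 1e-8) -> bool:
        return self.Pj + self.Pa > tol


@dataclasses.dataclass(frozen=True)
class BifurcationPoint:
    """A detected fold or invasion boundary along a branch."""

    kind: str  # "fold" | "invasion_boundary"
    param: str
    value: float
    equilibrium: Equilibrium
    species: str | None = None  # whose invasion growth changes sign

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "param": self.param,
            "value": self.value,
            "state": list(map(float, self.equilibrium.state)),
            "species": self.species,
        }


@dataclasses.dataclass
class Branch:
    """An equilibrium branch continued in one parameter."""

    param: str
    points: list
    bifurcations: list
    termination: str = "range_end"

    @property
    def param_values(self) -> np.ndarray:
        return np.array([getattr(eq.params, self.param) for eq in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eq in self.points:
            rows.append({
                "param": getattr(eq.params, self.param),
                "R": eq.R, "C": eq.C, "Pj": eq.Pj, "Pa": eq.Pa,
                "class": eq.label,
                "stable": eq.stable,
                "leading_eigenvalue_re": float(np.real(eq.eigenvalues[0])),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Solving and stability


def jacobian(state, p: ModelParameters, rel_step: float = 1e-7) -> np.ndarray:
    """Central finite-difference 4x4 Jacobian of the ODE right-hand side."""
    y = np.asarray(state, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        h = rel_step * (1.0 + abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        # keep finite differencing inside the positive cone for densities at 0
        if ym[j] < 0.0:
            ym[j] = 0.0
            h = (yp[j] - ym[j]) / 2.0
        J[:, j] = (rhs(yp, p) - rhs(ym, p)) / (2.0 * h)
    return J


def _sorted_eigenvalues(J: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvals(J)
    return ev[np.argsort(-ev.real)]


def jacobian_eigenvalues(eq: Equilibrium) -> np.ndarray:
    """Eigenvalues of the full 4x4 Jacobian, sorted by real part descending."""
    return _sorted_eigenvalues(jacobian(eq.state, eq.params))


def classify_equilibrium(state, presence_tol: float = 1e-8) -> str:
    """Label R / CR / PR / PCR from which components exceed the tolerance.

    Predator presence is judged on the joint biomass Pj + Pa — at any
    true equilibrium the stages are jointly present or jointly absent.
    A state with one stage well above the tolerance and the other at
    zero is structurally inconsistent and raises.
    """
    y = state.state if isinstance(state, Equilibrium) else np.asarray(state, dtype=float)
    c_present = y[1] > presence_tol
    pj, pa = y[2] > presence_tol, y[3] > presence_tol
    if pj != pa and max(y[2], y[3]) > 1e3 * presence_tol:
        raise InconsistentStageError(
            f"one predator stage present without the other: Pj={y[2]}, Pa={y[3]}")
    if y[2] + y[3] > presence_tol:
        return "PCR" if c_present else "PR"
    return "CR" if c_present else "R"


def _embed(u: np.ndarray, present: Sequence[int]) -> np.ndarray:
    y = np.zeros(4)
    y[list(present)] = u
    return y


def solve_equilibrium(guess, p: ModelParameters, absent: Iterable[str] = (),
                      *, tol: float = 1e-13, max_iter: int = 60,
                      presence_tol: float = 1e-8) -> Equilibrium:
    """Newton-solve a steady state on the subsystem of present species.

    ``absent`` species are pinned to exactly zero; for the predator,
    both stages are present or absent together.  The returned
    equilibrium carries eigenvalues of the full 4x4 Jacobian, so the
    invasion directions of absent species enter the stability flag.
    Convergence to a negative density is rejected.
    """
    absent = frozenset(absent)
    if "Pj" in absent or "Pa" in absent:
        absent = absent | {"Pj", "Pa"}
    if "R" in absent:
        raise ValueError("the resource cannot be absent under semichemostat renewal")
    present = [i for i, s in enumerate(SPECIES) if s not in absent]
    y0 = guess.as_array() if isinstance(guess, CommunityState) else np.asarray(guess, dtype=float)
    u = y0[present].astype(float)
    n = len(present)

    def f(u_vec: np.ndarray) -> np.ndarray:
        return rhs(_embed(u_vec, present), p)[present]

    fu = f(u)
    stalled = 0
    for _ in range(max_iter):
        if np.max(np.abs(fu)) < tol or stalled >= 3:
            break
        # finite-difference Jacobian of the reduced system
        Jr = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * (1.0 + abs(u[j]))
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            Jr[:, j] = (f(up) - f(um)) / (2.0 * h)
        try:
            step = np.linalg.solve(Jr, -fu)
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(f"singular Jacobian in Newton: {exc}",
                                   _embed(u, present)) from exc
        # damped update: backtrack while the residual grows
        lam = 1.0
        for _bt in range(30):
            u_new = u + lam * step
            f_new = f(u_new)
            if np.max(np.abs(f_new)) < np.max(np.abs(fu)) or lam < 1e-6:
                break
            lam *= 0.5
        stalled = stalled + 1 if np.max(np.abs(f_new)) >= 0.5 * np.max(np.abs(fu)) else 0
        u, fu = u_new, f_new
    # accept stagnation at rounding level, reject anything coarser
    if np.max(np.abs(fu)) > max(tol, 1e-10):
        raise EquilibriumError(
            f"Newton did not converge (residual {np.max(np.abs(fu)):.3e})",
            _embed(u, present))

    if np.any(u < -1e-12):
        raise EquilibriumError(
            f"converged to negative density {u}", _embed(u, present))
    u = np.maximum(u, 0.0)
    y = _embed(u, present)
    res = float(np.max(np.abs(rhs(y, p))))
    ev = _sorted_eigenvalues(jacobian(y, p))
    label = classify_equilibrium(y, presence_tol)
    stable = bool(np.max(ev.real) < 0.0)
    return Equilibrium(state=y, params=p, absent=absent, residual_norm=res,
                       eigenvalues=ev, stable=stable, label=label)


def invasion_growth(eq: Equilibrium, species: str) -> float:
    """Per-capita invasion growth rate of an absent species at ``eq``.

    For the consumer this is its per-capita growth in the equilibrium
    environment; for the predator it is the dominant eigenvalue of the
    2x2 juvenile/adult linearization at zero predator density (the sign
    of which is equivalent to the sign of R0 - 1).
    """
    p, y = eq.params, eq.state
    b = rates(y, p)
    if species == "C":
        enc = p.a_ar * y[0] + p.a_ac * (y[1] + p.beta * y[2])
        den = 1.0 + p.h_p * enc
        return b.nu_c - p.a_ac * y[3] / den - p.mu_c
    if species in ("P", "Pj", "Pa"):
        nu_a_pos = max(b.nu_a, 0.0)
        nu_a_neg = min(b.nu_a, 0.0)
        block = np.array([
            [b.nu_j - b.gamma - b.D_j, nu_a_pos],
            [b.gamma, -p.mu_p + nu_a_neg],
        ])
        return float(np.max(np.linalg.eigvals(block).real))
    raise ValueError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# One-parameter continuation


def _with_param(p: ModelParameters, param: str, value: float) -> ModelParameters:
    if param not in SWEEPABLE:
        raise ValueError(f"cannot continue in {param!r}; choose one of {SWEEPABLE}")
    return p.replace(**{param: float(value)})


def _solve_at(value: float, param: str, p: ModelParameters, guess: np.ndarray,
              absent: frozenset, **kw) -> Equilibrium:
    return solve_equilibrium(guess, _with_param(p, param, value), absent, **kw)


def _absent_groups(absent: frozenset) -> list:
    groups = []
    if "C" in absent:
        groups.append("C")
    if "Pj" in absent:
        groups.append("P")
    return groups


def continue_branch(eq0: Equilibrium, param: str, lo: float, hi: float,
                    *, ds0: float = 0.01, ds_min: float = 1e-8, ds_max: float = 0.05,
                    max_points: int = 20000, param_tol: float = 1e-6,
                    presence_tol: float = 1e-8, direction: int | None = None) -> Branch:
    """Continue an equilibrium branch over ``param`` in [lo, hi].

    Secant-predictor, pseudo-arclength Newton corrector; the branch is
    followed around folds.  Folds are recorded where the branch turns in
    the parameter and refined to ``param_tol``; invasion boundaries are
    recorded where an absent species' invasion growth changes sign.  If
    a present component hits zero the branch is truncated with reason
    ``"component_extinct"`` and the boundary point recorded.
    """
    absent = eq0.absent
    present = [i for i, s in enumerate(SPECIES) if s not in absent]
    p_base = eq0.params
    lam0 = getattr(p_base, param)
    if not lo <= lam0 <= hi:
        raise ValueError(f"branch start {param}={lam0} outside [{lo}, {hi}]")
    if direction is None:
        direction = 1.0 if (hi - lam0) >= (lam0 - lo) else -1.0
    direction = float(np.sign(direction)) or 1.0

    def solve_nat(lam: float, guess: np.ndarray) -> Equilibrium:
        return _solve_at(lam, param, p_base, guess, absent, presence_tol=presence_tol)

    def as_x(eq: Equilibrium) -> np.ndarray:
        return np.append(eq.state[present], getattr(eq.params, param))

    points = [eq0]
    bifs: list[BifurcationPoint] = []
    termination = "range_end"

    # second point by a small natural-parameter step
    ds = ds0
    eq_prev = eq0
    try:
        lam1 = np.clip(lam0 + direction * ds, lo, hi)
        eq1 = solve_nat(lam1, eq_prev.state)
    except EquilibriumError:
        # extremely steep branch at the start: shrink
        lam1 = np.clip(lam0 + direction * ds * 0.01, lo, hi)
        eq1 = solve_nat(lam1, eq_prev.state)
    points.append(eq1)

    def corrector(x_pred: np.ndarray, tangent: np.ndarray) -> Equilibrium | None:
        """Newton on F(u, lam) = 0 plus the arclength hyperplane constraint."""
        try:
            return _corrector_inner(x_pred, tangent)
        except ParameterError:
            # predictor left the parameter's domain (e.g. a_jr past a_p)
            return None

    def _corrector_inner(x_pred: np.ndarray, tangent: np.ndarray) -> Equilibrium | None:
        x = x_pred.copy()
        n = len(present)
        for _ in range(25):
            pl = _with_param(p_base, param, x[-1])
            y = _embed(x[:n], present)
            F = rhs(y, pl)[present]
            g = float(tangent @ (x - x_pred))
            resid = np.append(F, g)
            if np.max(np.abs(resid)) < 1e-11:
                break
            A = np.empty((n + 1, n + 1))
            for j in range(n + 1):
                h = 1e-7 * (1.0 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                Fp = rhs(_embed(xp[:n], present), _with_param(p_base, param, xp[-1]))[present]
                Fm = rhs(_embed(xm[:n], present), _with_param(p_base, param, xm[-1]))[present]
                A[:n, j] = (Fp - Fm) / (2.0 * h)
            A[n, :] = tangent
            try:
                x = x + np.linalg.solve(A, -resid)
            except np.linalg.LinAlgError:
                return None
        else:
            return None
        if np.any(x[:n] < -1e-12) or not (lo - 0.5 <= x[-1] <= hi + 0.5):
            return None
        try:
            # certify with a fixed-parameter solve (residual, eigenvalues, label)
            return solve_equilibrium(
                _embed(np.maximum(x[:n], 0.0), present),
                _with_param(p_base, param, float(x[-1])), absent,
                presence_tol=presence_tol)
        except EquilibriumError:
            return None

    for _ in range(max_points):
        x_prev, x_cur = as_x(points[-2]), as_x(points[-1])
        secant = x_cur - x_prev
        norm = np.linalg.norm(secant)
        if norm == 0:
            termination = "stalled"
            break
        tangent = secant / norm

        eq_new = None
        while ds >= ds_min:
            x_pred = x_cur + ds * tangent
            eq_new = corrector(x_pred, tangent)
            if eq_new is not None:
                step_len = np.linalg.norm(as_x(eq_new) - x_cur)
                if step_len <= 3.0 * ds:
                    break
                eq_new = None  # jumped too far; distrust
            ds *= 0.5
        if eq_new is None:
            # if the step collapsed right next to a range bound (a domain
            # edge such as a_jr = a_p), finish the branch exactly there
            lam_last = x_cur[-1]
            d_last = x_cur[-1] - x_prev[-1]
            bound = hi if d_last > 0 else lo
            if abs(lam_last - bound) <= 2.0 * ds_max and abs(lam_last - bound) > 0:
                pinned = _pin_to_bound(points[-1], bound, param, p_base, absent,
                                       presence_tol)
                if abs(getattr(pinned.params, param) - bound) < 1e-12:
                    points.append(pinned)
                    termination = "range_end"
                    break
            termination = "step_collapse"
            break
        ds = min(ds * 1.3, ds_max)

        lam_prev, lam_new = x_cur[-1], getattr(eq_new.params, param)

        # present component extinction -> truncate
        if np.any(eq_new.state[present] < presence_tol):
            small = [SPECIES[i] for i in present if eq_new.state[i] < presence_tol]
            bifs.append(BifurcationPoint("invasion_boundary", param, lam_new,
                                         eq_new, species="/".join(small)))
            points.append(eq_new)
            termination = "component_extinct"
            break

        # fold: the branch turned in the parameter
        d_prev = lam_prev - x_prev[-1]
        d_new = lam_new - lam_prev
        if d_prev * d_new < 0:
            fold = _refine_fold(points[-2], points[-1], eq_new, param, present,
                                absent, p_base, param_tol, presence_tol)
            if fold is not None:
                bifs.append(fold)

        # invasion boundary of absent species
        for grp in _absent_groups(absent):
            g_prev = invasion_growth(points[-1], grp)
            g_new = invasion_growth(eq_new, grp)
            if g_prev == 0.0 or g_prev * g_new < 0:
                bp = _refine_invasion(points[-1], eq_new, grp, param, p_base,
                                      absent, param_tol, presence_tol)
                if bp is not None:
                    bifs.append(bp)

        points.append(eq_new)

        # reached the end of the range?
        if lam_new >= hi - param_tol and d_new > 0:
            points[-1] = _pin_to_bound(points[-1], hi, param, p_base, absent, presence_tol)
            break
        if lam_new <= lo + param_tol and d_new < 0:
            points[-1] = _pin_to_bound(points[-1], lo, param, p_base, absent, presence_tol)
            break
    else:
        termination = "max_points"

    return Branch(param=param, points=points, bifurcations=bifs, termination=termination)


def _pin_to_bound(eq: Equilibrium, bound: float, param: str, p_base: ModelParameters,
                  absent: frozenset, presence_tol: float) -> Equilibrium:
    try:
        return solve_equilibrium(eq.state, _with_param(p_base, param, bound), absent,
                                 presence_tol=presence_tol)
    except EquilibriumError:
        return eq


def _refine_fold(eq_a: Equilibrium, eq_b: Equilibrium, eq_c: Equilibrium,
                 param: str, present: list, absent: frozenset,
                 p_base: ModelParameters, param_tol: float,
                 presence_tol: float) -> BifurcationPoint | None:
    """Refine a fold bracketed by three consecutive branch points.

    Near the turn the branch is re-parametrized by the state component
    with the largest variation; the parameter is then a smooth function
    lam(s) whose extremum is the fold.
    """
    xs = np.array([eq.state[present] for eq in (eq_a, eq_b, eq_c)])
    lams = np.array([getattr(eq.params, param) for eq in (eq_a, eq_b, eq_c)])
    j_loc = int(np.argmax(np.abs(xs[2] - xs[0])))
    j_full = present[j_loc]
    s_vals = xs[:, j_loc]
    order = np.argsort(s_vals)
    s_lo, s_hi = s_vals[order[0]], s_vals[order[-1]]
    if s_hi - s_lo <= 0:
        return None
    others = [i for i in present if i != j_full]
    sign = 1.0 if lams[1] >= max(lams[0], lams[2]) else -1.0

    cache = {"guess": np.append(eq_b.state[others], lams[1])}

    def lam_of_s(s: float) -> float:
        # solve the equilibrium system with component j pinned to s, param free
        x = cache["guess"].copy()
        n = len(others)
        for _ in range(40):
            y = np.zeros(4)
            y[j_full] = s
            y[others] = x[:n]
            pl = _with_param(p_base, param, x[-1])
            F = rhs(y, pl)[present]
            if np.max(np.abs(F)) < 1e-11:
                break
            A = np.empty((len(present), n + 1))
            for k in range(n + 1):
                h = 1e-7 * (1.0 + abs(x[k]))
                xp, xm = x.copy(), x.copy()
                xp[k] += h
                xm[k] -= h
                yp, ym = y.copy(), y.copy()
                if k < n:
                    yp[others[k]] = xp[k]
                    ym[others[k]] = xm[k]
                    Fp = rhs(yp, pl)[present]
                    Fm = rhs(ym, pl)[present]
                else:
                    Fp = rhs(y, _with_param(p_base, param, xp[-1]))[present]
                    Fm = rhs(y, _with_param(p_base, param, xm[-1]))[present]
                A[:, k] = (Fp - Fm) / (2.0 * h)
            try:
                x = x + np.linalg.solve(A, -F)
            except np.linalg.LinAlgError:
                return np.nan
        else:
            return np.nan
        cache["guess"] = x
        return float(x[-1])

    try:
        res = minimize_scalar(lambda s: -sign * lam_of_s(s),
                              bounds=(s_lo, s_hi), method="bounded",
                              options={"xatol": param_tol * 1e-2})
    except Exception:
        return None
    if not np.isfinite(res.fun):
        return None
    s_star = float(res.x)
    try:
        lam_star = lam_of_s(s_star)
    except ParameterError:
        return None
    if not np.isfinite(lam_star):
        return None
    y = np.zeros(4)
    y[j_full] = s_star
    y[others] = cache["guess"][:len(others)]
    pl = _with_param(p_base, param, lam_star)
    res_norm = float(np.max(np.abs(rhs(y, pl))))
    ev = _sorted_eigenvalues(jacobian(y, pl))
    try:
        label = classify_equilibrium(y, presence_tol)
    except InconsistentStageError:
        label = "?"
    eq_fold = Equilibrium(state=y, params=pl, absent=absent, residual_norm=res_norm,
                          eigenvalues=ev, stable=False, label=label)
    return BifurcationPoint("fold", param, lam_star, eq_fold)


def _refine_invasion(eq_a: Equilibrium, eq_b: Equilibrium, species: str,
                     param: str, p_base: ModelParameters, absent: frozenset,
                     param_tol: float, presence_tol: float) -> BifurcationPoint | None:
    lam_a = getattr(eq_a.params, param)
    lam_b = getattr(eq_b.params, param)
    guess = {"y": eq_a.state.copy()}

    def g(lam: float) -> float:
        eq = solve_equilibrium(guess["y"], _with_param(p_base, param, lam), absent,
                               presence_tol=presence_tol)
        guess["y"] = eq.state.copy()
        return invasion_growth(eq, species)

    try:
        lam_star = brentq(g, lam_a, lam_b, xtol=param_tol)
        eq_star = solve_equilibrium(guess["y"], _with_param(p_base, param, lam_star),
                                    absent, presence_tol=presence_tol)
    except (ValueError, EquilibriumError):
        return None
    return BifurcationPoint("invasion_boundary", param, float(lam_star),
                            eq_star, species=species)


# ---------------------------------------------------------------------------
# Two-parameter region maps


def _canonical_starts(p: ModelParameters, rng: np.ndarray | None = None,
                      n_random: int = 2, seed: int = 0) -> list:
    gen = np.random.default_rng(seed)
    starts = [
        np.array([p.R_max, 0.0, 0.0, 0.0]),
        np.array([0.5 * p.R_max, 1.0, 0.0, 0.0]),
        np.array([0.5 * p.R_max, 0.0, 0.5, 0.5]),
        np.array([0.5 * p.R_max, 0.5, 0.3, 0.3]),
    ]
    for _ in range(n_random):
        starts.append(np.array([
            gen.uniform(0.05 * p.R_max, p.R_max),
            gen.uniform(0.0, 2.0),
            gen.uniform(0.0, 1.0),
            gen.uniform(0.0, 1.0),
        ]))
    return starts


def two_parameter_map(p: ModelParameters, x_param: str, y_param: str,
                      x_grid: Sequence[float], y_grid: Sequence[float],
                      *, seed: int = 0, n_random: int = 2,
                      gradient_signs: bool = True,
                      t_max: float = 30000.0) -> pd.DataFrame:
    """Stable equilibrium classes (and selection-gradient signs) on a grid.

    For every grid cell the attractor is sought from four canonical
    starts (resource-only, CR-like, PR-like, PCR-like) plus ``n_random``
    seeded random states; the set of stable classes found is reported,
    together with the sign of the selection gradient on each stable
    predator-positive state.  Cells where any start is undecided are
    flagged rather than guessed.
    """
    from .dynamics import find_attractor  # local import: avoids a module cycle
    from .adaptive import selection_gradient

    rows = []
    for ix, xv in enumerate(x_grid):
        for iy, yv in enumerate(y_grid):
            p_cell = _with_param(_with_param(p, x_param, xv), y_param, yv)
            classes: dict[str, Equilibrium] = {}
            undecided = False
            for s0 in _canonical_starts(
                    p_cell, n_random=n_random, seed=seed + 977 * ix + 31 * iy):
                rep = find_attractor(s0, p_cell, t_max=t_max)
                if rep.status == "equilibrium" and rep.equilibrium is not None:
                    # only fully stable states count: an equilibrium an
                    # absent species can invade is not a community attractor
                    if rep.equilibrium.stable:
                        classes.setdefault(rep.equilibrium.label, rep.equilibrium)
                elif rep.status != "equilibrium":
                    undecided = True
            grad_sign = ""
            if gradient_signs:
                signs = []
                for label in sorted(classes):
                    eq = classes[label]
                    if eq.has_predators() and eq.stable:
                        try:
                            g = selection_gradient(eq)
                            signs.append(f"{label}:{'+' if g > 0 else '-' if g < 0 else '0'}")
                        except Exception:
                            signs.append(f"{label}:?")
                grad_sign = ";".join(signs)
            rows.append({
                x_param: xv, y_param: yv,
                "classes": "+".join(sorted(classes)),
                "gradient_sign": grad_sign,
                "undecided": undecided,
            })
    return pd.DataFrame(rows)
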