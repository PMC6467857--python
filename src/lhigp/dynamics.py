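"""Time integration of the LHIGP ODEs and attractor identification.

The model is analysed through its asymptotic states; trajectories matter
mainly as the route there and as the mechanism of attractor switches
(the ecological half of evolutionary suicide).  ``simulate`` integrates
the four ODEs with a stiff-capable solver and clamps any component that
falls below an extinction threshold to exactly zero — transcritical
exits produce exponentially small but positive densities that must not
fake persistence.  ``find_attractor`` integrates until the state stops
moving, polishes the endpoint with Newton and classifies it, or flags a
non-convergent oscillation as a cycle (cycles are detected, never
continued: where they occur their amplitude is negligible).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .continuation import Equilibrium, EquilibriumError, jacobian, solve_equilibrium
from .model import SPECIES, CommunityState, ModelParameters, rhs

__all__ = ["Trajectory", "AttractorReport", "simulate", "find_attractor"]


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_state: np.ndarray | None = None,
                 last_time: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclasses.dataclass
class Trajectory:
    """An integrated trajectory with its extinction-event log."""

    t: np.ndarray
    states: np.ndarray  # shape (n, 4)
    events: list  # dicts: {"time", "species"}

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_to_jsonl(self) -> str:
        import json
        return "\n".join(json.dumps(e) for e in self.events)


@dataclasses.dataclass
class AttractorReport:
    """Outcome of an attractor search: equilibrium, cycle, or undecided."""

    status: str  # "equilibrium" | "cycle" | "undecided"
    equilibrium: Equilibrium | None
    final_state: np.ndarray
    t_used: float
    envelope: dict | None = None  # per-species (min, max) over the last window

    @property
    def label(self) -> str | None:
        return self.equilibrium.label if self.equilibrium is not None else None


def _as_array(state) -> np.ndarray:
    if isinstance(state, CommunityState):
        return state.as_array()
    return np.asarray(state, dtype=float)


def simulate(state0, p: ModelParameters, t_end: float, *,
             t_start: float = 0.0, extinction_threshold: float = 1e-9,
             rtol: float = 1e-8, atol: float = 1e-10, method: str = "LSODA",
             max_events: int = 200, dense_n: int | None = None) -> Trajectory:
    """Integrate the four ODEs from ``state0`` to ``t_end``.

    Any component crossing ``extinction_threshold`` from above is set to
    exactly zero and logged; integration then restarts from the clamped
    state.  A component clamped at zero can still regrow if its
    derivative is positive (a juvenile stage replenished by adult
    reproduction, or the renewing resource); only components whose
    dynamics keep them at zero stay extinct.
    """
    y = np.maximum(_as_array(state0), 0.0)
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    thr = extinction_threshold

    def f(t, yv):
        return rhs(yv, p)

    def make_event(i):
        def ev(t, yv):
            return yv[i] - thr
        ev.terminal = True
        ev.direction = -1.0
        return ev

    events = [make_event(i) for i in range(4)]
    t_now = t_start
    ts = [t_now]
    ys = [y.copy()]
    log: list[dict] = []
    t_eval = None
    if dense_n:
        t_eval_all = np.linspace(t_start, t_end, dense_n)

    for _ in range(max_events):
        if dense_n:
            t_eval = t_eval_all[(t_eval_all > t_now) & (t_eval_all <= t_end)]
            if t_eval.size == 0:
                t_eval = None
        sol = solve_ivp(f, (t_now, t_end), y, method=method, rtol=rtol, atol=atol,
                        events=events, t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   last_state=ys[-1], last_time=ts[-1])
        if sol.t.size > 1 or sol.t[-1] != t_now:
            ts.extend(sol.t[1:] if sol.t[0] == t_now else sol.t)
            ys.extend(list((sol.y.T)[1:] if sol.t[0] == t_now else sol.y.T))
        if sol.status == 1:  # an extinction event fired
            t_now = float(sol.t[-1] if sol.t.size else t_now)
            y = sol.y[:, -1].copy() if sol.t.size else y.copy()
            for i, t_ev in enumerate(sol.t_events):
                if t_ev.size:
                    t_now = float(t_ev[-1])
                    y = sol.y_events[i][-1].copy()
                    y[i] = 0.0
                    log.append({"time": t_now, "species": SPECIES[i]})
            y = np.maximum(y, 0.0)
            ts.append(t_now)
            ys.append(y.copy())
            if t_now >= t_end:
                break
        else:
            break
    return Trajectory(t=np.asarray(ts), states=np.asarray(ys), events=log)


def find_attractor(state0, p: ModelParameters, *, t_window: float = 200.0,
                   t_max: float = 50000.0, conv_tol: float = 1e-9,
                   presence_tol: float = 1e-8, cycle_tol: float = 1e-6,
                   extinction_threshold: float = 1e-9,
                   rtol: float = 1e-8, atol: float = 1e-10) -> AttractorReport:
    """Integrate to the attractor and classify it.

    The state is advanced window by window; once the relative change
    over a window is small the endpoint is polished by Newton on the
    subsystem of species still present, accepted only if stable and
    close to the simulated state.  If the state keeps moving until
    ``t_max``, a bounded oscillation is reported as a cycle with its
    min/max envelope, anything else as undecided — never a silent guess.
    """
    y = np.maximum(_as_array(state0), 0.0)
    t_used = 0.0
    envelope = None
    while t_used < t_max:
        traj = simulate(y, p, t_window, extinction_threshold=extinction_threshold,
                        rtol=rtol, atol=atol, dense_n=64)
        y_new = np.maximum(traj.final_state, 0.0)
        t_used += t_window
        scale = 1.0 + np.max(np.abs(y_new))
        delta = np.max(np.abs(y_new - y)) / scale
        lo = traj.states.min(axis=0)
        hi = traj.states.max(axis=0)
        envelope = {s: (float(lo[i]), float(hi[i])) for i, s in enumerate(SPECIES)}
        y = y_new
        speed = np.max(np.abs(rhs(y, p))) / scale
        if delta < 1e-4 or speed < 1e-6:
            absent = {s for i, s in enumerate(SPECIES[1:], start=1)
                      if y[i] <= presence_tol}
            if ("Pj" in absent) != ("Pa" in absent):
                absent |= {"Pj", "Pa"}
            try:
                eq = solve_equilibrium(y, p, absent, presence_tol=presence_tol)
            except EquilibriumError:
                continue
            close = np.max(np.abs(eq.state - y)) / scale
            # the trajectory cannot leave the subspace of species it still
            # carries, so acceptance uses stability within that subspace;
            # eq.stable (full Jacobian, invasion directions included) may
            # still be False for an equilibrium an absent species could invade
            present = [i for i, s in enumerate(SPECIES) if s not in absent]
            J_red = jacobian(eq.state, p)[np.ix_(present, present)]
            subspace_stable = bool(np.max(np.linalg.eigvals(J_red).real) < 0.0)
            if subspace_stable and close < 0.2:
                return AttractorReport("equilibrium", eq, y, t_used, envelope)
            if not subspace_stable and close < conv_tol:
                # parked exactly on an unstable equilibrium: undecided
                return AttractorReport("undecided", eq, y, t_used, envelope)
    # no convergence within t_max: oscillation or slow transient?
    spread = max(hi[i] - lo[i] for i in range(4)) / (1.0 + np.max(np.abs(y)))
    if spread > cycle_tol:
        return AttractorReport("cycle", None, y, t_used, envelope)
    return AttractorReport("undecided", None, y, t_used, envelope)
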