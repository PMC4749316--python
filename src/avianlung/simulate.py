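"""Event-driven integration of the switched airflow model.

The model is piecewise linear: within each phase-plane region the
dynamics are a forced linear 2-D ODE, and the resistances ``R1``/``R2``
switch branch exactly where the flows ``q1``/``q2`` cross zero.  The
integrator advances one regime "leg" at a time with
:func:`scipy.integrate.solve_ivp`, using terminal root-located events on
the governing flow to place each switch, and cycles legs until the
breath-to-breath net tracheal volume vanishes (periodic steady state).

Zero crossings of the tracheal flow ``q_T`` are located as non-terminal
events: they mark the inspiration/expiration boundary but do not switch
any resistance (they always occur inside the shared region 2/3 block).

The regime cycle for one breath, starting from region 1, is::

    1 --(q1 v 0)--> 2&3 --(q2 ^ 0)--> 4 --(q2 v 0)--> 2&3 --(q1 ^ 0)--> 1

A third, auxiliary state component accumulates the tracheal volume
``integral of q_T dt`` so the steady-state criterion is evaluated at
solver accuracy without dense sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    REGION_1,
    REGION_23,
    REGION_4,
    FlowRegime,
    ModelParameters,
    SystemState,
    airsac_volumes,
    classify_region,
    compute_flows,
    external_pressure_rate,
    regime_for_label,
    regime_resistances,
    system_matrix,
)

__all__ = [
    "TimeSeries",
    "SteadyStateReport",
    "EventNotFoundError",
    "SlidingModeError",
    "simulate_breath",
    "simulate_to_steady_state",
    "oracle_fixed_step_integrate",
    "detect_phase_boundaries",
]

#: default output sampling step (s)
DEFAULT_DT = 1e-4
#: default steady-state tolerance on the net tracheal volume per breath (L)
DEFAULT_TOL = 1e-5
#: default relative/absolute solver tolerances
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
#: a leg shorter than this that bounces straight back to the previous
#: regime is treated as chatter on the switching surface
_CHATTER_DT = 1e-9


class EventNotFoundError(RuntimeError):
    """No switching event within the search horizon (degenerate dynamics)."""


class SlidingModeError(RuntimeError):
    """Immediate re-crossing after a resistance switch (surface chatter)."""


@dataclass
class SteadyStateReport:
    """Convergence summary of a steady-state simulation."""

    breaths: int
    net_tracheal_volume: float  # L, over the last measured breath
    converged: bool
    tol: float


@dataclass
class TimeSeries:
    """Sampled trajectory of one or more breaths plus located events.

    ``data`` columns: t, x1, x2, P1, P2, qT_Lps, q1_Lps, q2_Lps, qP_Lps,
    PJ, V1_mL, V2_mL, region, phase.  ``events`` columns: t, kind with
    kind in {q1_zero, q2_zero, qT_zero, breath_end}.
    """

    data: pd.DataFrame
    events: pd.DataFrame
    params: ModelParameters
    dt: float
    #: absolute simulation time of the sample at t = 0.  The final breath is
    #: re-timed so t = 0 is the start of inspiration; the forcing is a
    #: function of absolute time, so re-simulating from a sampled state
    #: requires ``t + t_offset``.
    t_offset: float = 0.0

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    def events_to_csv(self, path) -> None:
        self.events.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# leg integration machinery

# terminal transitions per regime: (event name, flow index, direction, next regime)
_TRANSITIONS = {
    "1": [("q1_zero", 1, -1.0, REGION_23)],
    "23": [("q1_zero", 1, +1.0, REGION_1), ("q2_zero", 2, +1.0, REGION_4)],
    "4": [("q2_zero", 2, -1.0, REGION_23)],
}


@dataclass
class _Leg:
    sol: object
    t0: float
    t1: float
    regime: FlowRegime
    switch_kind: str | None  # None if the leg ended at the time horizon
    next_regime: FlowRegime | None
    qT_crossings: list[tuple[float, int]] = field(default_factory=list)  # (t, +1/-1)


def _flow_coeffs(regime: FlowRegime, p: ModelParameters):
    """Coefficient rows c such that q = c . (x1, x2) for (q_T, q_1, q_2)."""
    R1, R2 = regime_resistances(regime, p)
    Rbar = R1 * R2 + R2 * p.R_T + p.R_T * R1
    return np.array(
        [
            [-R2 / Rbar, -R1 / Rbar],  # q_T
            [(-R2 - p.R_T) / Rbar, p.R_T / Rbar],  # q_1
            [-p.R_T / Rbar, (R1 + p.R_T) / Rbar],  # q_2
        ]
    )


def _advance_leg(t0, y0, regime, p, t_end, rtol, atol) -> _Leg:
    """Integrate one fixed-regime leg until a switching event or ``t_end``."""
    A = system_matrix(regime, p)
    C = _flow_coeffs(regime, p)
    qT_row = C[0]

    def rhs(t, y):
        rate = external_pressure_rate(t, p)
        return np.array(
            [
                A[0, 0] * y[0] + A[0, 1] * y[1] + rate,
                A[1, 0] * y[0] + A[1, 1] * y[1] + rate,
                qT_row[0] * y[0] + qT_row[1] * y[1],
            ]
        )

    events = []
    transitions = _TRANSITIONS[regime.label]
    for _name, idx, direction, _next in transitions:
        row = C[idx]

        def ev(t, y, row=row):
            return row[0] * y[0] + row[1] * y[1]

        ev.terminal = True
        ev.direction = direction
        events.append(ev)

    def qT_up(t, y):
        return qT_row[0] * y[0] + qT_row[1] * y[1]

    qT_up.terminal = False
    qT_up.direction = +1.0

    def qT_down(t, y):
        return qT_row[0] * y[0] + qT_row[1] * y[1]

    qT_down.terminal = False
    qT_down.direction = -1.0

    sol = solve_ivp(
        rhs,
        (t0, t_end),
        y0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events + [qT_up, qT_down],
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE solver failed: {sol.message}")

    n_term = len(transitions)
    switch_kind = next_regime = None
    t1 = None
    for (name, idx, _direction, nxt), te in zip(transitions, sol.t_events[:n_term]):
        valid = []
        for tev in te:
            tev = float(tev)
            if tev - t0 <= 1e-12:
                # an "event" at exactly the leg start with a stationary
                # event function is the degenerate case of a state sitting
                # on the surface (the unforced equilibrium, where every
                # flow is identically zero), not a crossing
                ye = sol.sol(tev)
                dy = rhs(tev, ye)
                if abs(C[idx, 0] * dy[0] + C[idx, 1] * dy[1]) < 1e-13:
                    continue
            valid.append(tev)
        if valid and (t1 is None or valid[0] < t1):
            switch_kind, next_regime, t1 = name, nxt, valid[0]
    if t1 is None:
        t1 = min(t_end, float(sol.t[-1]))

    crossings = [(float(t), +1) for t in sol.t_events[n_term] if t < t1] + [
        (float(t), -1) for t in sol.t_events[n_term + 1] if t < t1
    ]
    crossings.sort()
    return _Leg(sol, t0, t1, regime, switch_kind, next_regime, crossings)


def _run_legs(t0, x0, regime, p, *, stop_time=None, stop_on_cycle=False, horizon=None,
              rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
    """Drive the leg integrator until ``stop_time`` or a full regime cycle.

    Returns ``(legs, events, t_end, x_end, regime_end)`` where events is
    a list of ``(t, kind)`` including the located q_T crossings.
    """
    if horizon is None:
        horizon = 2.0 * p.T
    start_regime = regime
    t = float(t0)
    y = np.array([x0[0], x0[1], 0.0])
    legs: list[_Leg] = []
    events: list[tuple[float, str]] = []
    prev_regime: FlowRegime | None = None
    switches = 0
    deadline = t + horizon

    while True:
        t_end = deadline if stop_time is None else min(stop_time, t + horizon)
        leg = _advance_leg(t, y, regime, p, t_end, rtol, atol)
        legs.append(leg)
        for te, direction in leg.qT_crossings:
            events.append((te, "qT_zero"))
        if leg.switch_kind is None:
            if stop_time is not None and leg.t1 >= stop_time:
                y = leg.sol.sol(stop_time)
                return legs, events, stop_time, y, regime
            raise EventNotFoundError(
                f"no resistance-switch event within {horizon:g} s from t={t:g}; "
                "the forcing may be too weak to complete a breath (e.g. P_amp = 0)"
            )
        if leg.t1 - t < _CHATTER_DT and leg.next_regime == prev_regime:
            raise SlidingModeError(
                f"immediate re-crossing of the {leg.switch_kind} surface at t={leg.t1:g}; "
                "trajectory is sliding on a switching surface"
            )
        events.append((leg.t1, leg.switch_kind))
        y = leg.sol.sol(leg.t1)
        prev_regime = regime
        regime = leg.next_regime
        t = leg.t1
        switches += 1
        deadline = t + horizon
        if stop_on_cycle and switches >= 4 and regime == start_regime:
            return legs, events, t, y, regime
        if stop_time is not None and t >= stop_time:
            return legs, events, t, y, regime


def _sample_legs(legs, t_start, t_stop, p, dt) -> pd.DataFrame:
    """Sample a sequence of legs on a regular grid plus event times.

    Each leg contributes samples on ``[leg start, leg end]``; at a
    switch time the sample of the *incoming* regime is kept so that the
    recorded regime changes exactly at the event.  q_T zero-crossing
    times are inserted as extra samples so phase integrals have exact
    endpoints.
    """
    frames = []
    for i, leg in enumerate(legs):
        lo = max(leg.t0, t_start)
        hi = min(leg.t1, t_stop)
        if hi <= lo:
            continue
        ts = np.arange(lo, hi, dt)
        extra = [te for te, _d in leg.qT_crossings if lo < te < hi]
        ts = np.unique(np.concatenate([ts, [lo, hi], extra]))
        x = leg.sol.sol(ts)
        flows = compute_flows(x[0], x[1], leg.regime, p)
        V1, V2 = airsac_volumes(x[0], x[1], ts, p)
        frames.append(
            pd.DataFrame(
                {
                    "t": ts,
                    "x1": x[0],
                    "x2": x[1],
                    "P1": x[0] + p.P_atm,
                    "P2": x[1] + p.P_atm,
                    "qT_Lps": flows.q_T,
                    "q1_Lps": flows.q_1,
                    "q2_Lps": flows.q_2,
                    "qP_Lps": flows.q_P,
                    "PJ": flows.P_J,
                    "V1_mL": V1,
                    "V2_mL": V2,
                    "region": leg.regime.label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    # at duplicated switch times keep the later (incoming-regime) sample
    data = data.drop_duplicates(subset="t", keep="last").reset_index(drop=True)
    return data


def _phase_labels(ts, qT, crossings):
    """Vectorized phase labelling: segment sign from the mean q_T within it."""
    bounds = np.array(sorted(t for t, kind in crossings if kind == "qT_zero"))
    if bounds.size == 0:
        return np.where(np.asarray(qT) >= 0, "INSP", "EXP")
    seg = np.searchsorted(bounds, ts, side="right")
    labels = np.empty(len(ts), dtype=object)
    for s in np.unique(seg):
        mask = seg == s
        labels[mask] = "INSP" if float(np.median(np.asarray(qT)[mask])) >= 0 else "EXP"
    return labels


def simulate_breath(
    start: SystemState,
    start_regime: FlowRegime,
    p: ModelParameters,
    dt: float = DEFAULT_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
):
    """Integrate exactly one breath (a full four-switch regime cycle).

    Returns ``(series, end_state, end_regime)``.  Raises
    :class:`EventNotFoundError` if no switching event occurs within a
    horizon of two forcing periods, and :class:`SlidingModeError` on
    chatter at a switching surface.
    """
    legs, events, t_end, y_end, regime_end = _run_legs(
        start.t, (start.x1, start.x2), start_regime, p, stop_on_cycle=True,
        rtol=rtol, atol=atol,
    )
    events.append((t_end, "breath_end"))
    data = _sample_legs(legs, start.t, t_end, p, dt)
    data["phase"] = _phase_labels(data["t"].to_numpy(), data["qT_Lps"].to_numpy(), events)
    series = TimeSeries(
        data=data,
        events=pd.DataFrame(sorted(events), columns=["t", "kind"]),
        params=p,
        dt=dt,
    )
    return series, SystemState(t_end, float(y_end[0]), float(y_end[1])), regime_end


def simulate_to_steady_state(
    p: ModelParameters,
    dt: float = DEFAULT_DT,
    tol: float = DEFAULT_TOL,
    max_breaths: int = 200,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[TimeSeries, SteadyStateReport]:
    """Cycle breaths from equilibrium until periodic steady state.

    The simulation starts at the equilibrium state ``x = (0, 0)`` at the
    onset of inspiratory effort (the forcing maximum) in region 1.
    Breath boundaries are the located upward zero crossings of the
    tracheal flow (the start of inspiration), which recur once per
    forcing period whatever the regime cycle looks like; the run stops
    once the net tracheal volume between successive boundaries drops
    below ``tol`` (litres), or unconverged after ``max_breaths``.  The
    returned series covers one final breath of length ``T``, re-timed so
    that t = 0 is the start of inspiration.
    """
    t = p.T / 2.0
    y = np.array([0.0, 0.0, 0.0])
    regime = REGION_1
    prev_regime: FlowRegime | None = None
    boundary: tuple[float, float] | None = None  # (t, vT) at last inspiration onset
    breaths = 0
    net = np.inf
    converged = False
    t_up = None  # inspiration onset to align the final breath on
    up_state = None
    up_regime = None

    while breaths < max_breaths:
        leg = _advance_leg(t, y, regime, p, t + 2.0 * p.T, rtol, atol)
        for tc, direction in leg.qT_crossings:
            if direction <= 0:
                continue
            vT_c = float(leg.sol.sol(tc)[2])
            if boundary is not None:
                breaths += 1
                net = vT_c - boundary[1]
                if abs(net) < tol:
                    converged = True
            boundary = (tc, vT_c)
            t_up, up_state, up_regime = tc, leg.sol.sol(tc)[:2], leg.regime
            if converged or breaths >= max_breaths:
                break
        if converged or breaths >= max_breaths:
            break
        if leg.switch_kind is None:
            raise EventNotFoundError(
                "no resistance-switch event within two periods; the forcing may be "
                "too weak to complete a breath (e.g. P_amp = 0)"
            )
        if leg.t1 - t < _CHATTER_DT and leg.next_regime == prev_regime:
            raise SlidingModeError(
                f"immediate re-crossing of the {leg.switch_kind} surface at t={leg.t1:g}"
            )
        y = leg.sol.sol(leg.t1)
        prev_regime = regime
        regime = leg.next_regime
        t = leg.t1

    report = SteadyStateReport(
        breaths=breaths, net_tracheal_volume=float(net), converged=converged, tol=tol
    )
    if t_up is None:  # pragma: no cover - requires a breath that never inspires
        raise EventNotFoundError("no inspiration onset (upward q_T crossing) found")
    x_up = up_state
    up_leg_regime = up_regime

    # one full aligned breath of length exactly T
    legs, events, t_end, y_end, _ = _run_legs(
        t_up, x_up, up_leg_regime, p, stop_time=t_up + p.T, rtol=rtol, atol=atol
    )
    data = _sample_legs(legs, t_up, t_up + p.T, p, dt)
    data["phase"] = _phase_labels(data["t"].to_numpy(), data["qT_Lps"].to_numpy(), events)
    events = [(te - t_up, kind) for te, kind in events if t_up <= te <= t_up + p.T]
    events.append((p.T, "breath_end"))
    data["t"] = data["t"] - t_up
    series = TimeSeries(
        data=data,
        events=pd.DataFrame(sorted(events), columns=["t", "kind"]),
        params=p,
        dt=dt,
        t_offset=t_up,
    )
    return series, report


def oracle_fixed_step_integrate(
    p: ModelParameters,
    dt: float,
    x0: tuple[float, float] = (0.0, 0.0),
    t0: float = 0.0,
    duration: float | None = None,
):
    """Naive fixed-step RK4 reference integrator (verification only).

    At every step the regime is re-derived from the current flow signs
    via :func:`avianlung.model.classify_region`; no event location is
    performed, so switching times are only accurate to one step.
    Returns ``(t, x, labels, switch_times)`` with ``x`` of shape (2, n).
    """
    if dt > 1e-4:
        raise ValueError("oracle step must be <= 1e-4 s")
    if duration is None:
        duration = p.T
    n = int(round(duration / dt))
    ts = t0 + dt * np.arange(n + 1)
    xs = np.empty((2, n + 1))
    labels = np.empty(n + 1, dtype=object)
    xs[:, 0] = x0
    switch_times: list[float] = []
    A_cache = {lab: system_matrix(regime_for_label(lab), p) for lab in ("1", "23", "4")}
    prev_lab = None
    x = np.array(x0, dtype=float)
    for i in range(n + 1):
        lab, _signs = classify_region(x[0], x[1], p)
        lab = "23" if lab in ("2", "3") else lab
        labels[i] = lab
        if prev_lab is not None and lab != prev_lab:
            switch_times.append(ts[i])
        prev_lab = lab
        if i == n:
            break
        A = A_cache[lab]
        t = ts[i]

        def f(ti, xi):
            return A @ xi + external_pressure_rate(ti, p)

        k1 = f(t, x)
        k2 = f(t + dt / 2, x + dt / 2 * k1)
        k3 = f(t + dt / 2, x + dt / 2 * k2)
        k4 = f(t + dt, x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        xs[:, i + 1] = x
    xs[:, 0] = x0
    return ts, xs, labels, switch_times


def detect_phase_boundaries(series: TimeSeries) -> list[tuple[float, float, str]]:
    """Partition a series into (t_start, t_end, 'INSP'|'EXP') intervals.

    Boundaries are the event-located q_T zero crossings.  A series with
    identically zero tracheal flow yields an empty partition.  More than
    two crossings per breath (a multi-phase breath) is reported with a
    warning, not an error.
    """
    import warnings as _warnings

    data = series.data
    qT = data["qT_Lps"].to_numpy()
    ts = data["t"].to_numpy()
    if np.max(np.abs(qT)) < 1e-12:
        return []
    bounds = sorted(series.events.loc[series.events["kind"] == "qT_zero", "t"].tolist())
    n_breaths = max(1, int(round((ts[-1] - ts[0]) / series.params.T)))
    if len(bounds) > 2 * n_breaths:
        _warnings.warn(
            f"{len(bounds)} q_T crossings over {n_breaths} breath(s): multi-phase breath",
            stacklevel=2,
        )
    edges = [ts[0]] + [b for b in bounds if ts[0] < b < ts[-1]] + [ts[-1]]
    intervals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo <= 0:
            continue
        mask = (ts >= lo) & (ts <= hi)
        phase = "INSP" if float(np.median(qT[mask])) >= 0 else "EXP"
        intervals.append((float(lo), float(hi), phase))
    return intervals
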