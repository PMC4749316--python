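"""Breath-cycle summary metrics from a steady-state trajectory.

All volumes are obtained by trapezoidal integration of the sampled
flows, with the inspiration/expiration boundaries taken at the
event-located zero crossings of the tracheal flow (the crossing times
are inserted into the sample grid by the integrator, so each phase
integral has exact endpoints).

The simulation resolves a single (left or right) side of the
respiratory system; by convention the reported volumes are doubled to
whole-animal values unless ``whole_animal=False``.  Efficiency, the
valving efficacies and the I:E ratios are ratios of volumes, so the
doubling cancels and they are identical under either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .simulate import TimeSeries, detect_phase_boundaries

__all__ = [
    "BreathMetrics",
    "integrate_flow",
    "tidal_volume",
    "efficiency",
    "inspiratory_valving_efficacy",
    "expiratory_valving_efficacy",
    "expiratory_valving_efficacy_alt",
    "ie_parabronchial_flow_ratio",
    "ie_time_ratio",
    "ventilation_volumes",
    "compute_metrics",
]

_FLOW_COLUMNS = {
    "q_T": "qT_Lps",
    "q_1": "q1_Lps",
    "q_2": "q2_Lps",
    "q_P": "qP_Lps",
}


@dataclass(frozen=True)
class BreathMetrics:
    """Summary quantities of one steady-state breath.

    Volumes are in mL (whole animal unless computed single-side),
    durations in s, the efficacies and efficiency are fractions in
    [0, 1].
    """

    tidal_volume: float
    parabronchial_volume_per_breath: float
    efficiency: float
    insp_valving_efficacy: float
    exp_valving_efficacy: float
    exp_valving_efficacy_alt: float
    ie_flow_ratio: float
    T_i: float
    T_e: float
    ie_time_ratio: float
    ventilation_caudal: float
    ventilation_cranial: float
    caudal_ventilation_fraction: float
    peak_V1: float
    peak_V2: float
    whole_animal: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _phase_intervals(series: TimeSeries, phase: str) -> list[tuple[float, float]]:
    return [(lo, hi) for lo, hi, ph in detect_phase_boundaries(series) if ph == phase]


def _trapz_over(series: TimeSeries, values: np.ndarray, interval: str) -> float:
    """Trapezoidal integral of per-sample ``values`` over a named interval."""
    ts = series.data["t"].to_numpy()
    if interval == "breath":
        return float(np.trapezoid(values, ts))
    total = 0.0
    intervals = _phase_intervals(series, interval)
    if not intervals:
        raise ValueError(f"series contains no {interval} interval")
    for lo, hi in intervals:
        mask = (ts >= lo) & (ts <= hi)
        total += float(np.trapezoid(values[mask], ts[mask]))
    return total


def integrate_flow(series: TimeSeries, flow: str, interval: str = "breath") -> float:
    """Volume (L, single side) carried by a named flow over an interval.

    ``flow`` is one of ``q_T``, ``q_1``, ``q_2``, ``q_P``; ``interval``
    is ``"breath"`` (the full series), ``"INSP"`` or ``"EXP"``.
    """
    try:
        col = _FLOW_COLUMNS[flow]
    except KeyError:
        raise ValueError(f"unknown flow {flow!r}; expected one of {sorted(_FLOW_COLUMNS)}") from None
    return _trapz_over(series, series.data[col].to_numpy(), interval)


def tidal_volume(series: TimeSeries, whole_animal: bool = True) -> float:
    """Inspired tracheal volume per breath in mL."""
    v = integrate_flow(series, "q_T", "INSP") * 1e3
    return 2.0 * v if whole_animal else v


def efficiency(series: TimeSeries) -> float:
    """Fraction of the tidal volume that transits the parabronchi."""
    vt = integrate_flow(series, "q_T", "INSP")
    if vt == 0:
        raise ZeroDivisionError("zero tidal volume")
    return integrate_flow(series, "q_P", "breath") / vt


def inspiratory_valving_efficacy(series: TimeSeries) -> float:
    """Fraction of inspired air that reaches the caudal airsacs."""
    denom = integrate_flow(series, "q_T", "INSP")
    if denom == 0:
        raise ZeroDivisionError("zero inspiratory tracheal volume")
    return integrate_flow(series, "q_1", "INSP") / denom


def expiratory_valving_efficacy(series: TimeSeries) -> float:
    """Fraction of expired air originating from the cranial airsacs."""
    denom = -integrate_flow(series, "q_T", "EXP")
    if denom == 0:
        raise ZeroDivisionError("zero expiratory tracheal volume")
    return integrate_flow(series, "q_2", "EXP") / denom


def expiratory_valving_efficacy_alt(series: TimeSeries) -> float:
    """Alternative expiratory efficacy: parabronchial share of caudal outflow.

    The share of the total outflow from the caudal airsacs during
    expiration that passes through the parabronchi; the back-leak term
    ``-q_1`` is clamped at zero sample-wise so the measure stays a
    fraction of a genuine outflow even if ``q_1`` momentarily turns
    positive near a phase boundary.  This definition gives a lower
    estimate than the tracheal-referenced efficacy.
    """
    qP = series.data["qP_Lps"].to_numpy()
    leak = np.clip(-series.data["q1_Lps"].to_numpy(), 0.0, None)
    num = _trapz_over(series, qP, "EXP")
    denom = _trapz_over(series, qP + leak, "EXP")
    if denom == 0:
        raise ZeroDivisionError("zero caudal outflow during expiration")
    return num / denom


def ie_parabronchial_flow_ratio(series: TimeSeries) -> float:
    """Ratio of parabronchial throughput during inspiration vs expiration."""
    v_exp = integrate_flow(series, "q_P", "EXP")
    if v_exp == 0:
        raise ZeroDivisionError("zero expiratory parabronchial volume")
    return integrate_flow(series, "q_P", "INSP") / v_exp


def ie_time_ratio(series: TimeSeries) -> tuple[float, float, float]:
    """Durations ``(T_i, T_e)`` and their ratio from the q_T crossings."""
    T_i = sum(hi - lo for lo, hi in _phase_intervals(series, "INSP"))
    T_e = sum(hi - lo for lo, hi in _phase_intervals(series, "EXP"))
    if T_i == 0 or T_e == 0:
        raise ValueError("series lacks an inspiration or expiration phase")
    return T_i, T_e, T_i / T_e


def ventilation_volumes(series: TimeSeries, whole_animal: bool = True) -> tuple[float, float, float]:
    """Airsac ventilation volumes ``(dV1, dV2, caudal fraction)`` in mL.

    ``dV_i = max(V_i) - min(V_i)`` over the breath; independent of the
    baseline coelomic pressure and the resting volumes, which shift
    ``V_i`` additively.
    """
    scale = 2.0 if whole_animal else 1.0
    V1 = series.data["V1_mL"].to_numpy()
    V2 = series.data["V2_mL"].to_numpy()
    dV1 = scale * float(V1.max() - V1.min())
    dV2 = scale * float(V2.max() - V2.min())
    return dV1, dV2, dV1 / (dV1 + dV2)


def compute_metrics(series: TimeSeries, whole_animal: bool = True) -> BreathMetrics:
    """All breath metrics for a steady-state series."""
    scale = 2.0 if whole_animal else 1.0
    T_i, T_e, ratio_t = ie_time_ratio(series)
    dV1, dV2, frac = ventilation_volumes(series, whole_animal)
    return BreathMetrics(
        tidal_volume=tidal_volume(series, whole_animal),
        parabronchial_volume_per_breath=scale * integrate_flow(series, "q_P", "breath") * 1e3,
        efficiency=efficiency(series),
        insp_valving_efficacy=inspiratory_valving_efficacy(series),
        exp_valving_efficacy=expiratory_valving_efficacy(series),
        exp_valving_efficacy_alt=expiratory_valving_efficacy_alt(series),
        ie_flow_ratio=ie_parabronchial_flow_ratio(series),
        T_i=T_i,
        T_e=T_e,
        ie_time_ratio=ratio_t,
        ventilation_caudal=dV1,
        ventilation_cranial=dV2,
        caudal_ventilation_fraction=frac,
        peak_V1=scale * float(series.data["V1_mL"].max()),
        peak_V2=scale * float(series.data["V2_mL"].max()),
        whole_animal=whole_animal,
    )
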