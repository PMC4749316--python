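"""Parameter sweeps and inverse fits.

Every sweep point re-resolves the full parameter set from the base
configuration (never from the previous point), so linked parameters —
the valving multipliers ``R2_insp = k_insp R1_insp`` and ``R1_exp =
k_exp R2_exp``, the compliance split from ``(C_tot, gamma)`` and the
tracheal lumping — cannot drift along the sweep.  Each point is
simulated to periodic steady state and summarized with the full set of
breath metrics plus the algebraic valving certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import unidirectional_flow_condition
from .metrics import compute_metrics
from .model import ModelParameters, ParameterError, resolve_parameters
from .simulate import simulate_to_steady_state

__all__ = [
    "SweepSpec",
    "run_sweep",
    "resistance_ratio_sweep",
    "fit_gamma_to_ventilation_fraction",
]

_MODES = ("free", "fixed_valving_multipliers", "constant_total_resistance")


@dataclass
class SweepSpec:
    """Specification of a one-parameter sweep.

    ``mode='fixed_valving_multipliers'`` drops any explicit valved-branch
    values so both are re-derived from the multipliers at every point;
    ``mode='constant_total_resistance'`` sweeps the ratio
    ``R1_insp / R2_exp`` at fixed ``R1_insp + R2_exp = total``.
    """

    parameter: str
    values: list[float]
    mode: str = "free"
    overrides: dict[str, float] = field(default_factory=dict)
    total: float = 6.0  # cmH2O/(L/s), used by constant_total_resistance

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ParameterError(f"unknown sweep mode {self.mode!r}; expected one of {_MODES}")


def _point_config(spec: SweepSpec, base: dict[str, float], value: float) -> dict[str, float]:
    cfg = dict(base)
    cfg.update(spec.overrides)
    if spec.mode == "constant_total_resistance":
        r = value  # ratio R1_insp / R2_exp
        cfg["R1_insp"] = spec.total * r / (1.0 + r)
        cfg["R2_exp"] = spec.total / (1.0 + r)
        cfg.pop("R2_insp", None)
        cfg.pop("R1_exp", None)
    else:
        cfg[spec.parameter] = value
        if spec.mode == "fixed_valving_multipliers":
            cfg.pop("R2_insp", None)
            cfg.pop("R1_exp", None)
    return cfg


def _evaluate_point(p: ModelParameters, dt: float, tol: float, max_breaths: int) -> dict:
    cert = unidirectional_flow_condition(p)
    series, report = simulate_to_steady_state(p, dt=dt, tol=tol, max_breaths=max_breaths)
    row = {k: v for k, v in p.to_config().items()}
    row.update(compute_metrics(series).to_dict())
    row["converged"] = report.converged
    row["breaths"] = report.breaths
    row["certificate"] = cert.verdict
    return row


def run_sweep(
    spec: SweepSpec,
    base: dict[str, float],
    dt: float = 1e-3,
    tol: float = 1e-5,
    max_breaths: int = 200,
) -> pd.DataFrame:
    """Simulate and summarize every point of a sweep.

    Points whose parameters fail the unidirectionality certificate are
    still simulated; the certificate verdict is recorded per row.
    """
    rows = []
    for value in spec.values:
        p = resolve_parameters(_point_config(spec, base, value))
        row = {"swept_value": value, **_evaluate_point(p, dt, tol, max_breaths)}
        rows.append(row)
    return pd.DataFrame(rows)


def resistance_ratio_sweep(
    ratios,
    total: float,
    base: dict[str, float],
    dt: float = 1e-3,
    tol: float = 1e-5,
    max_breaths: int = 200,
) -> pd.DataFrame:
    """Sweep ``R1_insp / R2_exp`` at constant total resistance.

    At each ratio ``r``: ``R1_insp = total r / (1 + r)`` and
    ``R2_exp = total / (1 + r)``, with the valved branches re-derived
    from the multipliers so the valving strength stays fixed.
    """
    spec = SweepSpec(
        parameter="R1_insp", values=list(ratios), mode="constant_total_resistance", total=total
    )
    return run_sweep(spec, base, dt=dt, tol=tol, max_breaths=max_breaths)


def fit_gamma_to_ventilation_fraction(
    target_fraction: float,
    base: dict[str, float],
    gamma_range: tuple[float, float] = (0.05, 20.0),
    fraction_tol: float = 1e-3,
    dt: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 60,
) -> float:
    """Invert the model for the compliance ratio giving a ventilation split.

    Finds ``gamma`` such that the simulated caudal share of the total
    airsac ventilation equals ``target_fraction``.  The share is
    monotone increasing in ``gamma``, so a coarse geometric scan
    brackets the root and deterministic bisection refines it until the
    fraction matches to ``fraction_tol``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")

    def caudal_fraction(gamma: float) -> float:
        cfg = dict(base)
        cfg["gamma"] = gamma
        cfg.pop("C1", None)
        cfg.pop("C2", None)
        p = resolve_parameters(cfg)
        series, _report = simulate_to_steady_state(p, dt=dt, tol=tol)
        return compute_metrics(series).caudal_ventilation_fraction

    lo, hi = gamma_range
    grid = np.geomspace(lo, hi, 9)
    f_vals = {}
    bracket = None
    f_prev = None
    for g in grid:
        f = caudal_fraction(g) - target_fraction
        f_vals[g] = f
        if abs(f) < fraction_tol:
            return float(g)
        if f_prev is not None and f_prev * f < 0:
            bracket = (g_prev, g)
            break
        g_prev, f_prev = g, f
    if bracket is None:
        raise ValueError(
            f"no gamma in [{lo}, {hi}] achieves a caudal ventilation fraction of "
            f"{target_fraction}"
        )
    a, b = bracket
    fa = f_vals[a]
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        fm = caudal_fraction(mid) - target_fraction
        if abs(fm) < fraction_tol:
            return float(mid)
        if fa * fm < 0:
            b = mid
        else:
            a, fa = mid, fm
    return float(0.5 * (a + b))
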