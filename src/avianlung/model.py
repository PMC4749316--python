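"""Core equations of the avian-lung airflow model.

The avian respiratory system is represented as a two-compartment RC
network: the caudal and cranial airsac groups are lumped elastic
compartments with compliances ``C1`` and ``C2``, connected by rigid
airways with laminar (linear) flow resistances.  The state variables are
the transformed airsac pressures ``x_i = P_i - P_atm`` (cmH2O).  A
sinusoidal coelomic pressure ``P_ext(t)`` drives inflation/deflation of
both airsac groups.

Aerodynamic valving — flow rectification produced by airway geometry —
is modelled by making two of the resistances depend on the local flow
direction: the mesobronchial resistance ``R1`` jumps from ``R1_insp`` to
``R1_exp >= R1_insp`` when the flow ``q1`` into the caudal sacs
reverses, and the ventrobronchial resistance ``R2`` jumps from
``R2_exp`` to ``R2_insp >= R2_exp`` when ``q2`` reverses.  Which branch
of each resistance is active is captured by a :class:`FlowRegime`.

Internally everything is computed in a consistent {cmH2O, L, s} unit
system.  Configuration files use the field-conventional mixed units
(compliances in mL/cmH2O, volumes in mL); conversion happens once at
load time in :func:`resolve_parameters`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Literal

import numpy as np

__all__ = [
    "ParameterError",
    "FlowRegime",
    "REGION_1",
    "REGION_23",
    "REGION_4",
    "SystemState",
    "FlowSet",
    "ModelParameters",
    "resolve_parameters",
    "external_pressure",
    "external_pressure_rate",
    "regime_resistances",
    "compute_flows",
    "system_matrix",
    "state_derivative",
    "airsac_volumes",
    "classify_region",
    "CONFIG_KEYS",
]

Branch = Literal["insp", "exp"]

#: relative tolerance used for consistency checks between linked parameters
_LINK_RTOL = 1e-9


class ParameterError(ValueError):
    """Invalid, inconsistent or incomplete model parameters."""


@dataclass(frozen=True)
class FlowRegime:
    """Active branch of each switched resistance.

    The phase plane is divided by the zero-flow lines of ``q1`` and
    ``q2`` into regions: region 1 (``q1 > 0, q2 < 0``, both resistances
    on their inspiratory branch), regions 2/3 (``q1 < 0, q2 < 0``,
    distinguished only by the sign of the tracheal flow and sharing one
    resistance pair) and region 4 (``q1 < 0, q2 > 0``, both expiratory).
    The combination (insp, exp) never occurs along trajectories of the
    model and is rejected.
    """

    r1_branch: Branch
    r2_branch: Branch

    def __post_init__(self) -> None:
        for b in (self.r1_branch, self.r2_branch):
            if b not in ("insp", "exp"):
                raise ParameterError(f"unknown resistance branch {b!r}")
        if self.r1_branch == "insp" and self.r2_branch == "exp":
            raise ParameterError(
                "regime (R1 inspiratory, R2 expiratory) is unreachable: "
                "q1 > 0 and q2 > 0 cannot hold simultaneously"
            )

    @property
    def label(self) -> str:
        """Region label in the phase plane: '1', '23' or '4'."""
        return {("insp", "insp"): "1", ("exp", "insp"): "23", ("exp", "exp"): "4"}[
            (self.r1_branch, self.r2_branch)
        ]


REGION_1 = FlowRegime("insp", "insp")
REGION_23 = FlowRegime("exp", "insp")
REGION_4 = FlowRegime("exp", "exp")

_REGIMES_BY_LABEL = {"1": REGION_1, "2": REGION_23, "3": REGION_23, "23": REGION_23, "4": REGION_4}


@dataclass(frozen=True)
class SystemState:
    """State of the system: time and transformed pressures (cmH2O)."""

    t: float
    x1: float
    x2: float

    def pressures(self, p: "ModelParameters") -> tuple[float, float]:
        """Absolute airsac pressures ``(P1, P2)`` in cmH2O."""
        return self.x1 + p.P_atm, self.x2 + p.P_atm


@dataclass(frozen=True)
class FlowSet:
    """Volumetric flows (L/s, single side) and junction pressure (cmH2O).

    Sign conventions: ``q_T > 0`` into the bird (inspiration),
    ``q_1 > 0`` into the caudal sacs, ``q_2 > 0`` out of the cranial
    sacs towards the junction, ``q_P > 0`` caudal-to-cranial through the
    parabronchi.
    """

    q_T: float | np.ndarray
    q_1: float | np.ndarray
    q_2: float | np.ndarray
    q_P: float | np.ndarray
    P_J: float | np.ndarray


#: configuration keys accepted by :func:`resolve_parameters` (Table-1 symbols)
CONFIG_KEYS = frozenset(
    {
        "P_atm",
        "R_trachea",
        "R_EPPB",
        "R_T",
        "R_P",
        "R1_insp",
        "R1_exp",
        "R2_insp",
        "R2_exp",
        "k_insp",
        "k_exp",
        "gamma",
        "C_tot",
        "C1",
        "C2",
        "V1_res",
        "V2_res",
        "P_c",
        "P_amp",
        "T",
    }
)

_REQUIRED_KEYS = ("P_atm", "R_P", "R1_insp", "R2_exp", "V1_res", "V2_res", "P_c", "P_amp", "T")


@dataclass(frozen=True)
class ModelParameters:
    """Fully resolved model parameters in internal {cmH2O, L, s} units.

    Compliances are stored in L/cmH2O and resting volumes in L; use
    :meth:`to_config` to serialize back to the conventional mixed units
    (mL/cmH2O and mL).
    """

    P_atm: float  # atmospheric pressure, cmH2O
    R_P: float  # parabronchial (+ dorsobronchial) resistance, cmH2O/(L/s)
    R_T: float  # effective tracheal + primary bronchus resistance
    R1_insp: float  # mesobronchus resistance, inspiratory branch
    R1_exp: float  # mesobronchus resistance, expiratory branch (valved)
    R2_insp: float  # ventrobronchi resistance, inspiratory branch (valved)
    R2_exp: float  # ventrobronchi resistance, expiratory branch
    gamma: float  # compliance ratio C1/C2
    C_tot: float  # total airsac compliance, L/cmH2O
    C1: float  # caudal airsac compliance, L/cmH2O
    C2: float  # cranial airsac compliance, L/cmH2O
    V1_res: float  # caudal resting volume (single side), L
    V2_res: float  # cranial resting volume (single side), L
    P_c: float  # baseline coelomic pressure, cmH2O
    P_amp: float  # peak-to-peak forcing amplitude, cmH2O
    T: float  # breathing period, s
    k_insp: float = 100.0  # valving multiplier R2_insp / R1_insp
    k_exp: float = 10.0  # valving multiplier R1_exp / R2_exp
    R_trachea: float | None = None
    R_EPPB: float | None = None

    def __post_init__(self) -> None:
        positive = (
            "R_P R_T R1_insp R1_exp R2_insp R2_exp gamma C_tot C1 C2 T k_insp k_exp".split()
        )
        for name in positive:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"parameter {name} must be strictly positive, got {v!r}")
        if self.P_amp < 0:
            raise ParameterError(f"P_amp must be non-negative, got {self.P_amp!r}")
        # aerodynamic valving can only raise a resistance against the
        # non-preferred direction; the reversed ordering is physically odd
        # but dynamically well-defined, so it warns instead of failing
        # (wide resistance-ratio sweeps at fixed valving multipliers cross it)
        if self.R2_insp < self.R2_exp:
            warnings.warn(
                "R2_insp < R2_exp: inspiratory valving lowers resistance", stacklevel=2
            )
        if self.R1_exp < self.R1_insp:
            warnings.warn(
                "R1_exp < R1_insp: expiratory valving lowers resistance", stacklevel=2
            )
        if not math.isclose(self.C1 + self.C2, self.C_tot, rel_tol=_LINK_RTOL):
            raise ParameterError("C1 + C2 must equal C_tot")
        if not math.isclose(self.C1 / self.C2, self.gamma, rel_tol=_LINK_RTOL):
            raise ParameterError("C1 / C2 must equal gamma")

    def to_config(self) -> dict[str, float]:
        """Serialize to a flat config dict in conventional (mL-based) units."""
        cfg: dict[str, float] = {
            "P_atm": self.P_atm,
            "R_P": self.R_P,
            "R1_insp": self.R1_insp,
            "R1_exp": self.R1_exp,
            "R2_insp": self.R2_insp,
            "R2_exp": self.R2_exp,
            "gamma": self.gamma,
            "C_tot": self.C_tot * 1e3,
            "V1_res": self.V1_res * 1e3,
            "V2_res": self.V2_res * 1e3,
            "P_c": self.P_c,
            "P_amp": self.P_amp,
            "T": self.T,
            "k_insp": self.k_insp,
            "k_exp": self.k_exp,
        }
        if self.R_trachea is not None and self.R_EPPB is not None:
            cfg["R_trachea"] = self.R_trachea
            cfg["R_EPPB"] = self.R_EPPB
        else:
            cfg["R_T"] = self.R_T
        return cfg


def _check_consistent(name: str, given: float, derived: float) -> None:
    if not math.isclose(given, derived, rel_tol=_LINK_RTOL):
        raise ParameterError(
            f"over-determined configuration: {name} given as {given!r} but linked "
            f"parameters imply {derived!r}"
        )


def resolve_parameters(raw: dict[str, float]) -> ModelParameters:
    """Resolve a (possibly partial) configuration into :class:`ModelParameters`.

    Linkage rules: ``R_T = 2 R_trachea + R_EPPB`` unless given explicitly;
    ``C1 = gamma C_tot / (1 + gamma)`` and ``C2 = C_tot / (1 + gamma)``
    from either ``(C_tot, gamma)`` or ``(C1, C2)``; the valved branches
    default to ``R2_insp = k_insp * R1_insp`` and ``R1_exp = k_exp *
    R2_exp``.  Inputs supplied redundantly must agree to relative
    tolerance 1e-9 or a :class:`ParameterError` is raised.

    Compliances are accepted in mL/cmH2O and volumes in mL, as printed
    in the field's tables, and converted to L-based units internally.
    """
    unknown = set(raw) - CONFIG_KEYS
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise ParameterError(f"missing required parameter {key!r}")
    cfg = {k: float(v) for k, v in raw.items()}

    # effective tracheal resistance (both sides of the trachea in series
    # with the extrapulmonary primary bronchus, single-side reduction)
    R_trachea = cfg.get("R_trachea")
    R_EPPB = cfg.get("R_EPPB")
    if R_trachea is not None and R_EPPB is not None:
        R_T = 2.0 * R_trachea + R_EPPB
        if "R_T" in cfg:
            _check_consistent("R_T", cfg["R_T"], R_T)
    elif "R_T" in cfg:
        R_T = cfg["R_T"]
    else:
        raise ParameterError("missing required parameter 'R_T' (or 'R_trachea' and 'R_EPPB')")

    # compliances: config units are mL/cmH2O
    have_split = "C1" in cfg and "C2" in cfg
    if "C_tot" in cfg and "gamma" in cfg:
        C_tot, gamma = cfg["C_tot"], cfg["gamma"]
        C2 = C_tot / (1.0 + gamma)
        C1 = gamma * C_tot / (1.0 + gamma)
        if have_split:
            _check_consistent("C1", cfg["C1"], C1)
            _check_consistent("C2", cfg["C2"], C2)
    elif have_split:
        C1, C2 = cfg["C1"], cfg["C2"]
        C_tot = C1 + C2
        gamma = C1 / C2
        if "C_tot" in cfg:
            _check_consistent("C_tot", cfg["C_tot"], C_tot)
        if "gamma" in cfg:
            _check_consistent("gamma", cfg["gamma"], gamma)
    else:
        raise ParameterError(
            "missing required parameters: supply either ('C_tot', 'gamma') or ('C1', 'C2')"
        )

    # valved resistance branches
    R1_insp, R2_exp = cfg["R1_insp"], cfg["R2_exp"]
    if "R2_insp" in cfg:
        R2_insp = cfg["R2_insp"]
        if "k_insp" in cfg:
            _check_consistent("R2_insp", R2_insp, cfg["k_insp"] * R1_insp)
        k_insp = R2_insp / R1_insp
    else:
        k_insp = cfg.get("k_insp", 100.0)
        R2_insp = k_insp * R1_insp
    if "R1_exp" in cfg:
        R1_exp = cfg["R1_exp"]
        if "k_exp" in cfg:
            _check_consistent("R1_exp", R1_exp, cfg["k_exp"] * R2_exp)
        k_exp = R1_exp / R2_exp
    else:
        k_exp = cfg.get("k_exp", 10.0)
        R1_exp = k_exp * R2_exp

    return ModelParameters(
        P_atm=cfg["P_atm"],
        R_P=cfg["R_P"],
        R_T=R_T,
        R1_insp=R1_insp,
        R1_exp=R1_exp,
        R2_insp=R2_insp,
        R2_exp=R2_exp,
        gamma=gamma,
        C_tot=C_tot * 1e-3,
        C1=C1 * 1e-3,
        C2=C2 * 1e-3,
        V1_res=cfg["V1_res"] * 1e-3,
        V2_res=cfg["V2_res"] * 1e-3,
        P_c=cfg["P_c"],
        P_amp=cfg["P_amp"],
        T=cfg["T"],
        k_insp=k_insp,
        k_exp=k_exp,
        R_trachea=R_trachea,
        R_EPPB=R_EPPB,
    )


def external_pressure(t, p: ModelParameters):
    """Coelomic pressure ``P_ext(t) = P_c - (P_amp/2) cos(2 pi t / T)`` (cmH2O)."""
    return p.P_c - 0.5 * p.P_amp * np.cos(2.0 * np.pi * np.asarray(t) / p.T)


def external_pressure_rate(t, p: ModelParameters):
    """Time derivative of the coelomic pressure, ``P_amp (pi/T) sin(2 pi t / T)``."""
    return p.P_amp * np.pi / p.T * np.sin(2.0 * np.pi * np.asarray(t) / p.T)


def regime_resistances(regime: FlowRegime, p: ModelParameters) -> tuple[float, float]:
    """Active ``(R1, R2)`` pair for a flow regime."""
    R1 = p.R1_insp if regime.r1_branch == "insp" else p.R1_exp
    R2 = p.R2_insp if regime.r2_branch == "insp" else p.R2_exp
    return R1, R2


def _rbar(R1: float, R2: float, R_T: float) -> float:
    return R1 * R2 + R2 * R_T + R_T * R1


def compute_flows(x1, x2, regime: FlowRegime, p: ModelParameters) -> FlowSet:
    """All branch flows and the junction pressure for a state and regime.

    Accepts scalars or arrays for ``x1``/``x2``.  The junction mass
    balance ``q_T + q_2 = q_1`` holds identically by construction.
    """
    R1, R2 = regime_resistances(regime, p)
    Rbar = _rbar(R1, R2, p.R_T)
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    q_1 = (-R2 * x1 - p.R_T * (x1 - x2)) / Rbar
    q_2 = (R1 * x2 - p.R_T * (x1 - x2)) / Rbar
    q_T = (-R2 * x1 - R1 * x2) / Rbar
    q_P = (x1 - x2) / p.R_P
    P_J = p.P_atm + (R2 * p.R_T * x1 + p.R_T * R1 * x2) / Rbar
    return FlowSet(q_T=q_T, q_1=q_1, q_2=q_2, q_P=q_P, P_J=P_J)


def system_matrix(regime: FlowRegime, p: ModelParameters) -> np.ndarray:
    """Unscaled system matrix ``A`` of ``dx/dt = A x + (dP_ext/dt) [1, 1]^T``."""
    R1, R2 = regime_resistances(regime, p)
    Rbar = _rbar(R1, R2, p.R_T)
    beta = p.R_T * p.R_P + Rbar
    return np.array(
        [
            [-(beta + p.R_P * R2) / (p.C1 * Rbar * p.R_P), beta / (p.C1 * Rbar * p.R_P)],
            [beta / (p.C2 * Rbar * p.R_P), -(beta + p.R_P * R1) / (p.C2 * Rbar * p.R_P)],
        ]
    )


def state_derivative(t: float, x, regime: FlowRegime, p: ModelParameters) -> np.ndarray:
    """Right-hand side ``(dx1/dt, dx2/dt)`` for a frozen regime."""
    A = system_matrix(regime, p)
    rate = external_pressure_rate(t, p)
    return A @ np.asarray(x, dtype=float) + rate


def airsac_volumes(x1, x2, t, p: ModelParameters) -> tuple:
    """Single-side airsac volumes ``(V1, V2)`` in mL.

    ``V_i = C_i (x_i + P_atm - P_ext(t)) + V_i_res``.  Non-positive
    volumes indicate an unphysically large forcing and trigger a warning
    rather than an error.
    """
    pext = external_pressure(t, p)
    V1 = p.C1 * (np.asarray(x1) + p.P_atm - pext) + p.V1_res
    V2 = p.C2 * (np.asarray(x2) + p.P_atm - pext) + p.V2_res
    if np.any(np.asarray(V1) <= 0) or np.any(np.asarray(V2) <= 0):
        warnings.warn("airsac volume is non-positive; parameters are unphysical", stacklevel=2)
    return V1 * 1e3, V2 * 1e3


def classify_region(x1: float, x2: float, p: ModelParameters) -> tuple[str, dict[str, float]]:
    """Classify a state into phase-plane region '1', '2', '3' or '4'.

    The sign of ``q1`` is evaluated on the inspiratory branch of ``R2``
    (the branch active in regions 1-3, where the ``q1 = 0`` switching
    line lives) and the sign of ``q2`` on the expiratory branch of
    ``R1`` (active in regions 2-4).  Regions 2 and 3 share resistances
    and are separated only by the sign of the tracheal flow, evaluated
    with ``R1 = R1_exp`` and ``R2 = R2_insp``.

    Tie-break: flows exactly at zero take their preferred-direction
    branch (``q1 >= 0`` inspiratory, ``q2 <= 0`` inspiratory), so the
    equilibrium state maps to region 1.
    """
    f_insp = compute_flows(x1, x2, REGION_23, p)  # R2 = R2_insp branch
    if f_insp.q_1 >= 0:
        flows = compute_flows(x1, x2, REGION_1, p)
        return "1", {"q_T": float(flows.q_T), "q_1": float(flows.q_1), "q_2": float(flows.q_2)}
    f_exp = compute_flows(x1, x2, REGION_4, p)  # R1 = R1_exp branch
    if f_exp.q_2 > 0:
        return "4", {"q_T": float(f_exp.q_T), "q_1": float(f_exp.q_1), "q_2": float(f_exp.q_2)}
    f_23 = compute_flows(x1, x2, REGION_23, p)
    label = "2" if f_23.q_T > 0 else "3"
    return label, {"q_T": float(f_23.q_T), "q_1": float(f_23.q_1), "q_2": float(f_23.q_2)}


def regime_for_label(label: str) -> FlowRegime:
    """Map a region label ('1', '2', '3', '23', '4') to its resistance regime."""
    try:
        return _REGIMES_BY_LABEL[label]
    except KeyError:
        raise ParameterError(f"unknown region label {label!r}") from None
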