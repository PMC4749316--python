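"""Phase-plane analysis of the frozen-regime linear system.

Within any one flow regime the unforced model is a linear 2-D system
``dx/dt = A x``.  After scaling time by ``C1 * Rbar * R_P`` the matrix
takes the compact dimensionless-time form::

    A_hat = [[-(R2 R_P + beta),        beta          ],
             [      gamma beta, -gamma (R1 R_P + beta)]]

with ``beta = R_T R_P + Rbar`` and ``Rbar = R1 R2 + R2 R_T + R_T R1``.
For positive parameters the trace is negative, the determinant positive
and the discriminant strictly positive, so there are always two real
negative eigenvalues ``lambda1 < lambda2 < 0``: a fast and a slow decay
direction.  The slow eigenvector controls where trajectories settle in
the phase plane, which yields an algebraic certificate for
unidirectional parabronchial flow: ``gamma R1 <= R2`` during
inspiration and ``gamma R1 >= R2`` during expiration, with ``q_P``
identically zero in the borderline (both equalities) case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import FlowRegime, ModelParameters, regime_resistances

__all__ = [
    "EigenAnalysis",
    "ValvingCertificate",
    "scaled_system_matrix",
    "eigen_analysis",
    "special_case_eigen",
    "unidirectional_flow_condition",
]

#: relative tolerance used to treat a valving condition as an equality
_EQ_RTOL = 1e-12


@dataclass(frozen=True)
class EigenAnalysis:
    """Eigen-structure of the scaled frozen-regime system matrix."""

    A_hat: np.ndarray
    beta: float
    trace: float
    determinant: float
    discriminant: float
    lambda1: float  # fast (more negative)
    lambda2: float  # slow
    V_fast: np.ndarray  # normalized: first component 1
    V_slow: np.ndarray


@dataclass(frozen=True)
class ValvingCertificate:
    """Algebraic unidirectional-flow certificate.

    ``verdict`` is ``unidirectional`` when ``gamma R1_insp <= R2_insp``
    and ``gamma R1_exp >= R2_exp`` with at least one inequality strict,
    ``borderline`` when both hold with equality (zero parabronchial
    flow), and ``violated`` otherwise.
    """

    gamma_R1_insp: float
    R2_insp: float
    gamma_R1_exp: float
    R2_exp: float
    insp_condition: bool  # gamma R1 <= R2 during inspiration
    exp_condition: bool  # gamma R1 >= R2 during expiration
    verdict: str  # unidirectional | borderline | violated
    effective_valves: str  # inspiratory | expiratory | both | none

    def to_dict(self) -> dict:
        return {
            "gamma_R1_insp": self.gamma_R1_insp,
            "R2_insp": self.R2_insp,
            "gamma_R1_exp": self.gamma_R1_exp,
            "R2_exp": self.R2_exp,
            "insp_condition": self.insp_condition,
            "exp_condition": self.exp_condition,
            "verdict": self.verdict,
            "effective_valves": self.effective_valves,
        }


def scaled_system_matrix(regime: FlowRegime, p: ModelParameters) -> tuple[np.ndarray, float]:
    """Scaled matrix ``A_hat`` and the combined-resistance term ``beta``."""
    R1, R2 = regime_resistances(regime, p)
    Rbar = R1 * R2 + R2 * p.R_T + p.R_T * R1
    beta = p.R_T * p.R_P + Rbar
    g = p.gamma
    A_hat = np.array(
        [
            [-(R2 * p.R_P + beta), beta],
            [g * beta, -g * (R1 * p.R_P + beta)],
        ]
    )
    return A_hat, beta


def eigen_analysis(regime: FlowRegime, p: ModelParameters) -> EigenAnalysis:
    """Closed-form eigenpairs of the scaled frozen-regime system.

    The eigenvalues come from the trace/determinant quadratic and the
    eigenvectors from the first matrix row, normalized to a unit first
    component: ``V_i = [1, (lambda_i + R2 R_P + beta) / beta]``.  Labels
    fast/slow are assigned by eigenvalue magnitude and asserted to agree
    with the closed-form ordering.
    """
    R1, R2 = regime_resistances(regime, p)
    A_hat, beta = scaled_system_matrix(regime, p)
    g = p.gamma
    tr = -(g * R1 + R2) * p.R_P - (g + 1.0) * beta
    det = g * (R1 * R2 * p.R_P**2 + beta * (R1 + R2) * p.R_P)
    disc = tr * tr - 4.0 * det
    assert disc > 0, "discriminant must be positive for positive parameters"
    sq = math.sqrt(disc)
    lam1 = 0.5 * (tr - sq)  # fast: larger magnitude
    lam2 = 0.5 * (tr + sq)  # slow
    assert lam1 < lam2 < 0
    v_fast = np.array([1.0, (lam1 + R2 * p.R_P + beta) / beta])
    v_slow = np.array([1.0, (lam2 + R2 * p.R_P + beta) / beta])
    return EigenAnalysis(
        A_hat=A_hat,
        beta=beta,
        trace=tr,
        determinant=det,
        discriminant=disc,
        lambda1=lam1,
        lambda2=lam2,
        V_fast=v_fast,
        V_slow=v_slow,
    )


def special_case_eigen(regime: FlowRegime, p: ModelParameters) -> EigenAnalysis:
    """Simplified eigenpairs for equal compliances (``gamma = 1``).

    With ``gamma = 1`` the eigenvalues reduce to
    ``-(1/2) [(R1 + R2) R_P + 2 beta -+ sqrt((R2 - R1)^2 R_P^2 + 4 beta^2)]``
    and the eigenvector second components to
    ``[(R2 - R1) R_P / 2 -+ sqrt(...) / 2] / beta``.  Must agree with
    :func:`eigen_analysis` to rounding error.
    """
    if not math.isclose(p.gamma, 1.0, rel_tol=1e-12):
        raise ValueError(f"special-case analysis requires gamma = 1, got {p.gamma!r}")
    R1, R2 = regime_resistances(regime, p)
    A_hat, beta = scaled_system_matrix(regime, p)
    root = math.sqrt((R2 - R1) ** 2 * p.R_P**2 + 4.0 * beta**2)
    base = (R1 + R2) * p.R_P + 2.0 * beta
    lam1 = -0.5 * (base + root)
    lam2 = -0.5 * (base - root)
    v_fast = np.array([1.0, (0.5 * (R2 - R1) * p.R_P - 0.5 * root) / beta])
    v_slow = np.array([1.0, (0.5 * (R2 - R1) * p.R_P + 0.5 * root) / beta])
    tr = lam1 + lam2
    det = lam1 * lam2
    return EigenAnalysis(
        A_hat=A_hat,
        beta=beta,
        trace=tr,
        determinant=det,
        discriminant=tr * tr - 4.0 * det,
        lambda1=lam1,
        lambda2=lam2,
        V_fast=v_fast,
        V_slow=v_slow,
    )


def unidirectional_flow_condition(p: ModelParameters) -> ValvingCertificate:
    """Evaluate the algebraic conditions for unidirectional flow."""
    gi = p.gamma * p.R1_insp
    ge = p.gamma * p.R1_exp
    insp_eq = math.isclose(gi, p.R2_insp, rel_tol=_EQ_RTOL)
    exp_eq = math.isclose(ge, p.R2_exp, rel_tol=_EQ_RTOL)
    insp_ok = gi <= p.R2_insp or insp_eq
    exp_ok = ge >= p.R2_exp or exp_eq
    insp_strict = insp_ok and not insp_eq
    exp_strict = exp_ok and not exp_eq

    if insp_ok and exp_ok:
        verdict = "borderline" if (insp_eq and exp_eq) else "unidirectional"
    else:
        verdict = "violated"
    valves = {
        (True, True): "both",
        (True, False): "inspiratory",
        (False, True): "expiratory",
        (False, False): "none",
    }[(insp_strict, exp_strict)]
    return ValvingCertificate(
        gamma_R1_insp=gi,
        R2_insp=p.R2_insp,
        gamma_R1_exp=ge,
        R2_exp=p.R2_exp,
        insp_condition=insp_ok,
        exp_condition=exp_ok,
        verdict=verdict,
        effective_valves=valves,
    )
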