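# Methods

## Model

The avian respiratory system is reduced to one symmetric side of a
two-compartment RC network. The caudal (index 1) and cranial (index 2)
airsac groups are lumped elastic compartments, V_i = C_i (P_i − P_ext) +
V_i,res, ventilated through rigid resistive airways: trachea plus
extrapulmonary primary bronchus (R_T = 2·R_trachea + R_EPPB, the factor
two because the single-side reduction puts both tracheal halves in
series), mesobronchus (R₁), ventrobronchi (R₂) and the
dorsobronchi/parabronchi path (R_P). Flows are laminar (pressure drop
proportional to flow) and air compression is neglected, so the junction
obeys exact mass balance q_T + q₂ = q₁. Breathing enters as a
prescribed sinusoidal coelomic pressure acting identically on both
compartments, which in the transformed coordinates x_i = P_i − P_atm is
an additive forcing along [1, 1]ᵀ.

Aerodynamic valving is modelled by switching each of R₁ and R₂ between
two constant values as the sign of its branch flow changes (a Heaviside
dependence on the local pressure difference): R₂ rises from R2_exp to
R2_insp = k_insp·R1_insp while q₂ < 0 (inspiration), R₁ rises from
R1_insp to R1_exp = k_exp·R2_exp while q₁ < 0 (expiration). The state
space splits into regions by the signs of (q₁, q₂): region 1
(q₁ > 0, q₂ < 0), a shared region 2/3 block (both negative,
distinguished only by the sign of q_T, with identical resistances) and
region 4 (q₁ < 0, q₂ > 0). The combination q₁ > 0 with q₂ > 0 cannot
occur and is rejected as a regime.

Within each region the system is linear with matrix A; scaling time by
C₁R̄R_P gives Â = [[−(R₂R_P + β), β], [γβ, −γ(R₁R_P + β)]] with
β = R_T R_P + R̄ and γ = C₁/C₂. For positive parameters Tr(Â) < 0,
Det(Â) > 0 and the discriminant is strictly positive, so every region
has two real negative eigenvalues (a fast and a slow direction; the
slow eigenvector, normalized to first component 1, has second component
(λ_slow + R₂R_P + β)/β). Because the forcing acts along [1, 1]ᵀ and
trajectories relax onto the slow eigenvector, parabronchial flow
q_P = (x₁ − x₂)/R_P stays positive exactly when the slow eigenvector
lies on or below the diagonal in both phases: γR₁ ≤ R₂ during
inspiration and γR₁ ≥ R₂ during expiration. The package evaluates this
as a certificate (`unidirectional` / `borderline` / `violated`) and the
test suite confirms it against simulation in all three cases.

## Parameters

Defaults describe a resting duck; units are cmH₂O for pressures,
cmH₂O/(L/s) for resistances, mL/cmH₂O for compliances and mL for
volumes in configuration files. Internally everything is converted once
to a consistent {cmH₂O, L, s} system, which removes the classic
mixed-unit pitfall of mL-based compliances against L/s-based
resistances.

| symbol | default | meaning |
|---|---|---|
| R_trachea, R_EPPB | 1, 8 | tracheal / extrapulmonary bronchus resistance |
| R_P | 2.5 | parabronchial path resistance |
| R1_insp, R2_exp | 1, 5 | mesobronchial / ventrobronchial base resistances |
| k_insp, k_exp | 100, 10 | valving multipliers (set R2_insp, R1_exp) |
| γ | 1.35 | caudal/cranial compliance ratio |
| C_tot | 450 | total airsac compliance |
| V1_res, V2_res | 105.6, 103.6 | single-side resting volumes |
| P_amp, T | 0.5, 3 | peak-to-peak forcing amplitude, period |
| P_c = P_atm | 1033.6 | baseline coelomic / atmospheric pressure |

Linked quantities (R_T, C₁, C₂, R2_insp, R1_exp) are always re-derived
from their parents when a configuration is resolved; redundant inputs
must agree to a relative 1e-9 or resolution fails. The valving
orderings R2_insp ≥ R2_exp and R1_exp ≥ R1_insp are diagnostics
(warnings), not hard errors: wide resistance-ratio sweeps at fixed
multipliers legitimately cross them while remaining unidirectional.

## Numerical integration

Each fixed-regime "leg" of the trajectory is integrated with an
adaptive Runge–Kutta method (scipy `solve_ivp`, RK45, rtol 1e-9,
atol 1e-12) with terminal, direction-filtered events on the governing
flows: q₁ ↓ 0 leaves region 1, q₂ ↑ 0 / q₂ ↓ 0 bound region 4, q₁ ↑ 0
re-enters region 1. Event roots are bracketed by the solver and
polished to machine precision, so switching-time error is negligible
against the output sampling step. Zero crossings of q_T are located
the same way but switch nothing; they define the inspiration (q_T > 0)
/ expiration (q_T < 0) partition.

Degenerate situations are handled explicitly: a terminal event at the
exact start of a leg whose event function is stationary there is the
unforced equilibrium sitting on a switching surface, not a crossing,
and is ignored (an unforced run then correctly reports that no breath
completes); a leg that returns to the previous regime within 1e-9 s is
classified as chatter on the switching surface and raises a
sliding-mode error rather than being integrated — no Filippov sliding
solver is attempted. Simultaneous crossings (the borderline no-valving
case, where q₁ and q₂ reach zero together on the diagonal) pass
through correctly because the two surfaces carry identical resistance
values there.

Breath bookkeeping is keyed to the upward q_T crossing (start of
inspiration), which recurs once per forcing period in every regime
cycle we have encountered — including certificate-violating parameter
sets in which region 1 is never visited and the cycle alternates
between the region 2/3 block and region 4. The net tracheal volume per
breath is accumulated as an auxiliary ODE state (solver-accurate,
independent of output sampling); steady state is declared when its
magnitude falls below 1e-5 L, interpreted in litres as the consistent
unit (configurable). The initial condition is the equilibrium
x = (0, 0) taken at the forcing maximum (onset of inspiratory effort),
a pure phase choice that the steady-state criterion erases; defaults
converge in ~18 breaths.

The reported final breath spans exactly one period, re-timed so t = 0
is the start of inspiration, sampled on a δt = 1e-4 s grid (the
`TimeSeries.t_offset` attribute preserves the absolute forcing phase).
Event times are inserted into the grid, so phase integrals have exact
endpoints; at a switch time the sample of the incoming regime is kept,
which keeps t strictly increasing at the cost of the (discontinuous)
outgoing flow value at that single instant — an O(δt·Δq) ≈ 1e-3 mL
effect, far below reporting precision.

A deliberately naive fixed-step RK4 integrator that re-derives the
regime from flow signs at every step (no event location) ships as a
verification oracle; the test suite cross-checks the two integrators
to < 1e-4 cmH₂O over a breath on the defaults and on random
unidirectional parameter sets.

## Metrics

All volumes are trapezoidal integrals of the sampled flows
(numpy.trapezoid) over event-delimited intervals: tidal volume
∫_insp q_T, parabronchial throughput ∫_breath q_P, efficiency their
ratio, inspiratory valving efficacy ∫_insp q₁ / ∫_insp q_T, expiratory
valving efficacy ∫_exp q₂ / ∫_exp(−q_T), and an alternative expiratory
efficacy referenced to total caudal outflow, ∫_exp q_P / ∫_exp(q_P +
max(−q₁, 0)) — the back-leak term is clamped at zero sample-wise so the
denominator remains a genuine outflow (keeping the measure in [0, 1])
even if q₁ grazes positive near a phase boundary. Airsac ventilation is
max(V_i) − min(V_i) per breath, invariant to the baseline pressure and
resting volumes, which enter V_i additively. Flows and volumes are
single-side; reported volumes are doubled to whole-animal by default
(flag-controlled), and all ratios are doubling-invariant. Halving δt
moves every default-run metric by well under 0.1 %.

## Experiments

Sweeps re-resolve the complete parameter set from the base
configuration at every point, so linked parameters cannot drift along a
sweep. The constant-total-resistance mode sweeps r = R1_insp/R2_exp at
R1_insp + R2_exp = 6 cmH₂O/(L/s) with the valving multipliers
re-applied, reproducing the efficiency maximum at 0.2 < r < 1 and the
monotone rise of the I:E time ratio with r. The inverse fit recovers γ
from a target caudal share of total airsac ventilation by a coarse
geometric scan for a bracket followed by deterministic bisection
(tolerance 1e-3 in the fraction, full steady-state simulation per
evaluation); the share is monotone in γ over the scanned range
[0.05, 20]. Sweep and fit evaluations default to a coarser δt = 1e-3 s
sampling, which the step-halving stability results justify.

## What the fixtures do and do not show

The shipped configurations are idealizations: strictly laminar
(constant) resistances in each branch, a single rigid junction, a
perfectly sinusoidal single-compartment coelomic pressure, and
instantaneous resistance switching. Real airways have flow-dependent
resistances, compliant walls and neopulmonic shunt paths (absorbed here
into the lumped resistances), so quantitative agreement with any
individual animal is not implied; the reproduced quantities are
population-scale summaries (efficiencies, ventilation splits, timing
ratios) under resting-duck parameters. Gas exchange, O₂/CO₂ transport
and cross-current exchange efficiency are out of scope — "efficiency"
here is purely volumetric.

## Known limitations

- Parameter sets that induce genuine sliding on a switching surface are
  diagnosed, not simulated.
- Multi-phase breaths (more than two q_T crossings per period) are
  integrated and flagged with a warning, but the per-breath metrics then
  aggregate all same-phase intervals, which may not match how such
  breathing patterns are scored experimentally.
- Two published expiratory-efficacy figures for the single-valve
  variants could not be reconciled with the stated tracheal-referenced
  definition evaluated on trajectories that reproduce every co-reported
  quantity to printed precision; the package reports the definition as
  stated.
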