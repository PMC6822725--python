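# Methods

`undulate` models the energetics of steady, straight-line undulatory
swimming with three coupled sub-models — muscle, structure, hydrodynamics —
and optimizes swimmers against the two conflicting performance measures of
sustained speed *U* and cost of transport COT. This note records the model,
its assumptions, the numerical choices, and what the synthetic study
conditions do and do not establish.

## Muscle model

Fibers are assumed quasi-steady: at every instant the force of a tetanically
active fiber depends only on its current contraction strain rate *v* (in
fiber-lengths/s), through Hill's force–velocity relation with shape constant
G = 4,

    F_f/F0 = (1 - v_r)/(1 + G v_r)                      0 <= v_r <= 1
    F_f/F0 = 1.8 - 0.8 (1 + v_r)/(1 - 7.56 G v_r)      -1 <= v_r <  0

with v_r = v/v_max, and a companion consumption curve

    Q_f/(F0 v_max) = 0.23 - 0.16 exp(-8 v_r)            0 <= v_r <= 1
    Q_f/(F0 v_max) = 0.01 - 0.11 v_r + 0.06 exp(23 v_r) -1 <= v_r <  0

Both branches meet at v_r = 0 (values 1 and 0.07); the kink in F_f at zero
rate is physical and kept exact (no smoothing). Length–tension effects,
activation transients and calcium dynamics are out of scope (steady
swimming operates on the length–tension plateau, and the fiber adaptation
time is short against the tail-beat period). Only red (aerobic) muscle is
modeled.

During steady swimming the required muscle force F_m(t) and the contraction
rate v_r(t) at a cross section are single-harmonic sinusoids, characterized
by amplitudes (F^m, v^r) and a phase lag Phi. The fraction of the muscle
cross-section recruited is mu(t) = |F_m|/(F_f(v_a) A_m), where the active
side is selected by the sign of F_m and v_a = sign(F_m) v_R is the rate felt
by that side (negative while braking). Motion is feasible iff mu <= 1 at all
times (the force loop stays inside the full-activation envelope) and
v^r < 1. Cycle averages give the mechanical output p_bar (closed form
(1/2) F^m v^r cos Phi), the always-positive consumption q_bar, and the local
muscle efficiency eta_m = p_bar/q_bar, defined as 0 when p_bar <= 0
(braking mode is reported separately as the braking fraction).

With the standard constants (F0 = 150 kN/m², v_max = 5 s⁻¹, muscle density
1000 kg/m³ — equal to the body/water density, the choice that converts
volumetric to per-mass powers) the model yields: constant-rate fiber
efficiency peaking at 45.1% (v_r ≈ 0.23), constant-rate power peaking at
v_r = (√5−1)/4 ≈ 0.31 (71.6 W/kg), cyclic power peaking at 35.8 W/kg
(exactly half the constant-rate peak, from sin² averaging), cyclic
consumption peaking at 81.2 W/kg, and cyclic efficiency peaking at 44.5%
(v^r ≈ 0.27). These are recomputed from scratch by `scripts/acceptance.py`.

## Body and kinematics

The body is neutrally buoyant and laterally symmetric with elliptical
sections of height d(x) and width b(x) on x ∈ [0, L]. The five-parameter
shape basis (ξ = x/L)

    d/L = DL + c_d1 sin(πξ) + c_d2 sin(2πξ)
    b/L = BL sin(πξ)^c_b1

covers fusiform and peduncled outlines. Height equals the tail height D at
both ends, keeping the tail added mass nonzero; the width tapers to zero at
snout and tail. The taper is a deliberate numerical choice: the bending
stiffness I = (π/64) d b³ then vanishes cubically at the ends, so the
free-end conditions of the beam hold for any smooth envelope and the
elastic boundary terms in the energy budget vanish identically. Length
follows from the mass constraint m = ρ (π/4) L³ ∫ d̃ b̃ dξ; the wetted
surface integrates Ramanujan's elliptic-perimeter approximation; the added
mass per length is that of an elliptic cylinder translating perpendicular
to its vertical axis, m_a = ρ π d²/4 (set by the height alone).

Kinematics: h(x,t) = r(x) cos(2πx/λ_b − ωt) with body wavelength λ_b = L
fixed; the envelope r(x)/L is a 3-term Chebyshev series (validated
non-negative on the grid) and ω completes the four motion parameters —
nine optimization variables in total. The superficial-fiber strain rate is
v = ±(1/2) b ∂t ∂xx h; rigid recoil adds no curvature, so v is
recoil-independent.

## Hydrodynamics

Lighthill slender-body (reactive) theory: F_L = (∂t + U ∂x)[m_a (∂t + U ∂x) ĥ]
with total deflection ĥ = h + y0 + xφ. The rigid recoil (y0, φ) is solved
from whole-body lateral force and moment balance; because the model is
linear and single-harmonic, every operator acts on complex amplitudes and
time averages of products are ½ Re[A conj(B)]. Mean thrust is Lighthill's
tail expression; mean drag is ½ ρ U² S C_D with

    C_f = 1.33 Re^-1/2 (Re <= 5e5),  0.072 Re^-1/5 (Re > 5e5)
    C_D = C_f (1 + 1.5 (D/L)^1.5 + 7 (D/L)^3)

The drag discontinuity at Re_cr = 5×10⁵ (ratio ≈ 2.77) is the mechanism
that makes optimal swimmers of intermediate mass cling just below the
critical Reynolds number. The steady speed solves thrust = drag separately
on the laminar and turbulent branches (log-grid bracketing + Brent, relative
tolerance 1e-10); a root is accepted only if its Re is consistent with its
branch, and both roots are returned (fastest first) when both are
self-consistent near the transition. Validity: slender body, small
amplitude, Re ≳ 10⁴; no CFD, vortex-wake structure or large-amplitude
theory.

## Structure

The Euler–Bernoulli balance ρA ĥ_tt + (EIĥ″)″ + (ν_b I ĥ_t″)″ + F_L = −M″
yields the muscle bending moment by double integration from the snout with
M(0) = M′(0) = 0. The inertial + hydrodynamic load is integrated with nested
cumulative trapezoids; the elastic and visco-elastic terms integrate in
closed form to (E + ν_b ∂t) I ĥ″ because I and I′ vanish at the snout. The
recoil solve uses the same discrete functionals, so the free-tail closure
M(L) = M′(L) = 0 holds to machine precision and is checked (tolerance 1e-6
relative), not imposed. Aggregate passive properties E = 10⁵ N/m² and
ν_b = 10⁴ m²/s act on the full section I(x).

The muscle force is F_m = −M/(0.5 b). The sign is the package's convention:
the beam equation defines M only up to the curvature sign, and this choice
makes the length-integrated muscle power close as P = P_H + P_V (inertial
and elastic terms average to zero over a cycle), which is verified to 0.5%
on random feasible swimmers. Visco-elastic dissipation is
P_V = ν_b ∫ I ½ ω² |ĥ″|² dx and the internal efficiency
eta_I = 1/(1 + P_V/P_H).

## Integral measures

Per section, the complex fields F_m(x) and V(x) give (F^m, v^r, Phi)(x) and
hence p_bar(x), q_bar(x), eta_m(x), the activation envelope mu^(x) and the
braking regions (Phi > 90°). Length integration gives P (net, signed — tail
braking subtracts, consistent with the closure) and Q (always positive;
eccentric consumption counts). Then

    COT = (P_s + Q)/(m g U),  P_s = 0.1327 m^0.80 W
    eta_M = P/Q  (bounded by the cyclic maximum 44.5%)
    eta_T = eta_H · eta_M · eta_I  (computed as the product, an identity)
    Psi = P/m_M,  Theta = Q/m_M,  m_M = 0.5 μ0 m, μ0 = 0.1

g = 9.81 m/s² enters only the nondimensionalization of COT.

## Optimization

Two objectives: maximize U, minimize COT, at fixed mass, over the nine
parameters within documented box bounds (e.g. ω ∈ [0.1, 200] rad/s,
envelope coefficients keeping r/L ≲ 0.2). Infeasible candidates (invalid
shape, no steady speed, mu^ > 1 or v^r ≥ 1) never enter the Pareto set.

The optimizer is an elitist (μ+λ) evolutionary algorithm with
self-adaptive variation: binary tournament on (non-domination rank,
crowding distance), simulated binary crossover (η = 10) whose step scales
with the population spread, polynomial mutation (η = 20, rate 1/9), and
truncation of the merged population by rank then crowding. The initial
population is rejection-sampled feasible (ω log-uniform — the feasible
frequency window spans decades across masses). An external archive keeps
every feasible non-dominated point, making the front hypervolume
non-decreasing; the reported optimal population is the evolved final
population's non-dominated set, whose boundary members (the U-optimal and
COT-optimal swimmers) always survive selection. Everything is reproducible
from a single seed.

Desk-scale defaults are population 40 × 60 generations (≈ 1 minute per
mass); they reproduce the qualitative structure of the optimal populations
— the speed–cost trade-off, U-optimal swimmers that fully employ their
muscle (mu^ ≈ 1) and lead the population in muscle efficiency and specific
powers, COT-optimal swimmers that trail in both, and optima pinned just
below Re_cr. Converged quantitative fronts need budgets of order 500 × 500
(exposed through the configuration, not run by default).

## Numerical choices

- Grid: N = 256 points on [0, L]; derivatives by dense 4th-order central
  differences with one-sided closures (the second derivative is the square
  of the first, keeping nested products discretely consistent).
- Cycle quadrature: uniform midpoint rule, 1024 samples/period by default
  (4096 in the headline analytics); midpoints avoid landing on the |·|
  kinks. Scalar maximizations: bounded Brent, tolerance 1e-6 or finer;
  maximizer locations are reported at 1e-4 precision and compared after
  rounding to two decimals.
- Degenerate inputs: zero envelope → no-steady-speed error; zero force →
  mu = 0; sections with vanishing muscle strip carry zero power by
  construction; eta_m := 0 where p_bar <= 0.

## Synthetic study conditions and limitations

There are no external data. The reference fixture is a fusiform swimmer
with a per-decade frequency/amplitude allometry (ω = 8 m^-1/3 rad/s and
fixed amplitude above 1 kg; ω = 8 m^-1/4 with amplitude ∝ m^0.23 below),
calibrated once so the fixture is feasible from 1 g to 1000 t. It emulates
realistic size scaling of tail-beat frequency and relative contraction
rate; it does not emulate species-specific shapes, fin appendages,
intermittent (burst-and-coast) gaits, or white-muscle recruitment, so
passing tests demonstrate internal consistency of the model and the
qualitative optimality structure, not agreement with any particular
organism. Hydrodynamic efficiencies from reactive slender-body theory tend
to run high compared to CFD; absolute COT values inherit that bias.
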