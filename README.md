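# undulate

Energetics of steady undulatory swimming, for biomechanists and
computational physiologists who want whole-body power budgets — not just
kinematics — from body shape and motion alone.

A swimmer of mass *m* passes a single-harmonic wave of curvature
h(x,t) = r(x) cos(2πx/λ_b − ωt) down its body. Three coupled linear models
turn that motion into a complete energetic account:

- **Hydrodynamics** (Lighthill slender-body theory with rigid-body recoil)
  gives the lateral force field, the mean thrust, and the steady speed *U*
  from thrust = drag, with an empirical drag coefficient that jumps at the
  laminar–turbulent transition (Re_cr = 5×10⁵).
- **Structure** (Euler–Bernoulli beam with aggregate visco-elastic tissue)
  extracts the bending moment M(x,t) the muscles must supply, and the
  internal losses P_V.
- **Muscle** (Hill force–velocity model, G = 4) converts the required force
  and contraction rate at every cross section into the recruited fraction
  μ(x,t), the mechanical output p̄(x), the metabolic consumption q̄(x), and
  feasibility (μ ≤ 1, v̂ < v_max).

Whole-body measures follow: the cost of transport
COT = (P_s + Q)/(mgU) with standard metabolism P_s = 0.1327 m^0.80 W, the
muscle efficiency η_M = P/Q, the internal efficiency η_I = 1/(1+P_V/P_H),
the Froude efficiency η_H = F̄_T U/P_H, and the total efficiency
η_T = η_H η_M η_I. A built-in two-objective evolutionary optimizer evolves
populations of swimmers (maximize *U*, minimize COT) at fixed mass and
extracts the Pareto-optimal population.

## Worked example

Evaluate the 1 kg reference swimmer and print its report:

```sh
$ undulate simulate --mass 1.0 --out-dir out/
U = 0.3505 m/s  Re = 1.364e+05  COT = 0.341  eta_H = 0.750  eta_M = 0.334  eta_T = 0.0072  feasible = True
```

A 0.39 m, 1 kg swimmer beating its tail at 8 rad/s swims at 0.35 m/s in the
laminar regime (Re ≈ 1.4×10⁵). Moving costs it 0.34 J per newton of body
weight per metre travelled; a third of the metabolic power consumed by its
red muscle emerges as mechanical work (η_M = 0.334, below the cyclic
ceiling of 44.5%), and three quarters of the power reaching the fluid
becomes thrust work (η_H = 0.750). For this deliberately gentle,
un-optimized reference swimmer most of the muscle output is eaten by
visco-elastic tissue losses (η_I = 0.029), leaving η_T = 0.72% end to end —
optimized swimmers recover much higher internal efficiencies.
`out/profiles.csv` holds the longitudinal profiles (p̄, q̄, η_m, phase lag
Φ, activation envelope μ̂, contraction-rate envelope v̂_r);
`out/report.json` the full report.

The same from Python:

```python
from undulate import generate_fixture, evaluate

cfg = generate_fixture(1.0)
cand = evaluate(cfg.swimmer.params, cfg.swimmer.mass)
print(cand.report.U, cand.report.COT, cand.report.eta_M)
```

Muscle analytics and optimization:

```sh
undulate muscle-curves --out-dir out/        # Hill curves + cyclic maxima CSVs
undulate optimize --mass 1.0 --pop 40 --gens 60 --seed 0 --out-dir out/
undulate scan --masses 0.1,1,10 --out-dir out/
```

The optimizer prints the front ends, e.g. the U-optimal swimmer (fastest,
costliest, muscle fully employed) and the COT-optimal one (slowest,
cheapest); `pareto_front.csv` lists the optimal population.

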