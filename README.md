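# gpx4kin

Kinetic analysis of the selenoenzyme **GPX4** (glutathione peroxidase 4)
acting on membranes. GPX4 reduces phospholipid hydroperoxides in lipid
bilayers at the expense of GSH, the reaction that keeps membranes out of
ferroptosis; on liposomes its observed kinetics convolve a distinct
membrane-docking step with the interfacial peroxidase cycle. This package
is for enzymologists who want to simulate, fit and diagnose
NADPH-coupled progression curves of that reaction — including the
non-canonical behaviour of the wild-type enzyme on cardiolipin-containing
membranes (rates that start low and accelerate, an association constant
that grows with enzyme concentration) and its loss in the disease mutant
R152H.

## The model

Three reactions, five pools in bulk molarity:

```
E_sol + M   ⇌(k_A, k_B)   EM              membrane docking
EM + SLPCOOH    →(k_1s)   EoxM + SLPCOH   surface oxidative step
EoxM + 2 GSH    →(k_2s)   EM + GSSG       lumped reductive step
```

giving the ODE system

```
d[E_red]/dt   = −k_A [E_sol][M] + k_B [EM]
d[EM]/dt      =  k_A [E_red][M] + k_2s [EoxM][GSH]² − k_1s [EM][SLPCOOH] − k_B [EM]
d[SLPCOOH]/dt = −k_1s [EM][SLPCOOH]
d[EoxM]/dt    =  k_1s [EM][SLPCOOH] − k_2s [EoxM][GSH]²
d[GSSG]/dt    =  k_2s [EoxM][GSH]²
```

with `[M]` the total liposomal phospholipid (a binding platform, not a
substrate) and `[GSH]` held constant by the glutathione-reductase/NADPH
regenerating system. The observable is A340 = ε·ℓ·([NADPH]₀ − [GSSG](t)),
ε = 6220 M⁻¹cm⁻¹. Each recorded curve is fitted singly for
(k_A, k_B, k_1s, k_2s) by differential evolution in log10 space
(RMSD objective, exact forward-sensitivity least-squares polish).

For micellar substrates the package implements the simplified Dalziel
ping-pong law `E/v₀ = φ₀ + φ₁/[ROOH] + φ₂/[GSH]` (φ₀ ≈ 0 for
selenoperoxidases), extracting instantaneous velocities along progression
curves and returning the apparent constants k₁ = 1/φ₁ and k'₂ = 1/φ₂.
Bridges between representations: k_A = k_a2/(k_d1/k_a1 + [M]) and
k_B = k_d2 from two-step SPR constants, and k_2s = k'₂/[GSH].

Because no raw spectrophotometric traces are distributed, a first-class
synthetic-data module emulates the assays (0.4 mM liposomal phospholipid,
50 µM SLPCOOH, 2.5 mM GSH, 0.16 mM NADPH, nanomolar enzyme, Gaussian
instrument noise) so every stage is testable offline.

## Worked example

```python
import numpy as np
from gpx4kin import (
    DalzielCoefficients, KineticParameters, ReactionConditions,
    classify_rate_shape, estimate_initial_rate, extract_velocity_curve,
    fit_dalziel, generate_dalziel_dataset, generate_trace, simulate,
)

# liposome assay: wild-type enzyme on 20% cardiolipin membranes
params = KineticParameters(k_A=40.0, k_B=3e-3, k_1s=1e4, k_2s=1e5)
cond = ReactionConditions(E_total=9.5e-9, M_total=4e-4, ROOH_0=5e-5,
                          tocl_fraction=0.20)
trace = generate_trace(params, cond, duration=900, interval=1.0)
traj = simulate(params, cond, trace.times)
v0 = estimate_initial_rate(trace)
print(f"initial rate: {v0.v0:.3e} M/s")
print(f"amplitude:    {trace.a340[0] - trace.a340[-1]:.4f} AU")
print(f"rate shape:   {classify_rate_shape(traj)}")

# micellar assay: Dalziel analysis of three progression curves
truth = DalzielCoefficients.from_rate_constants(k1=9.6e4, k2_prime=4.0e3)
curves = [extract_velocity_curve(t) for t in
          generate_dalziel_dataset(truth, E=1e-8, duration=900, interval=0.5)]
coeffs = fit_dalziel(curves)
print(f"recovered k1 = {coeffs.k1:.3e} M^-1 s^-1, "
      f"k2' = {coeffs.k2_prime:.3e} M^-1 s^-1 (R^2 = {coeffs.r_squared:.6f})")
```

prints

```
initial rate: 9.179e-10 M/s
amplitude:    0.0124 AU
rate shape:   interior_maximum
recovered k1 = 9.600e+04 M^-1 s^-1, k2' = 4.000e+03 M^-1 s^-1 (R^2 = 1.000000)
```

The slow-docking wild-type parameters produce the tell-tale
`interior_maximum` rate shape (the velocity climbs while bound enzyme
accumulates, then decays with substrate); the Dalziel fit recovers the
generating apparent constants of the wild-type/H₂O₂ pair exactly from
the reconstructed velocity curves.

There is also a thin CLI over the same library:

```
gpx4kin generate --outdir traces --seed 1        # 4-fixture synthetic set
gpx4kin fit --indir traces --outdir fits --seed 1
gpx4kin dalziel --outdir dalziel
gpx4kin report --indir . --outdir report
```

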