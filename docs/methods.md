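# Methods

## Model and assumptions

The interfacial model couples a one-step docking equilibrium with the
two half-reactions of the peroxidase cycle on the membrane surface.
Its deliberate simplifications:

- **One global docking step.** SPR resolves binding into a fast
  low-affinity head-group contact followed by a conformational
  relaxation (k_a1, k_d1, k_a2, k_d2). Progression curves cannot
  separate those, so the model uses a single pair (k_A, k_B); under a
  stationary intermediate the two descriptions are related by
  k_A = k_a2/(k_d1/k_a1 + [M]) and k_B = k_d2 (`spr_to_onestep`). The
  typeset grouping of the k_A relation is ambiguous in the source
  material; the adopted reading reproduces the quoted ≈40 M⁻¹s⁻¹ for
  wild-type enzyme on cardiolipin bilayers.
- **Lumped reduction.** The two consecutive GSH reactions that
  re-reduce the selenenic acid are collapsed into one termolecular step,
  rate k_2s·[EoxM]·[GSH]²; k_2s therefore carries M⁻²s⁻¹ and maps to
  the micellar reductive constant only roughly, via k_2s = k'₂/[GSH].
- **Bulk-equivalent molarity.** Membrane-bound pools are expressed as
  bulk concentrations even though the chemistry is two-dimensional; all
  rate constants are effective constants at the stated lipid
  concentration.
- **[M] and [GSH] constant.** Phospholipid is a platform (0.4 mM total,
  counted irrespective of cardiolipin content); GSH is enzymatically
  regenerated in the assay, and each regenerated GSSG costs one NADPH,
  which is what A340 reports (ε = 6220 M⁻¹cm⁻¹, 1 cm path). A
  `gsh_constant=False` switch integrates GSH as a sixth state
  (dGSH/dt = −2·dGSSG/dt) for non-regenerating designs.
- **Cardiolipin is metadata.** Its mechanistic effect enters only
  through the fitted values of the four constants, not as a model term;
  the empirical dependence of fitted k_A on enzyme concentration
  (surface sensing / positive feedback) is *diagnosed*
  (`cooperativity_diagnostics`) but deliberately not modelled — that
  would require a density-dependent k_A(EM) or a stochastic surface
  model, both out of scope.
- **Only solution-phase reduced enzyme is a distinct pool** (E_sol ≡
  E_red): the oxidised enzyme is assumed not to dissociate, which is
  what lets slow docking throttle the whole cycle.

Exact structural identities, used as test invariants: enzyme
conservation (E_red + EM + EoxM = E_total), oxidising-equivalent
balance (ROOH₀ − SLPCOOH = GSSG + EoxM), monotone SLPCOOH/GSSG/A340.

## Parameters

| constant | meaning | units | typical liposome values |
|---|---|---|---|
| k_A | association to the membrane | M⁻¹s⁻¹ | ~1 (plain PC) to 20–110 (wt + cardiolipin) |
| k_B | dissociation of reduced bound enzyme | s⁻¹ | 5·10⁻² down to 3·10⁻³ (wt + cardiolipin) |
| k_1s | surface oxidative step | M⁻¹s⁻¹ | 10⁴–10⁶ |
| k_2s | lumped surface reduction | M⁻²s⁻¹ | 10⁵–10⁷ |

Slow docking relative to the surface cycle (k_A·M + k_B ≪ k_1s·ROOH,
k_2s·GSH²) yields a rate curve with an interior maximum — the
wild-type-on-cardiolipin signature; fast docking gives the monotone
decay of mutant-like traces. `classify_rate_shape` separates the two by
the rise time to 95% of the maximal d[GSSG]/dt (threshold 10 s —
robust against the flat-topped curves where an exact argmax drifts).

## Numerical choices

- **Simulation** (`simulate`): LSODA, rtol 1e-8, atol 1e-14 M, arbitrary
  sampling grids, standard initial condition E_red = E_total,
  SLPCOOH = ROOH₀, everything else zero. Verified against an
  independently coded fixed-step RK4 integrator (dt = 1 ms) to ≤1e-5
  relative on all pools.
- **Fit objective**: RMSD in absorbance units over the recorded grid
  (optionally after profiling out a constant baseline). Inside the
  optimiser the ODE is solved with BDF at rtol 1e-7/atol 1e-13:
  accuracy loss is ~1e-9 relative while avoiding LSODA stiffness-switch
  stalls in the extreme corners of the search box. Solver failures
  return a finite penalty (1e3 AU) so the population keeps evolving.
- **Search**: scipy differential evolution over log10 parameters
  (defaults popsize multiplier 15, ≤300 generations, tol 1e-8, seeded;
  bounds k_A ∈ [1e-2, 1e4], k_B ∈ [1e-5, 1], k_1s, k_2s ∈ [1e2, 1e9]).
  Long traces are decimated to ~240 points for the global stage only.
- **Polish**: the RMSD surface carries long, nearly flat valleys
  (k_B/k_1s/k_2s trade-offs at fixed steady-state flux), where a scalar
  finite-difference polish stalls ~10³ above the optimum. The package
  instead refines the best population members with trust-region least
  squares on the residual *vector*, using exact Jacobians from the
  forward sensitivity system (5 states × 4 parameters), restarted until
  converged. On noiseless traces this reaches the generating parameters
  to <0.1%.
- **Flags, not silent answers**: any parameter within 1% (log scale) of
  a bound is flagged; flat traces (amplitude <1e-6 AU) are returned
  unconverged.
- **Velocity extraction**: centred moving average (default 5 points;
  heavier smoothing recommended for noisy data) plus centred
  differences for v(t) = −Ȧ/(ε·ℓ); ROOH(t) is reconstructed from the
  *raw* absorbance drop to keep the concentration axis bias-free;
  points under 5% of ROOH₀ are dropped to bound 1/ROOH leverage.
- **Dalziel regression**: one multilinear fit of E/v on
  [1, 1/ROOH, 1/GSH] pooled across curves — equivalent to the classical
  two-stage reciprocal plots on clean data, better conditioned on noisy
  data — weighted by v⁴/E² because Var(E/v) ∝ (E/v²)²·Var(v). φ₀ can
  be pinned to 0 (selenoenzyme default), which also makes single-GSH
  designs identifiable.
- **Cooperativity diagnostics**: log–log slope of fitted k_A vs
  E_total with a seeded 999-permutation one-sided p-value and an
  effect-size floor of 0.05 decades/decade (per-fit numerical error can
  otherwise make a ~1e-4 trend "significant"; the real wild-type effect
  is ~0.5).

## What the synthetic generator does and does not emulate

It reproduces the assay's composition (0.4 mM phospholipid, 50 µM
SLPCOOH in-test, 2.5 mM GSH regenerated, 0.16 mM NADPH), enzyme ranges
(≈3×10⁻⁹–6.4×10⁻⁸ M), cardiolipin fractions {0, 3, 11, 20}%, the
NADPH-coupled optical readout, and additive Gaussian instrument noise
(default sd 5×10⁻⁴ AU, a typical spectrophotometer figure — the source
experiments do not state theirs; offset and linear drift optional).
Cooperative parameter schedules are explicit inputs, never inferred.

It does **not** emulate liposome polydispersity or light scattering,
mixing dead time, photobleaching, heteroscedastic shot noise, or any
mechanistic cardiolipin term. Passing recovery tests therefore shows
the pipeline is correct and well-conditioned for data of the stated
structure, not that real traces satisfy the model.

## Known limitations

- **Single-trace identifiability is marginal under noise.** With
  5×10⁻⁴ AU noise on a single 900 s / 1 Hz trace, the binding constants
  sit on a flat likelihood ridge: fits reach the noise floor with k_B
  anywhere over ~1 decade (linearised information analysis agrees).
  Noiseless recovery is exact, and k_A, k_1s, k_2s remain usable under
  noise, but per-trace k_B values from noisy data should be read as
  order-of-magnitude; the bound-hit/convergence flags expose the cases
  that are degenerate. Joint fitting across traces would fix this and
  is deliberately out of scope (the method fits each curve singly).
- The Dalziel module assumes the ping-pong law with no saturation term
  beyond φ₀; Michaelis–Menten-style models are out of scope.
- Problem sizes in the test suite (trace length 600–900 s at 1–3 s
  sampling, DE populations of 24–60) are chosen so the whole suite runs
  on one CPU in minutes; recovery tolerances are independent of these
  choices.
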