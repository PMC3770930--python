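# depspec — dual-cycle DEP collection-rate spectroscopy

`depspec` characterizes the dielectric properties of nanoparticles —
above all the particle conductivity σ_p — from pulsed dielectrophoretic
(DEP) collection kinetics. It is aimed at AC-electrokinetics labs and
modellers who measure fluorescence collection curves of nanospheres on
planar microelectrode arrays and want a systematic, least-squares route
from collection-rate ratios to σ_p, together with a simulator to design
the experiment and a Monte-Carlo framework to quantify how much better
rate-ratio estimation is than the classical crossover-frequency method.

## The model

The DEP force on a nanosphere of radius r in a medium of relative
permittivity ε_m is proportional to the real part of the Clausius–Mossotti
(CM) factor,

    F_DEP = π ε₀ ε_m r³ Re[CM](ω) ∇|E|²,
    CM(ω) = (ε_p* − ε_m*) / (ε_p* + 2 ε_m*),   ε* = ε ε₀ − j σ/ω.

For a single Maxwell–Wagner relaxation, Re[CM] moves monotonically between
a conductivity-governed low-frequency plateau A = (σ_p − σ_m)/(σ_p + 2σ_m)
and a permittivity-governed high-frequency plateau
B = (ε_p − ε_m)/(ε_p + 2ε_m), bounded in [−0.5, 1], crossing zero at the
crossover frequency f_x when A and B differ in sign. The particle
conductivity of a nanosphere is σ_p = σ_b + 2K_s/r with surface
conductance K_s.

In a **dual-cycle** experiment each period holds two on/off pulses: a
*control* collection at fixed carrier f₁ followed by a *probe* collection
at a switched carrier f₂. Initial collection rates are proportional to the
DEP force, so the probe/control initial-rate ratio

    ρ(f₂) = (dn/dt)₂ / (dn/dt)₁ = m · Re[CM](f₂; σ_p)

cancels shared experimental factors (local concentration, illumination,
camera gain) up to one scale m. Fitting the two parameters (σ_p, m) to
ratios collected over several probe frequencies is a two-step procedure:
a line of best fit of ρ on log₁₀ f extrapolates the crossover
(f_x0 = 10^(−α/β)) which inverts to an initial σ₀, then Newton–Raphson on
σ (analytic SSE derivatives through the Debye form of Re[CM]) alternates
with the closed-form least-squares update of m until convergence.

The package also simulates the full dual-cycle number/fluorescence
dynamics (exponential-series modes with states carried across phase
boundaries, closed-form cyclic steady state, AM bandwidth), provides a 1D
drift-diffusion (Fokker–Planck) oracle with reflecting walls validating
those kinetics against the Boltzmann steady state, and runs the
Monte-Carlo comparison between the rate-ratio estimator (36 samples) and
the crossover estimator (4 samples).

## Worked example

Generate a synthetic experiment (seven probe frequencies between 1 and
4 MHz, five dual cycles of 15 s on / 10 s off per cycle, a 26 mS/m
particle in a 2 mS/m medium, 15% cycle-to-cycle conductivity noise),
extract rate ratios and fit:

```sh
depspec fixture --seed 7 --outdir demo
depspec extract-rates --trace demo/trace_00.csv:1e6 ... --out demo/ratios.csv
depspec fit-cm --ratios demo/ratios.csv --sigma-m 0.002 --eps-p 2.55 --eps-m 78
```

which prints

```json
{
  "sigma_p": 0.025213523789577877,
  "scale_m": 1.4734020704278838,
  "sigma_0": 0.028068620327020424,
  "m_0": 0.9764567173557939,
  "iterations": 13,
  "sse": 0.11121110221250301,
  "converged": true,
  "crossover_estimate": 4279777.236458003,
  "n_samples": 28
}
```

`sigma_p` is the fitted particle conductivity in S/m — 25.2 mS/m here,
within 3% of the generating 26 mS/m; `sigma_0` is the line-fit
initialization (28.1 mS/m), `scale_m` the CM scaling factor, and
`crossover_estimate` the crossover frequency implied by the fit
(4.28 MHz, against 4.41 MHz for the true parameters). The estimator
comparison:

```sh
depspec montecarlo --trials 200 --seed 1 --out mc.json
# variance_ratio=3.903 (rate mean 25.71 mS/m, crossover mean 26.02 mS/m)
```

Both estimators are unbiased at 15% conductivity noise, but the crossover
method's variance is near fourfold larger — less than the ninefold
sample-count ratio because Re[CM] responds nonlinearly to conductivity
noise.

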