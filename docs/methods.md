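# Methods

## Dielectric model

A homogeneous sphere in a conductive medium has one Maxwell–Wagner
interfacial relaxation; the real part of its Clausius–Mossotti factor is
evaluated from the full complex quotient and, equivalently, admits the
exact Debye decomposition

    Re[CM](ω) = B + (A − B) / (1 + ω²τ²),
    τ = ε₀ (ε_p + 2ε_m) / (σ_p + 2σ_m),

with plateaus A = (σ_p − σ_m)/(σ_p + 2σ_m) and
B = (ε_p − ε_m)/(ε_p + 2ε_m). All closed forms built on this
decomposition — the crossover frequency, its inversion to σ_p, the
log-frequency gradient at the crossover ln(10)·2AB/(A − B), and the
three-line piecewise approximation — are enforced in tests against
independent numerics (bisection roots, central differences, a sympy
reference for the fit derivatives) rather than trusted as algebra.
Degenerate inputs: σ_p = σ_m = 0 defines the low plateau as 0 by
continuity; absence of a crossover is a typed `None`, not an exception,
because Monte-Carlo draws legitimately produce such parameter sets.
Permittivities are relative everywhere; ε₀ is applied internally.

## Dual-cycle kinetics

Collection and release are modelled as a per-mode linear state-space
system: mode i relaxes exponentially toward its phase target (weight
a_i times the cycle transition Δñ_l during collection, the baseline
during release) and the mode states are carried across phase boundaries.
This makes the profile continuous by construction, exactly solvable for
the cyclic steady state (the per-period map is affine per mode; its fixed
point is computed in closed form), and exactly time-rescaling invariant.
Defaults: two modes, weights (0.7, 0.3), collection and release time
constants (3 s, 20 s) — seconds-scale dynamics consistent with 15 s-on
protocols reaching quasi-steady collection; 15 s on / 10 s off per cycle
(60% duty, 20 mHz modulation), control carrier 1 MHz. Cycle timing is
noted to be reported inconsistently across sources for this protocol
(7 s vs 15 s on); the 15 s/10 s variant is self-consistent with the
20 mHz / 60% figures and is the default.

The fluorescence map is affine with a smooth soft limit,
F = k_fc + S·tanh(k_f·n/S), S = saturation − k_fc: linear at small n,
bounded, monotone. The AM bandwidth uses cutoff ε = 0.1 of the
ultralow-modulation amplitude by default and is found by bisection on
log f_m, asserting amplitude monotonicity along the way.

## Drift-diffusion oracle

A 1D finite-volume Fokker–Planck solver on a slab with reflecting walls
validates the exponential-series kinetics: constant downward force during
"on" phases, Scharfetter–Gummel (exponentially fitted) interface fluxes so
the discrete steady state is exactly the Boltzmann profile and particle
number is conserved to round-off, implicit Euler stepping (banded solves).
The constant-force slab is a validation device, not a field model: the
real DEP force decays away from the electrode plane. Collection
transients from the solver are well fit (R² > 0.99) by a two-mode
exponential series, which is the justification for the kinetic model's
form. Units are free (only force·h/kT and kT/drag enter); tests use
nondimensional parameters.

## Rate extraction

Initial rates are ordinary least-squares slopes over the first 13 samples
of each collection window (10 samples/s by default; the window length is a
flag). On the default kinetics this finite window sits ≈17% below the
t = 0 derivative — a curvature bias that is *shape-dependent but cancels
exactly in the probe/control ratio* when both cycles share kinetics,
which is the method's core rationale; the ratio is likewise invariant to
gain and additive background. One ratio is extracted per dual cycle, the
transient first dual cycle excluded by default (four cyclic-steady-state
replicates per recording); per-recording averaging is a flag.

A caveat the synthetic generator makes visible: with a 20 s release mode
and only 10 s off-phases, release is incomplete, so at cyclic steady
state each collection starts from a residual mode state and the measured
ρ is biased low, most visibly where Re[CM] is small (absolute offsets up
to ~0.06 near the crossover; net σ̂ bias ≈6.5% under noiseless default
conditions). This is a genuine feature of the emulated protocol, kept in
the default study conditions; exact ratio identity (tested to 1e-6) holds
when the off-phases are long enough for complete release and the
fluorescence map is in its linear regime.

## Two-step bivariate fit

The model is ρ = m·Re[CM](f; σ_p) with the offset fixed at zero, since a
vanishing rate ratio at the crossover is a verified property of the ratio
method; this makes the scale update a one-parameter least-squares closed
form m = Σρg/Σg². Initialization: OLS line of ρ on log₁₀ f over a window
where the ratios fall steeply (default 1–4 MHz for experiment-shaped
data, 1–10 MHz for the Monte-Carlo grid); its zero crossing
10^(−α/β) inverts to σ₀; m₀ is the mean control-frequency ratio divided
by the model value there (control points = samples within 10% of the
control frequency in log f). Refinement: Newton–Raphson on σ with
analytic first/second SSE derivatives through the Debye form, safeguarded
by step-halving whenever the SSE would rise, alternated with the closed
form for m, until |Δσ| ≤ 0.01 mS/m (default) or the iteration budget; a
Nelder–Mead fallback handles curvature failure and is reported in the
diagnostics. The final estimate is insensitive to m₀ (tested), so the
initializer reconstruction risk is contained. An alternative
"gradient-method" initializer (equating the line slope with the
piecewise-diagonal gradient) is implemented but marked experimental and
excluded from defaults: its historical worked value could not be
reproduced from any faithful reconstruction.

## Monte-Carlo estimator comparison

Per trial: conductivities are drawn with multiplicative Gaussian noise
σ_i = σ_true(1 + 0.15·z_i) (equivalent to randomizing surface conductance
at σ_b ≈ 0; negative draws are truncated with a logged count), rate
ratios ρ_i = m·Re[CM](f_i; σ_i) are simulated at 9 log-spaced frequencies
× 4 replicates (36 samples) with m the reciprocal RMS of the noisy
Re[CM] values, and σ_p is estimated twice — by the full two-step fit, and
from 4 noisy crossover observations by inverting the mean crossover
frequency (the least-SSE solution for one shared σ_p at a single medium
conductivity; averaging per-sample inversions is a flag and changes the
variance ratio by <1%).

The frequency grid runs from the 1 MHz control carrier to the 100 MHz
high-frequency plateau, so its first point doubles as the control group
required by the scale initializer and matches the instrument's probe
floor. The resulting crossover/collection variance ratio is sensitive to
these endpoints (grids extending a decade below the control push it down
toward ~2.3; grids stopping at 10 MHz push it up toward ~5.8); at the
frozen design its population value is ≈3.6 (measured once at 20000
trials), with 200-trial studies scattering roughly between 3 and 4.5.
Under this grid the generating scale factor is m̄ ≈ 2.24. Both arms are
unbiased to within sampling error; the ratio stays well below the
ninefold sample-count (CLT) bound because the high-frequency samples are
permittivity-dominated and carry almost no conductivity information.

## Problem sizes

Defaults keep everything desk-scale: traces at 10 samples/s over five
50 s dual cycles (≈2500 samples), 200-trial Monte-Carlo studies in a few
tens of milliseconds each, the acceptance report pooling ten 1000-trial
blocks in well under a minute, and the drift-diffusion oracle on a
150–200 cell grid.

## Known limitations

Single-shell spheres with one dispersion only (no multi-crossover cell
spectra, no electrode-polarization correction); positive-DEP control and
probe only; the constant-force slab oracle does not model the spatial
decay of the real DEP force or electrohydrodynamic flows; the synthetic
fluorescence generator emulates shot-to-shot conductivity noise, camera
noise and soft saturation but not background drift, bleaching, or
particle–particle interactions at high concentration — passing recovery
tests therefore demonstrates correctness of the estimation chain under
the stated noise model, not robustness to every artifact of real video
data.
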