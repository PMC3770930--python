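"""Dual-cycle pulsed-DEP collection/release dynamics.

A dual cycle is two consecutive on/off pulses of the DEP field: the first
("control") cycle at a fixed carrier frequency f1, the second ("probe") at a
switched frequency f2.  While the field is on, particles collect near the
electrode edges; while it is off they diffuse back into the bulk.  The
particle number in the capture volume is modelled as a sum of first-order
modes: during a collection phase of cycle l, mode i relaxes exponentially
toward a_i * dn_l with time constant tau_i^c, and during release back toward
the baseline with tau_i^r.  Mode states are carried across phase boundaries,
so the profile is continuous and settles into a cyclic steady state (cSS)
whose per-mode initial condition is the fixed point of an affine map, solved
here in closed form.

A 1D drift-diffusion (Fokker-Planck) finite-volume solver for the particle
concentration in a slab with reflecting walls serves as an independent
oracle for the exponential-series kinetics and the Boltzmann steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.constants import epsilon_0 as EPS0
from scipy.linalg import solve_banded

from .exceptions import ConvergenceError

__all__ = [
    "CycleSpec",
    "KineticModel",
    "FluorescenceMap",
    "Trace",
    "DiffusionSpec",
    "duty_cycle",
    "modulation_frequency",
    "switch_envelope",
    "default_kinetics",
    "simulate_number",
    "css_state",
    "cycle_amplitude",
    "detect_css",
    "am_bandwidth",
    "fluorescence_from_number",
    "dep_force_scale",
    "simulate_mde_1d",
    "boltzmann_steady_number",
]


def duty_cycle(t_on: float, t_off: float) -> float:
    """Fraction of a cycle during which the DEP field is on."""
    period = t_on + t_off
    if period <= 0:
        raise ValueError("cycle period must be positive")
    if t_on < 0 or t_off < 0:
        raise ValueError("durations must be non-negative")
    return t_on / period


@dataclass(frozen=True)
class CycleSpec:
    """Dual-cycle timing (s), carrier frequencies (Hz) and drive amplitude (V)."""

    t_on_1: float
    t_off_1: float
    t_on_2: float
    t_off_2: float
    f1: float = 1e6
    f2: float = 1e6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for d in (self.t_on_1, self.t_off_1, self.t_on_2, self.t_off_2):
            if d < 0:
                raise ValueError("durations must be non-negative")
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("each cycle period must be positive")
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("carrier frequencies must be positive")

    @property
    def T1(self) -> float:
        return self.t_on_1 + self.t_off_1

    @property
    def T2(self) -> float:
        return self.t_on_2 + self.t_off_2

    @property
    def T(self) -> float:
        return self.T1 + self.T2

    @property
    def eta1(self) -> float:
        return duty_cycle(self.t_on_1, self.t_off_1)

    @property
    def eta2(self) -> float:
        return duty_cycle(self.t_on_2, self.t_off_2)

    def scaled(self, factor: float) -> "CycleSpec":
        """All durations multiplied by ``factor`` (duty ratios preserved)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, t_on_1=self.t_on_1 * factor,
                       t_off_1=self.t_off_1 * factor,
                       t_on_2=self.t_on_2 * factor,
                       t_off_2=self.t_off_2 * factor)


def modulation_frequency(spec: CycleSpec) -> float:
    """f_m = 1/(T1 + T2), the reciprocal of the dual-cycle period."""
    return 1.0 / spec.T


def switch_envelope(t, spec: CycleSpec):
    """Phase label at time(s) t: ``cycle1_on``, ``cycle2_on`` or ``off``.

    Times are wrapped modulo the dual-cycle period; switch-on occurs at the
    start of each cycle.
    """
    t = np.asarray(t, dtype=float)
    tm = np.mod(t, spec.T)
    out = np.full(tm.shape, "off", dtype=object)
    out[tm < spec.t_on_1] = "cycle1_on"
    out[(tm >= spec.T1) & (tm < spec.T1 + spec.t_on_2)] = "cycle2_on"
    return str(out[()]) if out.ndim == 0 else out


@dataclass(frozen=True)
class KineticModel:
    """Exponential-series collection/release kinetics.

    ``dn1``/``dn2`` are the initial-to-collection-steady-state transitions of
    the two cycles (arbitrary, possibly normalized, particle-number units);
    ``weights_c``/``weights_r`` are the per-mode weights (non-negative, sum
    to 1 per phase) and ``tau_c``/``tau_r`` the collection/release time
    constants (s).
    """

    dn1: float
    dn2: float
    weights_c: tuple
    weights_r: tuple
    tau_c: tuple
    tau_r: tuple

    def __post_init__(self) -> None:
        n = len(self.weights_c)
        if not (len(self.weights_r) == len(self.tau_c) == len(self.tau_r) == n):
            raise ValueError("mode lists must have equal length")
        for w in (self.weights_c, self.weights_r):
            if any(x < 0 for x in w):
                raise ValueError("weights must be non-negative")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1 per phase")
        for taus in (self.tau_c, self.tau_r):
            if any(tau <= 0 for tau in taus):
                raise ValueError("time constants must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.weights_c)

    @property
    def min_tau(self) -> float:
        return min(min(self.tau_c), min(self.tau_r))

    @property
    def max_tau(self) -> float:
        return max(max(self.tau_c), max(self.tau_r))

    def rescaled_time(self, factor: float) -> "KineticModel":
        return replace(self, tau_c=tuple(t * factor for t in self.tau_c),
                       tau_r=tuple(t * factor for t in self.tau_r))


def default_kinetics(dn1: float = 1.0, dn2: float = 0.3) -> KineticModel:
    """Two-mode seconds-scale kinetics typical of submicron nanospheres."""
    return KineticModel(dn1=dn1, dn2=dn2,
                        weights_c=(0.7, 0.3), weights_r=(0.7, 0.3),
                        tau_c=(3.0, 20.0), tau_r=(3.0, 20.0))


@dataclass(frozen=True)
class FluorescenceMap:
    """Affine fluorescence-per-particle map with a smooth soft limit.

    F = k_fc + S*tanh(k_f*n/S), S = saturation - k_fc: linear with gradient
    k_f and intercept k_fc at small n, bounded by ``saturation``.
    """

    k_f: float
    k_fc: float = 0.0
    saturation: float = math.inf

    def __post_init__(self) -> None:
        if self.k_f <= 0:
            raise ValueError("k_f must be positive")
        if self.saturation <= self.k_fc:
            raise ValueError("saturation must exceed the intercept")

    def __call__(self, n):
        n = np.asarray(n, dtype=float)
        span = self.saturation - self.k_fc
        if math.isinf(span):
            out = self.k_fc + self.k_f * n
        else:
            out = self.k_fc + span * np.tanh(self.k_f * n / span)
        return float(out) if out.ndim == 0 else out


@dataclass
class Trace:
    """Uniformly sampled time series of particle number or fluorescence."""

    times: np.ndarray
    values: np.ndarray
    spec: CycleSpec | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def _phase_table(spec: CycleSpec, kin: KineticModel, dn1: float, dn2: float):
    """(duration, per-mode target, per-mode tau) for the four phases of one dual cycle."""
    w_c = np.asarray(kin.weights_c, dtype=float)
    tau_c = np.asarray(kin.tau_c, dtype=float)
    tau_r = np.asarray(kin.tau_r, dtype=float)
    zero = np.zeros(kin.n_modes)
    return [
        (spec.t_on_1, w_c * dn1, tau_c),
        (spec.t_off_1, zero, tau_r),
        (spec.t_on_2, w_c * dn2, tau_c),
        (spec.t_off_2, zero, tau_r),
    ]


def simulate_number(spec: CycleSpec, kin: KineticModel, n_cycles: int,
                    dt: float, ic: np.ndarray | None = None,
                    dn_schedule: Sequence[tuple[float, float]] | None = None,
                    baseline: float = 0.0) -> Trace:
    """Simulate the dual-cycle particle-number profile on a uniform grid.

    Per-mode states are propagated exactly (analytic exponential relaxation
    within each phase, states carried across phase boundaries), so the
    profile is continuous and independent of grid alignment.  ``dn_schedule``
    optionally overrides (dn1, dn2) per dual cycle, which lets the fixture
    generator inject cycle-to-cycle conductivity noise.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if dt > kin.min_tau / 10.0:
        raise ValueError(
            f"dt={dt} too coarse: must be <= min(tau)/10 = {kin.min_tau / 10.0}")
    if dn_schedule is not None and len(dn_schedule) < n_cycles:
        raise ValueError("dn_schedule shorter than n_cycles")

    times = np.arange(round(n_cycles * spec.T / dt) + 1) * dt
    values = np.empty_like(times)
    x = np.zeros(kin.n_modes) if ic is None else np.asarray(ic, dtype=float).copy()

    t0 = 0.0
    idx = 0
    for j in range(n_cycles):
        dn1, dn2 = (kin.dn1, kin.dn2) if dn_schedule is None else dn_schedule[j]
        for dur, target, tau in _phase_table(spec, kin, dn1, dn2):
            t1 = t0 + dur
            # grid points in [t0, t1); the final sample is handled after the loop
            stop = idx
            while stop < len(times) and times[stop] < t1 - 1e-9 * dt:
                stop += 1
            if stop > idx:
                tt = times[idx:stop, None] - t0
                xs = target[None, :] + (x - target)[None, :] * np.exp(-tt / tau[None, :])
                values[idx:stop] = baseline + xs.sum(axis=1)
                idx = stop
            x = target + (x - target) * np.exp(-dur / tau)
            t0 = t1
    values[idx:] = baseline + x.sum()  # final grid point at t = n_cycles*T
    return Trace(times, values, spec)


def css_state(spec: CycleSpec, kin: KineticModel) -> np.ndarray:
    """Per-mode state at a dual-cycle start in cyclic steady state.

    Each mode evolves through one period by a composition of affine maps
    x -> a x + b; the cSS initial condition is the fixed point b/(1 - a),
    which exists and is unique since 0 < a < 1.
    """
    a = np.ones(kin.n_modes)
    b = np.zeros(kin.n_modes)
    for dur, target, tau in _phase_table(spec, kin, kin.dn1, kin.dn2):
        decay = np.exp(-dur / tau)
        b = target * (1.0 - decay) + decay * b
        a = decay * a
    return b / (1.0 - a)


def _cycle_span(spec: CycleSpec, cycle_index: int, which: int) -> tuple[float, float]:
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    start = cycle_index * spec.T + (0.0 if which == 1 else spec.T1)
    return start, start + (spec.T1 if which == 1 else spec.T2)


def cycle_amplitude(trace: Trace, cycle_index: int, which: int) -> float:
    """max - min of the trace over the designated cycle of dual cycle ``cycle_index``."""
    spec = trace.spec
    if spec is None:
        raise ValueError("trace carries no CycleSpec")
    t_start, t_end = _cycle_span(spec, cycle_index, which)
    eps = 0.5 * trace.dt
    if t_end > trace.times[-1] + eps:
        raise ValueError("trace does not cover the requested cycle")
    mask = (trace.times >= t_start - eps) & (trace.times <= t_end + eps)
    window = trace.values[mask]
    return float(window.max() - window.min())


def detect_css(trace: Trace, spec: CycleSpec, tol: float = 1e-3) -> int:
    """First dual-cycle index at cyclic steady state.

    Compares the particle number at successive dual-cycle boundaries against
    ``tol`` times the dual-cycle amplitude; raises ConvergenceError if the
    trace never settles.
    """
    dt = trace.dt
    per = round(spec.T / dt)
    n_full = (len(trace) - 1) // per
    if n_full < 2:
        raise ValueError("need at least two full dual cycles")
    for j in range(n_full - 1):
        n_j = trace.values[j * per]
        n_next = trace.values[(j + 1) * per]
        window = trace.values[j * per:(j + 1) * per + 1]
        amp = window.max() - window.min()
        if abs(n_next - n_j) <= tol * amp:
            return j
    raise ConvergenceError("trace did not reach cyclic steady state")


def _css_amplitude(spec: CycleSpec, kin: KineticModel, which: int) -> float:
    x0 = css_state(spec, kin)
    dt = min(kin.min_tau / 10.0, spec.T / 400.0)
    trace = simulate_number(spec, kin, 1, dt, ic=x0)
    return cycle_amplitude(trace, 0, which)


def am_bandwidth(kin: KineticModel, spec_template: CycleSpec,
                 cutoff: float = 0.1, which: int = 1,
                 rel_tol: float = 1e-3) -> float:
    """Modulation-frequency bandwidth of the cyclic collection amplitude.

    Largest f_m at which the cSS amplitude of cycle ``which`` still reaches
    ``cutoff`` times its ultralow-f_m value (the full transition dn_l),
    found by bisection on log f_m.  The amplitude is monotone non-increasing
    in f_m for this linear model; a detected violation raises
    ConvergenceError as a diagnostic.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    amp_ul = abs(kin.dn1 if which == 1 else kin.dn2)
    target = cutoff * amp_ul

    def amp_at(f_m: float) -> float:
        return _css_amplitude(spec_template.scaled(1.0 / (f_m * spec_template.T)), kin, which)

    # bracket: start slow enough for full relaxation, double until below cutoff
    f_lo = 1.0 / (100.0 * kin.max_tau)
    a_prev = amp_at(f_lo)
    if a_prev < target:
        raise ConvergenceError("amplitude below cutoff already at ultralow f_m")
    f_hi = f_lo
    for _ in range(64):
        f_hi *= 2.0
        a = amp_at(f_hi)
        if a > a_prev * (1.0 + 1e-6):
            raise ConvergenceError("amplitude not monotone in f_m")
        a_prev = a
        if a < target:
            break
    else:
        raise ConvergenceError("failed to bracket the bandwidth")
    while f_hi / f_lo > 1.0 + rel_tol:
        mid = math.sqrt(f_lo * f_hi)
        if amp_at(mid) >= target:
            f_lo = mid
        else:
            f_hi = mid
    return math.sqrt(f_lo * f_hi)


def fluorescence_from_number(trace: Trace, fmap: FluorescenceMap) -> Trace:
    """Map a particle-number trace to fluorescence through ``fmap``."""
    return Trace(trace.times.copy(), fmap(trace.values), trace.spec)


def dep_force_scale(radius: float, eps_m: float, re_cm_value: float,
                    grad_e2: float) -> float:
    """Time-averaged DEP force magnitude on a nanosphere (N).

    F = pi * eps0 * eps_m * r^3 * Re[CM] * grad|E|^2, the time-average
    convention for a peak-amplitude field.  Only relative magnitudes matter
    downstream: the ratio of forces at two frequencies is the ratio of
    Re[CM] values.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return math.pi * EPS0 * eps_m * radius**3 * re_cm_value * grad_e2


@dataclass(frozen=True)
class DiffusionSpec:
    """1D slab for the drift-diffusion oracle.

    Chamber height h (m), constant downward DEP force during "on" phases
    (N), thermal energy kT (J), drag coefficient (N s/m), capture height y*
    defining the counting volume, and grid resolution.  Units may be SI or
    nondimensional; only the ratios force*h/kT and kT/(drag) enter.
    """

    height: float
    force: float
    kT: float
    drag: float
    capture_height: float
    n_grid: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.capture_height < self.height:
            raise ValueError("capture_height must lie inside (0, height)")
        if self.kT <= 0 or self.drag <= 0:
            raise ValueError("kT and drag must be positive")
        if self.n_grid < 10:
            raise ValueError("n_grid too small")


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x/(e^x - 1), the Scharfetter-Gummel weighting; B(0) = 1."""
    small = np.abs(x) < 1e-10
    return np.where(small, 1.0 - 0.5 * x, x / np.expm1(np.where(small, 1.0, x)))


def _fp_banded(n: int, dy: float, d_coef: float, v: float, dt: float) -> np.ndarray:
    """Banded (I - dt*M) for implicit Euler of the finite-volume Fokker-Planck.

    Interface fluxes use exponential (Scharfetter-Gummel) fitting, so the
    discrete steady state is exactly the Boltzmann profile and zero-flux
    walls conserve the total number to round-off.
    """
    p = v * dy / d_coef
    b_minus = float(_bernoulli(np.array(-p)))   # multiplies the lower cell
    b_plus = float(_bernoulli(np.array(p)))     # multiplies the upper cell
    c = d_coef / dy**2
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    # interface k between cells k-1 and k: J_k = c*dy*(B(-p) c_{k-1} - B(p) c_k)
    diag[:-1] += c * b_minus   # outflow from cell k-1 through interface k
    upper[1:] -= c * b_plus    # inflow to cell k-1 from cell k
    diag[1:] += c * b_plus     # outflow (backwards) from cell k
    lower[:-1] -= c * b_minus  # inflow to cell k from cell k-1
    ab = np.zeros((3, n))
    ab[0, :] = dt * upper
    ab[1, :] = 1.0 + dt * diag
    ab[2, :] = dt * lower
    return ab


def simulate_mde_1d(diff: DiffusionSpec, spec: CycleSpec, duration: float,
                    dt: float | None = None, total_number: float = 1.0
                    ) -> tuple[Trace, tuple[np.ndarray, np.ndarray]]:
    """Drift-diffusion oracle: capture-volume number trace and final profile.

    Reflecting (zero-flux) boundaries at y = 0 and y = h; "on" phases apply
    a constant downward drift v = force/drag.  Returns the number of
    particles below ``capture_height`` over time and the final
    concentration profile (cell centers, concentration).
    """
    n = diff.n_grid
    dy = diff.height / n
    d_coef = diff.kT / diff.drag
    if dt is None:
        dt = duration / 2000.0
    v_on = -diff.force / diff.drag  # downward drift toward y = 0
    ab_on = _fp_banded(n, dy, d_coef, v_on, dt)
    ab_off = _fp_banded(n, dy, d_coef, 0.0, dt)

    centers = (np.arange(n) + 0.5) * dy
    capture = centers < diff.capture_height
    c = np.full(n, total_number / diff.height)

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    numbers = np.empty(n_steps + 1)
    numbers[0] = c[capture].sum() * dy
    for k in range(n_steps):
        phase = switch_envelope(times[k], spec)
        ab = ab_off if phase == "off" else ab_on
        c = solve_banded((1, 1), ab, c)
        if not np.all(np.isfinite(c)):
            raise ConvergenceError("drift-diffusion step became unstable")
        numbers[k + 1] = c[capture].sum() * dy
    return Trace(times, numbers, spec), (centers, c)


def boltzmann_steady_number(diff: DiffusionSpec, total_number: float = 1.0) -> float:
    """Capture-volume number at the Boltzmann (collection steady) state.

    Closed form: total * (1 - exp(-F y*/kT)) / (1 - exp(-F h/kT)); reduces
    to the volume fraction y*/h at zero force and to the whole population
    when F h >> kT.
    """
    phi = diff.force / diff.kT
    if phi == 0.0:
        return total_number * diff.capture_height / diff.height
    return total_number * math.expm1(-phi * diff.capture_height) / math.expm1(-phi * diff.height)
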