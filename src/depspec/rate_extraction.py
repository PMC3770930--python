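"""Initial collection rates and control/probe rate ratios.

The initial slope of the particle-number (or fluorescence) trace just after
DEP switch-on is approximately proportional to the DEP force, hence to
Re[CM] at the carrier frequency.  The ratio rho of the probe-cycle slope to
the control-cycle slope cancels every shared experimental factor — local
concentration, illumination, camera gain, fluorescence offset — which is
the point of the dual-cycle design.  Slopes are ordinary least-squares fits
over the first few samples of each collection window (13 points by
default, a robust compromise at typical 10 frames/s sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dualcycle import CycleSpec, Trace
from .exceptions import InsufficientDataError

__all__ = [
    "RateEstimate",
    "RateRatioSample",
    "segment_collection_windows",
    "initial_rate",
    "rate_ratio",
    "extract_dataset",
]

DEFAULT_FIT_POINTS = 13


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of a collection window (value per second)."""

    slope: float
    intercept: float
    n_points: int
    residual_sd: float
    cycle_index: int = 0
    which_cycle: int = 1


@dataclass(frozen=True)
class RateRatioSample:
    """One probe/control rate ratio at a probe carrier frequency."""

    frequency: float
    replicate: int
    rho: float
    control_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not np.isfinite(self.rho):
            raise ValueError("rho must be finite")


def segment_collection_windows(trace: Trace, spec: CycleSpec, n_cycles: int
                               ) -> list[tuple[int, int, slice]]:
    """Index windows of the collection (switch-on) phases.

    Returns (dual-cycle index, which cycle, sample slice) for each of the
    2*n_cycles collection phases, each window starting at the switch-on
    sample and spanning the on-phase.
    """
    dt = trace.dt
    out = []
    for j in range(n_cycles):
        for which, t_start, t_on in ((1, j * spec.T, spec.t_on_1),
                                     (2, j * spec.T + spec.T1, spec.t_on_2)):
            i0 = round(t_start / dt)
            n_samp = round(t_on / dt)
            if i0 + n_samp > len(trace):
                raise ValueError("trace shorter than the requested cycle schedule")
            out.append((j, which, slice(i0, i0 + n_samp)))
    return out


def initial_rate(values: np.ndarray, dt: float,
                 n_points: int = DEFAULT_FIT_POINTS,
                 cycle_index: int = 0, which_cycle: int = 1) -> RateEstimate:
    """OLS slope over the first ``n_points`` samples, in per-second units."""
    values = np.asarray(values, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(values) < n_points:
        raise InsufficientDataError(
            f"window has {len(values)} samples, need {n_points}")
    t = np.arange(n_points) * dt
    y = values[:n_points]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    dof = max(n_points - 2, 1)
    return RateEstimate(slope=float(slope), intercept=float(intercept),
                        n_points=n_points,
                        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
                        cycle_index=cycle_index, which_cycle=which_cycle)


def rate_ratio(probe: RateEstimate, control: RateEstimate) -> float:
    """rho = probe.slope / control.slope; signs propagate unmodified."""
    scale = max(abs(probe.slope), 1.0)
    if abs(control.slope) < 1e3 * np.finfo(float).eps * scale:
        raise ZeroDivisionError("control slope too close to zero for a ratio")
    return probe.slope / control.slope


def extract_dataset(traces, spec: CycleSpec, css_only: bool = True,
                    n_points: int = DEFAULT_FIT_POINTS,
                    average_cycles: bool = False) -> list[RateRatioSample]:
    """Rate-ratio samples from a batch of dual-cycle traces.

    ``traces`` is an iterable of (Trace, probe frequency).  With
    ``css_only`` the transient first dual cycle of each trace is excluded,
    leaving one rho per cyclic-steady-state dual cycle; replicate indices
    are assigned per frequency in input order.  ``average_cycles`` instead
    collapses each trace to a single rho (mean over retained cycles).
    """
    counters: dict[float, int] = {}
    samples: list[RateRatioSample] = []
    for trace, freq in traces:
        dt = trace.dt
        n_cycles = int((trace.times[-1] + 0.5 * dt) / spec.T)
        first = 1 if css_only else 0
        if n_cycles <= first:
            raise InsufficientDataError(
                "trace too short for the requested cycle selection")
        windows = segment_collection_windows(trace, spec, n_cycles)
        per_cycle = {}
        for j, which, sl in windows:
            if j < first:
                continue
            per_cycle.setdefault(j, {})[which] = initial_rate(
                trace.values[sl], dt, n_points, cycle_index=j, which_cycle=which)
        rhos = [rate_ratio(cyc[2], cyc[1]) for _, cyc in sorted(per_cycle.items())]
        if average_cycles:
            rhos = [float(np.mean(rhos))]
        for rho in rhos:
            k = counters.get(freq, 0)
            counters[freq] = k + 1
            samples.append(RateRatioSample(frequency=freq, replicate=k,
                                           rho=rho, control_frequency=spec.f1))
    return samples
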