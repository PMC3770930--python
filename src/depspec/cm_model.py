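"""Clausius–Mossotti (CM) spectrum of a homogeneous dielectric sphere.

The real part of the CM factor,

    Re[CM](omega) = Re[(eps_p* - eps_m*) / (eps_p* + 2 eps_m*)],
    eps* = eps_r * eps_0 - j * sigma / omega,

sets the sign and magnitude of the dielectrophoretic (DEP) force on a
nanosphere suspended in an aqueous medium.  For a single Maxwell–Wagner
interfacial relaxation Re[CM] moves monotonically between a low-frequency
plateau A = (sigma_p - sigma_m)/(sigma_p + 2 sigma_m) governed by the
conductivities and a high-frequency plateau B = (eps_p - eps_m)/
(eps_p + 2 eps_m) governed by the permittivities, and is bounded in
[-0.5, 1].  When A and B differ in sign the spectrum crosses zero at the
crossover frequency f_x (pDEP <-> nDEP transition); inverting that relation
yields the particle conductivity from a measured crossover.

All permittivities in this module are *relative*; the vacuum permittivity
is applied internally.  Conductivities are in S/m, frequencies in Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import epsilon_0 as EPS0

from .exceptions import NoCrossoverError

__all__ = [
    "DielectricParams",
    "ParticleProps",
    "PiecewiseCM",
    "re_cm",
    "crossover_frequency",
    "sigma_p_from_crossover",
    "cm_limits",
    "crossover_gradient",
    "piecewise_linear_cm",
    "maxwell_wagner_time",
    "particle_conductivity",
    "surface_conductance",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class DielectricParams:
    """Conductivities (S/m) and relative permittivities of particle and medium."""

    sigma_p: float
    sigma_m: float
    eps_p: float
    eps_m: float

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_m < 0:
            raise ValueError("conductivities must be non-negative")
        if self.eps_p <= 0 or self.eps_m <= 0:
            raise ValueError("relative permittivities must be positive")

    def with_sigma_p(self, sigma_p: float) -> "DielectricParams":
        """Copy with the particle conductivity replaced (used by the fitter)."""
        return replace(self, sigma_p=sigma_p)


@dataclass(frozen=True)
class ParticleProps:
    """Nanosphere radius (m), bulk conductivity (S/m), surface conductance (S)."""

    radius: float
    sigma_b: float = 0.0
    K_s: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.sigma_b < 0 or self.K_s < 0:
            raise ValueError("sigma_b and K_s must be non-negative")


@dataclass(frozen=True)
class PiecewiseCM:
    """Three-line (log-frequency) approximation of Re[CM].

    Two horizontal plateaus joined by the tangent ("diagonal") at the
    crossover.  When no crossover exists the degenerate two-plateau form is
    returned, with both breakpoints at the Maxwell–Wagner relaxation
    frequency and no diagonal.
    """

    low_limit: float
    high_limit: float
    crossover_freq: float | None
    gradient_at_crossover: float | None
    breakpoint_low: float
    breakpoint_high: float

    def evaluate(self, f):
        """Evaluate the piecewise-linear approximation at frequency f (Hz)."""
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive")
        logf = np.log10(f)
        if self.crossover_freq is None:
            out = np.where(logf < np.log10(self.breakpoint_low),
                           self.low_limit, self.high_limit)
        else:
            lx = math.log10(self.crossover_freq)
            diag = self.gradient_at_crossover * (logf - lx)
            out = np.clip(diag, self.high_limit, self.low_limit)
        return float(out) if out.ndim == 0 else out


def _complex_perm(eps_r: float, sigma: float, omega):
    return eps_r * EPS0 - 1j * sigma / omega


def re_cm(f, p: DielectricParams):
    """Real part of the CM factor at frequency ``f`` (Hz, scalar or array)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    ep = _complex_perm(p.eps_p, p.sigma_p, omega)
    em = _complex_perm(p.eps_m, p.sigma_m, omega)
    out = np.asarray(np.real((ep - em) / (ep + 2.0 * em)))
    return float(out) if out.ndim == 0 else out


def maxwell_wagner_time(p: DielectricParams) -> float:
    """Interfacial relaxation time tau = eps0 (eps_p + 2 eps_m)/(sigma_p + 2 sigma_m)."""
    denom = p.sigma_p + 2.0 * p.sigma_m
    if denom <= 0:
        raise ValueError("sigma_p + 2*sigma_m must be positive")
    return EPS0 * (p.eps_p + 2.0 * p.eps_m) / denom


def cm_limits(p: DielectricParams) -> tuple[float, float]:
    """Low- and high-frequency plateaus (A, B) of Re[CM].

    The degenerate case sigma_p = sigma_m = 0 is defined as A = 0 by
    continuity.
    """
    denom = p.sigma_p + 2.0 * p.sigma_m
    low = 0.0 if denom == 0 else (p.sigma_p - p.sigma_m) / denom
    high = (p.eps_p - p.eps_m) / (p.eps_p + 2.0 * p.eps_m)
    return low, high


def crossover_frequency(p: DielectricParams) -> float | None:
    """Frequency f_x (Hz) where Re[CM] = 0, or ``None`` when no crossover exists.

    f_x = (1/2pi) sqrt[(sigma_m - sigma_p)(sigma_p + 2 sigma_m) /
                       ((eps_p - eps_m)(eps_p + 2 eps_m) eps0^2)]

    Absence of a crossover (plateaus of equal sign) is a valid outcome, not
    an error: Monte-Carlo parameter draws may legitimately produce it.
    """
    num = (p.sigma_m - p.sigma_p) * (p.sigma_p + 2.0 * p.sigma_m)
    den = (p.eps_p - p.eps_m) * (p.eps_p + 2.0 * p.eps_m) * EPS0**2
    if den == 0.0 or num == 0.0:
        return None
    ratio = num / den
    if ratio <= 0.0:
        return None
    return math.sqrt(ratio) / (2.0 * math.pi)


def sigma_p_from_crossover(f_x: float, sigma_m: float,
                           eps_p: float, eps_m: float) -> float:
    """Particle conductivity from a pDEP->nDEP crossover frequency.

    Positive root of (sigma_p - sigma_m)(sigma_p + 2 sigma_m) =
    (2 pi f_x)^2 (eps_m - eps_p)(eps_p + 2 eps_m) eps0^2.
    """
    if f_x <= 0:
        raise ValueError("crossover frequency must be positive")
    if sigma_m < 0:
        raise ValueError("sigma_m must be non-negative")
    if eps_p >= eps_m:
        raise ValueError(
            "eps_p >= eps_m is inconsistent with a pDEP->nDEP crossover")
    k = (2.0 * math.pi * f_x) ** 2 * (eps_m - eps_p) * (eps_p + 2.0 * eps_m) * EPS0**2
    return 0.5 * (-sigma_m + math.sqrt(9.0 * sigma_m**2 + 4.0 * k))


def crossover_gradient(p: DielectricParams) -> float:
    """Slope of Re[CM] with respect to log10(f) at the crossover.

    Closed form ln(10) * 2AB/(A - B) from the exact Debye decomposition
    Re[CM](omega) = B + (A - B)/(1 + omega^2 tau^2); always <= 0 at a
    pDEP->nDEP crossover.
    """
    if crossover_frequency(p) is None:
        raise NoCrossoverError("spectrum has no crossover; gradient undefined")
    a, b = cm_limits(p)
    return _LN10 * 2.0 * a * b / (a - b)


def piecewise_linear_cm(p: DielectricParams) -> PiecewiseCM:
    """Three-line approximation of Re[CM] on the log-frequency axis."""
    a, b = cm_limits(p)
    f_x = crossover_frequency(p)
    if f_x is None:
        f_mw = 1.0 / (2.0 * math.pi * maxwell_wagner_time(p))
        return PiecewiseCM(a, b, None, None, f_mw, f_mw)
    g = crossover_gradient(p)
    lx = math.log10(f_x)
    return PiecewiseCM(
        low_limit=a,
        high_limit=b,
        crossover_freq=f_x,
        gradient_at_crossover=g,
        breakpoint_low=10.0 ** (lx + a / g),
        breakpoint_high=10.0 ** (lx + b / g),
    )


def particle_conductivity(props: ParticleProps) -> float:
    """sigma_p = sigma_b + 2 K_s / r for a sphere with surface conductance K_s."""
    return props.sigma_b + 2.0 * props.K_s / props.radius


def surface_conductance(sigma_p: float, sigma_b: float, radius: float) -> float:
    """K_s = (sigma_p - sigma_b) r / 2; warns when the result is unphysical."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    k_s = 0.5 * (sigma_p - sigma_b) * radius
    if k_s < 0:
        warnings.warn("sigma_p < sigma_b yields a negative surface conductance",
                      stacklevel=2)
    return k_s
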