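"""Two-step bivariate fit of the CM spectrum to rate-ratio data.

Model: rho_i = m * Re[CM](f_i; sigma_p), a scaled CM spectrum with the
offset fixed at zero (a vanishing rate ratio at the crossover is a feature
of the ratio method).  Two parameters are estimated from the samples:

* step 1 (initiation) — a line of best fit of rho on log10 f over a window
  where the ratios fall steeply gives a crossover extrapolation
  f_x0 = 10^(-alpha/beta), inverted to an initial conductivity sigma_0;
  the mean ratio at the control frequency divided by the model value there
  gives an initial scale m_0;
* step 2 (refinement) — Newton–Raphson on sigma_p (analytic first and
  second derivatives of the sum of squared errors through the Debye form
  of Re[CM]) alternated with the closed-form least-squares update of m,
  until the conductivity update falls below tolerance.

Newton steps are safeguarded by step-halving whenever the SSE would
increase, with a Nelder–Mead fallback on curvature failure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import epsilon_0 as EPS0
from scipy.optimize import minimize

from .cm_model import (DielectricParams, crossover_frequency, re_cm,
                       sigma_p_from_crossover, surface_conductance)
from .exceptions import (CurvatureError, InsufficientDataError,
                         MissingControlError)

__all__ = [
    "LineFit",
    "FitConfig",
    "FitResult",
    "fit_line",
    "initial_sigma",
    "initial_sigma_gradient",
    "initial_scale",
    "sse",
    "newton_step",
    "update_scale",
    "fit",
    "surface_conductance",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class LineFit:
    """OLS line rho = alpha + beta*log10(f) over a frequency window."""

    alpha: float
    beta: float
    freq_window: tuple[float, float]
    n_used: int


@dataclass(frozen=True)
class FitConfig:
    """Medium/particle permittivity context and fitting controls.

    ``tol_sigma`` is the conductivity-update convergence threshold in S/m
    (default 0.01 mS/m); ``fallback`` selects the safeguard on curvature
    failure ("simplex" = Nelder–Mead, "newton" = fail hard).
    """

    sigma_m: float
    eps_p: float
    eps_m: float
    control_frequency: float = 1e6
    line_window: tuple[float, float] = (1e6, 4e6)
    tol_sigma: float = 1e-5
    max_iter: int = 100
    fallback: str = "simplex"

    def __post_init__(self) -> None:
        if self.tol_sigma <= 0:
            raise ValueError("tol_sigma must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.line_window[0] >= self.line_window[1]:
            raise ValueError("line_window must be ordered")
        if self.fallback not in ("newton", "simplex"):
            raise ValueError("fallback must be 'newton' or 'simplex'")

    def params(self, sigma_p: float) -> DielectricParams:
        return DielectricParams(sigma_p=sigma_p, sigma_m=self.sigma_m,
                                eps_p=self.eps_p, eps_m=self.eps_m)


@dataclass
class FitResult:
    """Estimated conductivity and CM scale with iteration diagnostics."""

    sigma_p: float
    scale_m: float
    sigma_0: float
    m_0: float
    iterations: int
    sse: float
    converged: bool
    crossover_estimate: float | None
    used_fallback: bool = False
    history: list = field(default_factory=list)


def _arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    f = np.array([s.frequency for s in samples], dtype=float)
    rho = np.array([s.rho for s in samples], dtype=float)
    return f, rho


def fit_line(samples, window: tuple[float, float]) -> LineFit:
    """OLS of rho on log10 f over ``window`` (inclusive)."""
    f, rho = _arrays(samples)
    mask = (f >= window[0]) & (f <= window[1])
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 samples inside the line window")
    beta, alpha = np.polyfit(np.log10(f[mask]), rho[mask], 1)
    return LineFit(alpha=float(alpha), beta=float(beta),
                   freq_window=window, n_used=int(mask.sum()))


def initial_sigma(line: LineFit, sigma_m: float, eps_p: float, eps_m: float) -> float:
    """Initial conductivity from the line's extrapolated zero crossing.

    The line crosses zero at f_x0 = 10^(-alpha/beta); the crossover
    inversion then gives sigma_0.
    """
    if line.beta >= 0:
        raise ValueError("rate ratios do not decrease with frequency; "
                         "cannot extrapolate a crossover")
    f_x0 = 10.0 ** (-line.alpha / line.beta)
    return sigma_p_from_crossover(f_x0, sigma_m, eps_p, eps_m)


def initial_sigma_gradient(line: LineFit, sigma_m: float, eps_p: float,
                           eps_m: float) -> float:
    """EXPERIMENTAL gradient-method initializer (not used by default).

    Equates the fitted slope beta with the closed-form crossover gradient
    ln(10)*2AB/(A-B) and solves for the low-frequency plateau A, hence
    sigma_p.  Kept for completeness; the zero-crossing initializer is the
    default and the refined estimate is insensitive to the choice.
    """
    if line.beta >= 0:
        raise ValueError("beta must be negative")
    b = (eps_p - eps_m) / (eps_p + 2.0 * eps_m)
    a = line.beta * b / (line.beta - 2.0 * _LN10 * b)
    if a >= 1.0 or a <= -0.5:
        raise ValueError("gradient method yields an out-of-range plateau")
    return sigma_m * (1.0 + 2.0 * a) / (1.0 - a)


def initial_scale(samples, config: FitConfig, sigma_0: float) -> float:
    """m_0 = mean control rho / Re[CM](f_c; sigma_0).

    Control points are samples within 10% of the control frequency on the
    log10 scale.
    """
    f, rho = _arrays(samples)
    lc = math.log10(config.control_frequency)
    mask = np.abs(np.log10(f) - lc) <= 0.1 * abs(lc)
    if not mask.any():
        raise MissingControlError("no samples near the control frequency")
    g_c = re_cm(config.control_frequency, config.params(sigma_0))
    if g_c == 0:
        raise ZeroDivisionError("Re[CM] vanishes at the control frequency")
    return float(rho[mask].mean() / g_c)


def _model_derivs(f: np.ndarray, sigma: float, config: FitConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re[CM] and its first two partial derivatives w.r.t. sigma_p.

    Uses the exact Debye decomposition g = B + (A - B)/(1 + w^2 tau^2) with
    A = (sigma_p - sigma_m)/u, tau = eps0*(eps_p + 2 eps_m)/u, u = sigma_p
    + 2 sigma_m; B does not depend on sigma_p.
    """
    u = sigma + 2.0 * config.sigma_m
    a = (sigma - config.sigma_m) / u
    b = (config.eps_p - config.eps_m) / (config.eps_p + 2.0 * config.eps_m)
    tau = EPS0 * (config.eps_p + 2.0 * config.eps_m) / u
    w = 2.0 * np.pi * f
    x = (w * tau) ** 2
    one = 1.0 + x

    da = 3.0 * config.sigma_m / u**2
    d2a = -6.0 * config.sigma_m / u**3
    dtau = -tau / u
    d2tau = 2.0 * tau / u**2
    dx = 2.0 * w**2 * tau * dtau
    d2x = 2.0 * w**2 * (dtau**2 + tau * d2tau)

    g = b + (a - b) / one
    dg = da / one - (a - b) * dx / one**2
    d2g = (d2a / one - 2.0 * da * dx / one**2
           - (a - b) * d2x / one**2 + 2.0 * (a - b) * dx**2 / one**3)
    return g, dg, d2g


def sse(sigma: float, m: float, samples, config: FitConfig) -> float:
    """Sum of squared errors of rho_i against m*Re[CM](f_i; sigma)."""
    f, rho = _arrays(samples)
    g = re_cm(f, config.params(sigma))
    return float(((rho - m * g) ** 2).sum())


def _sse_derivs(sigma: float, m: float, samples, config: FitConfig
                ) -> tuple[float, float, float]:
    f, rho = _arrays(samples)
    g, dg, d2g = _model_derivs(f, sigma, config)
    r = rho - m * g
    s = float((r**2).sum())
    d1 = float((-2.0 * m * r * dg).sum())
    d2 = float((2.0 * m**2 * dg**2 - 2.0 * m * r * d2g).sum())
    return s, d1, d2


def newton_step(sigma_k: float, m_k: float, samples, config: FitConfig) -> float:
    """One Newton–Raphson update of sigma at fixed scale m.

    Raises CurvatureError when the local curvature of the SSE is not
    positive (the step would not descend).
    """
    _, d1, d2 = _sse_derivs(sigma_k, m_k, samples, config)
    if d2 <= 0:
        raise CurvatureError("non-positive SSE curvature at sigma_k")
    return sigma_k - d1 / d2


def update_scale(sigma: float, samples, config: FitConfig) -> float:
    """Closed-form least-squares scale m = sum(rho*g)/sum(g^2) at fixed sigma."""
    f, rho = _arrays(samples)
    g = re_cm(f, config.params(sigma))
    den = float((g**2).sum())
    if den == 0:
        raise ZeroDivisionError("Re[CM] vanishes at every sample frequency")
    return float((rho * g).sum() / den)


def _simplex(sigma0: float, m0: float, samples, config: FitConfig):
    res = minimize(lambda z: sse(abs(z[0]), z[1], samples, config),
                   x0=np.array([sigma0, m0]), method="Nelder-Mead",
                   options={"xatol": config.tol_sigma / 10.0,
                            "fatol": 1e-14, "maxiter": 2000})
    return abs(float(res.x[0])), float(res.x[1]), bool(res.success)


def fit(samples, config: FitConfig) -> FitResult:
    """Full two-step estimate of (sigma_p, m) from rate-ratio samples."""
    if len(samples) < 3 or len({s.frequency for s in samples}) < 2:
        raise InsufficientDataError(
            "need >= 3 samples spanning >= 2 frequencies")
    line = fit_line(samples, config.line_window)
    sigma_0 = initial_sigma(line, config.sigma_m, config.eps_p, config.eps_m)
    m_0 = initial_scale(samples, config, sigma_0)

    sigma, m = sigma_0, m_0
    converged = False
    used_fallback = False
    history = [(sigma, m, sse(sigma, m, samples, config))]
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        sigma_prev = sigma
        try:
            proposal = newton_step(sigma, m, samples, config)
        except CurvatureError:
            if config.fallback == "newton":
                raise
            logger.info("Newton curvature failure; switching to Nelder-Mead")
            sigma, m, ok = _simplex(sigma, m, samples, config)
            converged = ok
            used_fallback = True
            break
        # step-halving safeguard: never accept an SSE increase
        current = sse(sigma, m, samples, config)
        for _ in range(40):
            if proposal > 0 and sse(proposal, m, samples, config) <= current + 1e-15:
                break
            proposal = 0.5 * (sigma + proposal)
        sigma = proposal
        m = update_scale(sigma, samples, config)
        history.append((sigma, m, sse(sigma, m, samples, config)))
        if abs(sigma - sigma_prev) <= config.tol_sigma:
            converged = True
            break

    final_sse = sse(sigma, m, samples, config)
    return FitResult(sigma_p=sigma, scale_m=m, sigma_0=sigma_0, m_0=m_0,
                     iterations=iterations, sse=final_sse, converged=converged,
                     crossover_estimate=crossover_frequency(config.params(sigma)),
                     used_fallback=used_fallback, history=history)
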