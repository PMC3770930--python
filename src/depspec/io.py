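"""File formats, run configuration and the synthetic fixture generator.

Rate-ratio tables travel as CSV with columns
``frequency_hz,replicate,rho[,control_frequency_hz]`` (``#`` lines carry
provenance); traces as ``time_s,value`` CSV; run configuration as YAML/JSON
mapping onto the domain dataclasses.  ``generate_fixture`` ties the whole
pipeline together: it synthesizes dual-cycle fluorescence traces whose
cycle transitions are weighted by Re[CM] at the control and probe carrier
frequencies, with per-dual-cycle multiplicative conductivity noise and
additive Gaussian trace noise, emulating a camera recording of a real
collection experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .cm_model import DielectricParams, ParticleProps, re_cm
from .dualcycle import (CycleSpec, FluorescenceMap, KineticModel, Trace,
                        default_kinetics, fluorescence_from_number,
                        simulate_number)
from .exceptions import SchemaError
from .rate_extraction import RateRatioSample

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "RateRatioTable",
    "read_ratio_csv",
    "write_ratio_csv",
    "read_trace_csv",
    "write_trace_csv",
    "load_run_config",
    "default_run_config",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
_RATIO_COLUMNS = ("frequency_hz", "replicate", "rho")


@dataclass(frozen=True)
class RunConfig:
    """Complete description of a synthetic dual-cycle experiment."""

    dielectric: DielectricParams
    cycle: CycleSpec
    kinetics: KineticModel
    fluorescence: FluorescenceMap
    particle: ParticleProps | None = None
    noise_sd: float = 1.0
    cond_noise_frac: float = 0.15
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RateRatioTable:
    """Typed rate-ratio table with provenance."""

    samples: list
    provenance: str = ""
    schema_version: str = SCHEMA_VERSION


def read_ratio_csv(path) -> RateRatioTable:
    """Read and validate a rate-ratio CSV; row order preserved."""
    provenance = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                provenance += line[1:].strip() + "\n"
            else:
                break
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df.empty:
        warnings.warn("rate-ratio file contains a header only", stacklevel=2)
        return RateRatioTable([], provenance.strip())
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"non-numeric value in column {col!r}, row {int(bad[0])}")
    dup = df.duplicated(subset=["frequency_hz", "replicate"])
    if dup.any():
        raise SchemaError(
            f"duplicate (frequency, replicate) key at row {int(df.index[dup][0])}")
    has_control = "control_frequency_hz" in df.columns
    samples = [
        RateRatioSample(
            frequency=float(r.frequency_hz), replicate=int(r.replicate),
            rho=float(r.rho),
            control_frequency=float(r.control_frequency_hz)
            if has_control else float("nan"))
        for r in df.itertuples()
    ]
    return RateRatioTable(samples, provenance.strip())


def write_ratio_csv(table, path, provenance: str | None = None) -> None:
    """Write a rate-ratio table; ``read_ratio_csv(write(...))`` round trips."""
    if isinstance(table, RateRatioTable):
        samples = table.samples
        provenance = provenance if provenance is not None else table.provenance
    else:
        samples = list(table)
    df = pd.DataFrame(
        {"frequency_hz": [s.frequency for s in samples],
         "replicate": [s.replicate for s in samples],
         "rho": [s.rho for s in samples],
         "control_frequency_hz": [s.control_frequency for s in samples]})
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        for line in (provenance or "").splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trace_csv(path, spec: CycleSpec | None = None) -> Trace:
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise SchemaError(f"trace file missing column {col!r}")
    return Trace(df["time_s"].to_numpy(), df["value"].to_numpy(), spec)


def write_trace_csv(trace: Trace, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        for line in (provenance or "").splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
            fh, index=False, float_format="%.9g")


def default_run_config(seed: int = 0) -> RunConfig:
    """Study conditions of a typical latex-nanosphere experiment.

    26 mS/m particle in a 2 mS/m medium (eps 2.55/78), 100 nm radius with
    1.3 nS surface conductance, 15 s on / 10 s off per cycle (20 mHz
    modulation, 60% duty), control carrier 1 MHz, two-mode kinetics with
    3 s / 20 s time constants, near-linear fluorescence map, 15%
    cycle-to-cycle conductivity noise and unit-scale additive trace noise.
    """
    return RunConfig(
        dielectric=DielectricParams(sigma_p=26e-3, sigma_m=2e-3,
                                    eps_p=2.55, eps_m=78.0),
        particle=ParticleProps(radius=100e-9, sigma_b=0.0, K_s=1.3e-9),
        cycle=CycleSpec(15.0, 10.0, 15.0, 10.0, f1=1e6, f2=2e6, amplitude=1.0),
        kinetics=default_kinetics(dn1=1.0, dn2=0.3),
        fluorescence=FluorescenceMap(k_f=100.0, k_fc=50.0, saturation=500.0),
        noise_sd=1.0,
        cond_noise_frac=0.15,
        seed=seed,
    )


def _build(cls, mapping):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key, value in kwargs.items():
        if isinstance(value, (list, tuple)):
            kwargs[key] = tuple(float(v) for v in value)
        elif isinstance(value, str):
            # YAML 1.1 reads "1e6" as a string; coerce numeric scalars
            kwargs[key] = float(value)
    return cls(**kwargs)


def load_run_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file path or a mapping.

    Any section omitted falls back to the defaults of
    :func:`default_run_config`.
    """
    if isinstance(source, (str, bytes, os.PathLike)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    base = default_run_config()
    parts = {}
    for name, cls in (("dielectric", DielectricParams), ("cycle", CycleSpec),
                      ("kinetics", KineticModel),
                      ("fluorescence", FluorescenceMap),
                      ("particle", ParticleProps)):
        if name in data:
            parts[name] = _build(cls, data[name])
    for scalar in ("noise_sd", "cond_noise_frac", "seed"):
        if scalar in data:
            parts[scalar] = data[scalar]
    return replace(base, **parts)


def generate_fixture(config: RunConfig, probe_frequencies,
                     n_cycles: int = 5, sample_rate: float = 10.0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[list[tuple[Trace, float]], dict]:
    """Synthetic dual-cycle fluorescence traces plus a true-parameter manifest.

    For each probe frequency a dual-cycle trace is simulated with
    collection transitions dn_l proportional to Re[CM] at the cycle's
    carrier (control on cycle 1, probe on cycle 2), normalized so the
    control transition is ~1.  Each dual cycle draws its own conductivity
    sigma_j = sigma_p*(1 + eta*z_j), so the probe/control ratio inherits
    the multiplicative conductivity noise; the fluorescence map and
    additive Gaussian noise emulate the camera signal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_true = config.dielectric
    g_control = re_cm(config.cycle.f1, p_true)
    if g_control <= 0:
        raise ValueError("control frequency must sit in the pDEP band")
    traces = []
    for f2 in probe_frequencies:
        if re_cm(f2, p_true) <= 0:
            warnings.warn(
                f"probe frequency {f2:g} Hz has Re[CM] <= 0: "
                "rate ratios will be non-positive", stacklevel=2)
        spec = replace(config.cycle, f2=float(f2))
        schedule = []
        for _ in range(n_cycles):
            z = rng.standard_normal()
            sigma_j = max(p_true.sigma_p * (1.0 + config.cond_noise_frac * z), 0.0)
            p_j = p_true.with_sigma_p(sigma_j)
            schedule.append((re_cm(spec.f1, p_j) / g_control,
                             re_cm(f2, p_j) / g_control))
        number = simulate_number(spec, config.kinetics, n_cycles,
                                 dt=1.0 / sample_rate, dn_schedule=schedule)
        fluor = fluorescence_from_number(number, config.fluorescence)
        noisy = fluor.values + config.noise_sd * rng.standard_normal(len(fluor))
        traces.append((Trace(fluor.times, noisy, spec), float(f2)))
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "sigma_p": p_true.sigma_p,
        "sigma_m": p_true.sigma_m,
        "eps_p": p_true.eps_p,
        "eps_m": p_true.eps_m,
        "control_frequency": config.cycle.f1,
        "probe_frequencies": [float(f) for f in probe_frequencies],
        "m_equivalent": 1.0 / g_control,
        "n_cycles": n_cycles,
        "sample_rate": sample_rate,
        "cond_noise_frac": config.cond_noise_frac,
        "noise_sd": config.noise_sd,
    }
    return traces, manifest
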