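"""Synthetic multi-injection batches with injectable instrument faults.

The forward model is deliberately simple — Gaussian chromatographic peaks
on a flat noisy baseline, one centroid per compound per MS1 scan — but it
carries the statistical structure the QC engine assumes: run-to-run
log-normal height variation, retention-time jitter, and small per-run mass
biases on a lock-mass-corrected instrument. Fault scenarios reproduce the
phenomenology of real excursions:

``nominal``
    In-control acquisition; used to build rolling histories and NOC models.
``hv_failure``
    Detector high-voltage fault: standards above a pivot m/z are
    attenuated (more strongly at higher m/z, down to a floor factor at the
    heaviest), lighter standards gain; a strong univariate intensity fault.
``pump_drift``
    Failing organic-phase pump: retention times drift later across the
    batch, early eluters worst, eventually beyond the extraction window so
    standards go missing.
``ac_mass_bias``
    Air-conditioning outage: every standard's mass error shifts by ~1.3
    ppm — far inside the +/-10 ppm univariate limit, but a clear
    multivariate anomaly in the mass-error block.
``post_maintenance_gain``
    All standards gain a common factor after maintenance: univariate
    intensity flags, but height *ratios* are untouched, so the
    multivariate height block stays quiet.

Batches are bitwise reproducible: each run draws from a generator seeded
from (seed, injection_index), so runs are independent of processing order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Literal, Sequence

import numpy as np

from .config import CompoundSpec
from .raw_io import Run, Spectrum

__all__ = [
    "ScenarioConfig",
    "RunLabel",
    "SCENARIOS",
    "simulate_run",
    "simulate_batch",
    "reference_fragments",
]

ScenarioName = Literal[
    "nominal", "hv_failure", "pump_drift", "ac_mass_bias", "post_maintenance_gain"
]

SCENARIOS: tuple[ScenarioName, ...] = (
    "nominal", "hv_failure", "pump_drift", "ac_mass_bias", "post_maintenance_gain"
)

#: scenario-specific parameter defaults, merged under ScenarioConfig.params
_SCENARIO_DEFAULTS: dict[str, dict[str, float]] = {
    "nominal": {},
    "hv_failure": {"pivot_mz": 236.1544, "attenuation_at_max": 0.3, "low_mz_boost": 1.5},
    "pump_drift": {"max_shift": 30.0, "late_eluter_factor": 0.5},
    "ac_mass_bias": {"bias_mean": 1.3, "bias_sd": 0.3},
    "post_maintenance_gain": {"gain": 2.5},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated batch: scenario, size, timing and generator settings.

    Generator defaults (units in comments) model a routine small-molecule
    gradient method:

    * ``scan_interval`` 0.5 s MS1 scans over a ``gradient_end`` = 900 s run
    * Gaussian peaks, ``peak_sd`` 3 s, base height 1e5 counts
    * flat baseline of 500 counts with white noise, sd 200 counts
    * run-to-run per-standard height variation: log-normal, cv 10 %
    * per-run retention jitter: sd 1 s per standard
    * per-run per-standard mass bias: sd 0.15 ppm; per-scan centroid
      jitter: sd 0.3 ppm — together ~0.2 ppm run-to-run measured mass
      error, the reproducibility of a lock-mass-corrected QTOF
    """

    name: ScenarioName = "nominal"
    n_injections: int = 25
    injection_interval_min: float = 30.0
    seed: int = 0
    start_time: datetime = datetime(2024, 1, 1, tzinfo=timezone.utc)
    include_blank: bool = True
    scan_interval: float = 0.5
    gradient_end: float = 900.0
    peak_sd: float = 3.0
    base_height: float = 1.0e5
    baseline_level: float = 500.0
    baseline_noise_sd: float = 200.0
    height_cv: float = 0.10
    rt_jitter_sd: float = 1.0
    mass_bias_sd_ppm: float = 0.15
    mz_scan_jitter_ppm: float = 0.3
    dda_compounds: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        merged = dict(_SCENARIO_DEFAULTS[self.name])
        merged.update(self.params)
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class RunLabel:
    """Ground truth attached to a simulated run."""

    run_id: str
    injection_index: int
    sample_type: str
    faults: tuple[str, ...]


def _height_factors(
    scenario: ScenarioConfig, compounds: Sequence[CompoundSpec]
) -> np.ndarray:
    p = scenario.params
    mzs = np.array([c.theoretical_mz for c in compounds])
    factors = np.ones(len(compounds))
    if scenario.name == "hv_failure":
        pivot = p["pivot_mz"]
        mz_max = mzs.max()
        above = mzs > pivot
        if mz_max > pivot:
            frac = (mzs - pivot) / (mz_max - pivot)
            factors = np.where(
                above, 1.0 - (1.0 - p["attenuation_at_max"]) * frac, p["low_mz_boost"]
            )
    elif scenario.name == "post_maintenance_gain":
        factors[:] = p["gain"]
    return factors


def _rt_shifts(
    scenario: ScenarioConfig,
    compounds: Sequence[CompoundSpec],
    injection_index: int,
) -> np.ndarray:
    if scenario.name != "pump_drift":
        return np.zeros(len(compounds))
    p = scenario.params
    rts = np.array([c.expected_rt for c in compounds])
    span = rts.max() - rts.min()
    rel = (rts - rts.min()) / span if span > 0 else np.zeros_like(rts)
    per_compound = 1.0 - (1.0 - p["late_eluter_factor"]) * rel
    progress = injection_index / scenario.n_injections
    return progress * p["max_shift"] * per_compound


def reference_fragments(compound: CompoundSpec, n: int = 6) -> list[tuple[float, float]]:
    """Deterministic reference MS2 fragment list for a compound (stable
    across processes: seeded from a CRC of the identifier)."""
    rng = np.random.default_rng(zlib.crc32(compound.identifier.encode()) & 0x7FFFFFFF)
    fracs = np.sort(rng.uniform(0.15, 0.92, size=n))
    mzs = np.round(compound.theoretical_mz * fracs, 4)
    mzs = np.unique(mzs)
    intensities = rng.uniform(100.0, 1000.0, size=mzs.size)
    return [(float(m), float(i)) for m, i in zip(mzs, intensities)]


def _run_rng(scenario: ScenarioConfig, injection_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([scenario.seed & 0x7FFFFFFF, injection_index])
    )


def simulate_run(
    scenario: ScenarioConfig,
    injection_index: int,
    compounds: Sequence[CompoundSpec],
    sample_type: str = "sample",
) -> Run:
    """Generate one injection as a :class:`Run` of MS1 (and optional DDA
    MS2) spectra.

    ``injection_index`` positions the run inside the batch (progressive
    faults such as pump drift scale with it) and, with the scenario seed,
    fully determines the random stream.
    """
    rng = _run_rng(scenario, injection_index)
    n_c = len(compounds)
    mz0 = np.array([c.theoretical_mz for c in compounds])
    rt0 = np.array([c.expected_rt for c in compounds])

    heights = (
        scenario.base_height
        * _height_factors(scenario, compounds)
        * rng.lognormal(mean=0.0, sigma=scenario.height_cv, size=n_c)
    )
    centers = (
        rt0
        + _rt_shifts(scenario, compounds, injection_index)
        + rng.normal(0.0, scenario.rt_jitter_sd, size=n_c)
    )
    bias_ppm = rng.normal(0.0, scenario.mass_bias_sd_ppm, size=n_c)
    if scenario.name == "ac_mass_bias":
        p = scenario.params
        bias_ppm = bias_ppm + rng.normal(p["bias_mean"], p["bias_sd"], size=n_c)

    t = np.arange(0.0, scenario.gradient_end, scenario.scan_interval)
    n_scans = t.size
    peak = heights[None, :] * np.exp(
        -((t[:, None] - centers[None, :]) ** 2) / (2.0 * scenario.peak_sd ** 2)
    )
    noise = rng.normal(scenario.baseline_level, scenario.baseline_noise_sd, (n_scans, n_c))
    intensity = np.clip(peak + noise, 0.0, None)
    jitter = rng.normal(0.0, scenario.mz_scan_jitter_ppm, (n_scans, n_c))
    mz = mz0[None, :] * (1.0 + (bias_ppm[None, :] + jitter) * 1e-6)

    order0 = np.argsort(mz0)
    spectra: list[Spectrum] = []
    for i in range(n_scans):
        row_mz = mz[i, order0]
        row_int = intensity[i, order0]
        o = np.argsort(row_mz, kind="stable")  # jitter cannot reorder, but be safe
        spectra.append(
            Spectrum(ms_level=1, rt=float(t[i]), mz=row_mz[o], intensity=row_int[o])
        )

    by_id = {c.identifier: (i, c) for i, c in enumerate(compounds)}
    for cid in scenario.dda_compounds:
        if cid not in by_id:
            continue
        i, comp = by_id[cid]
        frags = reference_fragments(comp)
        f_mz = np.array([f[0] for f in frags])
        f_int = np.array([f[1] for f in frags])
        for offset in (-2.0, 1.0):  # two DDA events near the apex
            a_mz = f_mz + rng.normal(0.0, 0.002, f_mz.size)
            a_int = f_int * rng.lognormal(0.0, 0.05, f_int.size)
            o = np.argsort(a_mz, kind="stable")
            spectra.append(
                Spectrum(
                    ms_level=2,
                    rt=float(centers[i] + offset),
                    mz=a_mz[o],
                    intensity=a_int[o],
                    precursor_mz=float(mz0[i]),
                    acquisition_mode="DDA",
                )
            )

    acquired_at = scenario.start_time + timedelta(
        minutes=scenario.injection_interval_min * injection_index
    )
    run_id = f"{scenario.name}_{scenario.seed}_{injection_index:03d}"
    return Run(
        path=f"synthetic://{run_id}",
        acquired_at=acquired_at,
        sample_type=sample_type,
        spectra=spectra,
        polarity="positive",
        batch_id=f"{scenario.name}_{scenario.seed}",
    )


def simulate_batch(
    scenario: ScenarioConfig, compounds: Sequence[CompoundSpec]
) -> tuple[list[Run], list[RunLabel]]:
    """Generate a whole batch with ascending timestamps and ground-truth labels.

    With ``include_blank`` the injection at index 0 is a blank (used by the
    retention-time correction); sample injections then run from index 1.
    """
    runs: list[Run] = []
    labels: list[RunLabel] = []
    fault = () if scenario.name == "nominal" else (scenario.name,)
    start = 0
    if scenario.include_blank:
        run = simulate_run(scenario, 0, compounds, sample_type="blank")
        runs.append(run)
        labels.append(RunLabel(run.path, 0, "blank", ()))
        start = 1
    for i in range(start, start + scenario.n_injections):
        run = simulate_run(scenario, i, compounds, sample_type="sample")
        runs.append(run)
        labels.append(RunLabel(run.path, i, "sample", fault))
    return runs, labels
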