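"""Synthetic volunteer profiles and cohorts with known ground truth.

Emulates the caffeine-capsule study conditions: a 200 mg dose after a
caffeine fast, finger-sweat sampling on the published grids, technical
duplicates, per-time-point sweat volumes fluctuating within
[0.05, 4] uL, ~10% multiplicative technical noise (the internal
standard's observed CV) and below-LOD censoring.  Every generated table
carries its generating parameters, so parameter-recovery experiments
can score the fitted constants against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import MeasurementTable
from .model import (
    SPECIES,
    V_SWEAT_MAX,
    V_SWEAT_MIN,
    DomainError,
    InitialState,
    InputError,
    PKConstants,
    RateConstants,
    SweatVolumeSeries,
    simulate,
)

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "PopulationSpec",
    "GroundTruth",
    "DESIGNS",
    "sample_rate_constants",
    "sample_ground_truth",
    "generate_profile",
    "generate_cohort",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule of one study arm.

    grid_min: sampling times in minutes, strictly increasing from 0;
    n_replicates: technical replicates per time-point; dose_mg: ingested
    caffeine; fasting_h: pre-study caffeine fast, which controls the
    pre-dose baseline of the dimethylxanthines (long fasts deplete it).
    """

    name: str
    grid_min: tuple[float, ...]
    n_replicates: int = 2
    dose_mg: float = 200.0
    fasting_h: float = 48.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_min, dtype=float)
        if g.size < 2 or g[0] != 0 or np.any(np.diff(g) <= 0):
            raise InputError(
                "grid must be strictly increasing and start at 0"
            )
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")

    @property
    def grid_h(self) -> np.ndarray:
        return np.asarray(self.grid_min, dtype=float) / 60.0


#: published sampling schedules (minutes)
DESIGNS = {
    "A": StudyDesign("A", (0, 15, 30, 45, 60, 90, 120), fasting_h=12.0),
    "B": StudyDesign("B", (0, 15, 30, 45, 60, 90, 120), fasting_h=12.0),
    "C1": StudyDesign(
        "C1",
        (0, 15, 30, 45, 60, 90, 120,
         180, 240, 360, 480, 1440, 1500, 1560, 1620),
        fasting_h=48.0,
    ),
    "C2": StudyDesign(
        "C2",
        (0, 15, 30, 45, 60, 90, 120,
         180, 240, 300, 360, 420, 480, 540, 600,
         660, 720, 780, 840, 1440),
        fasting_h=72.0,
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    technical_cv: relative SD of the multiplicative log-normal technical
    noise (default 0.10, matching the internal standard's AUC CV);
    lod: censoring threshold in signal units (rows below it are flagged);
    noise_floor: SD of additive blank-level noise; volume_process:
    'loguniform' draws each time-point's sweat volume independently,
    'ar1' adds temporal autocorrelation (coefficient ``ar1_rho``).
    """

    technical_cv: float = 0.10
    lod: float = 0.0
    noise_floor: float = 0.0
    volume_process: str = "loguniform"
    ar1_rho: float = 0.7

    def __post_init__(self) -> None:
        if self.technical_cv < 0:
            raise DomainError("technical_cv must be >= 0")
        if self.lod < 0:
            raise DomainError("lod must be >= 0")
        if self.noise_floor < 0:
            raise DomainError("noise_floor must be >= 0")
        if self.volume_process not in ("loguniform", "ar1"):
            raise DomainError("volume_process must be 'loguniform' or 'ar1'")


@dataclass(frozen=True)
class PopulationSpec:
    """Inter-individual distribution of the rate constants.

    Centers are literature-informed defaults (fast oral absorption;
    overall caffeine turnover ~0.1 1/h dominated by the paraxanthine
    route; product eliminations within the model's [0, 0.2] 1/h bound);
    draws are normal around each center with relative SD ``rel_sd``,
    truncated to the model bounds.  ``rel_sd=0`` returns the centers.
    """

    centers: dict[str, float] = field(
        default_factory=lambda: {
            "k1": 4.0, "k2": 0.06, "k3": 0.012, "k4": 0.008, "k5": 0.02,
            "k6": 0.12, "k7": 0.05, "k8": 0.08,
        }
    )
    rel_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise DomainError("rel_sd must be >= 0")
        try:
            RateConstants(**self.centers)
        except DomainError as e:
            raise DomainError(f"population centers outside bounds: {e}")


def sample_rate_constants(rng: np.random.Generator,
                          spec: PopulationSpec = PopulationSpec()
                          ) -> RateConstants:
    """Draw one individual's rate constants from the population spec."""
    from .model import K1_MAX, K_MAX

    out = {}
    for name, center in spec.centers.items():
        hi = K1_MAX if name == "k1" else K_MAX
        if spec.rel_sd == 0:
            out[name] = center
            continue
        sd = spec.rel_sd * center
        v = rng.normal(center, sd)
        while not 0 <= v <= hi:  # truncation by rejection
            v = rng.normal(center, sd)
        out[name] = v
    return RateConstants(**out)


@dataclass(frozen=True)
class GroundTruth:
    """The parameters actually used to generate a profile."""

    rates: RateConstants
    initial: InitialState
    volumes: SweatVolumeSeries


def _sample_volumes(rng: np.random.Generator, n: int,
                    noise: NoiseModel) -> np.ndarray:
    lo, hi = np.log(V_SWEAT_MIN), np.log(V_SWEAT_MAX)
    if noise.volume_process == "loguniform":
        return np.exp(rng.uniform(lo, hi, n))
    # AR(1) in log-volume, mapped through the stationary normal CDF to
    # keep the marginal log-uniform on the bounds
    from scipy.stats import norm

    rho = noise.ar1_rho
    z = np.empty(n)
    z[0] = rng.normal()
    for i in range(1, n):
        z[i] = rho * z[i - 1] + np.sqrt(1 - rho ** 2) * rng.normal()
    return np.exp(lo + (hi - lo) * norm.cdf(z))


def sample_ground_truth(rng: np.random.Generator, design: StudyDesign,
                        population: PopulationSpec = PopulationSpec(),
                        noise: NoiseModel = NoiseModel()) -> GroundTruth:
    """Draw rates, baseline and sweat volumes for one volunteer."""
    rates = sample_rate_constants(rng, population)
    if design.fasting_h >= 48:
        c0 = rng.uniform(0.0, 0.05, 3)  # long fast: depleted baseline
    else:
        c0 = rng.uniform(0.05, 1.0, 3)  # short fast: residual products
    initial = InitialState(*c0)
    volumes = SweatVolumeSeries(
        _sample_volumes(rng, len(design.grid_min), noise)
    )
    return GroundTruth(rates, initial, volumes)


def generate_profile(truth: GroundTruth, design: StudyDesign,
                     noise: NoiseModel = NoiseModel(),
                     seed: int | np.random.Generator = 0,
                     constants: PKConstants | None = None
                     ) -> tuple[MeasurementTable, GroundTruth]:
    """Forward-simulate one volunteer profile.

    Expected signal is V_sweat(t_j) * C_i(t_j); replicates at a
    time-point share the sweat volume and differ only by technical
    noise.  Noise is multiplicative log-normal with the configured CV
    (unit mean) plus an optional additive floor; rows below the LOD are
    flagged censored, not removed.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if constants is None:
        constants = PKConstants(dose=design.dose_mg)
    traj = simulate(truth.rates, constants, truth.initial, design.grid_h)
    expected = truth.volumes.volumes[:, None] * traj.conc  # (T, 4)

    rows = []
    cv = noise.technical_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    for j, t_h in enumerate(design.grid_h):
        for rep in range(1, design.n_replicates + 1):
            for i, sp in enumerate(SPECIES):
                y = expected[j, i]
                if sigma > 0:
                    y *= rng.lognormal(-0.5 * sigma * sigma, sigma)
                if noise.noise_floor > 0:
                    y += rng.normal(0.0, noise.noise_floor)
                y = max(y, 0.0)
                rows.append((t_h, sp, f"r{rep}", y, y < noise.lod))
    df = pd.DataFrame(
        rows, columns=["time_h", "species", "replicate", "signal", "censored"]
    )
    return MeasurementTable(df), truth


def generate_cohort(n_volunteers: int, design: StudyDesign,
                    population: PopulationSpec = PopulationSpec(),
                    noise: NoiseModel = NoiseModel(), seed: int = 0
                    ) -> list[tuple[MeasurementTable, GroundTruth]]:
    """Generate independent volunteer profiles with per-volunteer truths."""
    if n_volunteers < 1:
        raise InputError("n_volunteers must be >= 1")
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_volunteers):
        rng = np.random.default_rng(child)
        truth = sample_ground_truth(rng, design, population, noise)
        out.append(generate_profile(truth, design, noise, rng))
    return out
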