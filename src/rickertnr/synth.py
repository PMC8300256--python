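"""Synthetic TNR-program generators.

Two regimes cover the two jobs synthetic data must do here:

* :func:`generate_ricker_program` draws a population that truly follows
  the Ricker map, observed through a surgery index and a noisy census —
  the ground truth for parameter-recovery checks.
* :func:`generate_managed_program` emulates a well-run TNR program of the
  kind whose published census record declines *linearly* (not in Ricker
  boom–bust fashion): a straight-line census with Poisson jitter,
  binomial annual surgery effort at a target neutering fraction, per-cat
  surgery records with a linearly declining monthly pregnancy
  probability, and kitten-age adoption removals. This is the regime on
  which the Ricker criteria are expected to *fail* to register decline —
  the model-mismatch demonstration.

All draws flow from NumPy's PCG64 generator seeded per run, with a
per-year substream (``default_rng([seed, year_index])``) so results do
not depend on draw order within a year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DataValidationError
from .io import CatRecord, ProgramTimeSeries
from .ricker import RickerParams, simulate

__all__ = [
    "RickerGenConfig",
    "ManagedDeclineConfig",
    "generate_ricker_program",
    "generate_managed_program",
    "preset",
]


@dataclass(frozen=True)
class RickerGenConfig:
    """A Ricker-governed population observed through surgeries + census.

    ``surgery_fraction`` is the fraction of the population sterilized
    (and therefore counted in the surgery index) each year — a scalar or
    one value per year. ``obs_noise_sd`` is the standard deviation of
    multiplicative lognormal noise on the census observation; 0 makes
    the output fully deterministic.
    """

    r_m: float
    K: float
    N_1: float
    years: int = 20
    surgery_fraction: Union[float, Sequence[float]] = 1.0
    obs_noise_sd: float = 0.0
    seed: int = 0
    start_year: int = 2000

    def fractions(self) -> list[float]:
        if isinstance(self.surgery_fraction, (int, float)):
            fr = [float(self.surgery_fraction)] * self.years
        else:
            fr = [float(f) for f in self.surgery_fraction]
            if len(fr) != self.years:
                raise DataValidationError(
                    "surgery_fraction sequence must have one value per year"
                )
        for f in fr:
            if not 0 < f <= 1:
                raise DataValidationError(f"surgery fraction {f} outside (0, 1]")
        return fr


@dataclass(frozen=True)
class ManagedDeclineConfig:
    """A managed, linearly declining program with per-cat records.

    The census follows the straight line from ``N_start`` to ``N_end``
    with Poisson jitter; surgeries are a binomial draw at
    ``neutering_fraction_median`` of each year's population; the monthly
    pregnancy probability declines linearly from ``pregnancy_start`` to
    ``pregnancy_end`` over the program; adopted cats get lognormal ages
    with median ``adoption_age_months_median``. ``immigration_rate``
    (cats/year, default 0) is added to the expected census — an
    extrapolation knob, not an observed quantity.
    """

    N_start: int
    N_end: int
    years: int
    neutering_fraction_median: float
    adoption_age_months_median: float = 4.8
    pregnancy_start: float = 0.35
    pregnancy_end: float = 0.03
    female_fraction: float = 0.5
    adoption_fraction: float = 0.3
    immigration_rate: float = 0.0
    seed: int = 0
    start_year: int = 1995

    def __post_init__(self) -> None:
        if self.N_start <= 0 or self.N_end <= 0:
            raise DataValidationError("populations must be positive")
        if self.N_end > self.N_start:
            raise DataValidationError(
                f"managed-decline scenario needs N_end <= N_start "
                f"(got {self.N_start} -> {self.N_end})"
            )
        if self.years < 2:
            raise DataValidationError("need at least 2 years")
        for name in ("neutering_fraction_median", "pregnancy_start",
                     "pregnancy_end", "female_fraction", "adoption_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataValidationError(f"{name}={v} outside [0, 1]")
        if self.immigration_rate < 0:
            raise DataValidationError("immigration_rate must be >= 0")
        if self.adoption_age_months_median <= 0:
            raise DataValidationError("adoption age must be positive")


def generate_ricker_program(config: RickerGenConfig) -> ProgramTimeSeries:
    """Simulate a Ricker population and observe it as a program series.

    The latent trajectory is exact (real-valued); surgeries are
    ``round(fraction_t * N_t)`` and the census is ``round(N_t * eps_t)``
    with eps lognormal(0, ``obs_noise_sd``). Deterministic given the
    seed.
    """
    fractions = config.fractions()
    if config.obs_noise_sd < 0:
        raise DataValidationError("obs_noise_sd must be >= 0")
    params = RickerParams.from_r_m(config.r_m, K_index=config.K)
    traj = simulate(params, N_1=config.N_1, T=config.years)
    rng = np.random.default_rng(config.seed)
    if config.obs_noise_sd > 0:
        eps = np.exp(rng.normal(0.0, config.obs_noise_sd, size=config.years))
    else:
        eps = np.ones(config.years)
    years = [config.start_year + i for i in range(config.years)]
    surgeries = [int(round(f * n)) for f, n in zip(fractions, traj.N)]
    census = [int(round(n * e)) for n, e in zip(traj.N, eps)]
    return ProgramTimeSeries(
        program_id=f"ricker_synthetic_seed{config.seed}",
        years=years,
        surgeries=surgeries,
        census=census,
    )


def _year_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_managed_program(
    config: ManagedDeclineConfig,
) -> tuple[ProgramTimeSeries, list[CatRecord]]:
    """Generate a managed-decline program and its per-cat records.

    Returns the yearly series (census, surgeries, removals) and one
    :class:`~rickertnr.io.CatRecord` per surgery. Deterministic given
    the seed; draws use a per-year substream.
    """
    T = config.years
    line = np.linspace(config.N_start, config.N_end, T) + config.immigration_rate
    years = [config.start_year + i for i in range(T)]
    total_months = T * 12

    surgeries: list[int] = []
    census: list[int] = []
    removals: list[int] = []
    records: list[CatRecord] = []

    for i in range(T):
        rng = _year_rng(config.seed, i)
        pop = int(rng.poisson(line[i]))
        n_surg = int(rng.binomial(pop, config.neutering_fraction_median)) if pop > 0 else 0
        months = rng.integers(1, 13, size=n_surg)
        removed = 0
        for m in sorted(months):
            month_idx = i * 12 + (m - 1)
            p_preg = config.pregnancy_start + (
                config.pregnancy_end - config.pregnancy_start
            ) * month_idx / max(total_months - 1, 1)
            female = bool(rng.random() < config.female_fraction)
            pregnant = bool(female and rng.random() < p_preg)
            adopted = bool(rng.random() < config.adoption_fraction)
            if adopted:
                age = float(
                    math.exp(rng.normal(math.log(config.adoption_age_months_median), 0.6))
                )
                outcome = "adopted"
                removed += 1
            else:
                # returned adults: broad lognormal around 3 years
                age = float(math.exp(rng.normal(math.log(36.0), 0.6)))
                outcome = "returned"
            records.append(
                CatRecord(
                    year=years[i], month=int(m), sex="female" if female else "male",
                    pregnant=pregnant, age_months=age, outcome=outcome,
                )
            )
        surgeries.append(n_surg)
        census.append(pop)
        removals.append(removed)

    series = ProgramTimeSeries(
        program_id=f"managed_synthetic_seed{config.seed}",
        years=years,
        surgeries=surgeries,
        census=census,
        removals=removals,
    )
    return series, records


_PRESETS: dict[str, ManagedDeclineConfig] = {
    # a private-community program: 455 -> 206 cats, median neutering
    # fraction 0.22, monthly pregnancy proportion falling to near zero
    "orcat_like": ManagedDeclineConfig(
        N_start=455, N_end=206, years=22,
        neutering_fraction_median=0.22,
        adoption_age_months_median=4.8,
        pregnancy_start=0.35, pregnancy_end=0.03,
        start_year=1995,
    ),
    # a campus program: 68 -> 10 cats over 28 years, median fraction 0.16
    "ucf_like": ManagedDeclineConfig(
        N_start=68, N_end=10, years=28,
        neutering_fraction_median=0.16,
        adoption_age_months_median=4.8,
        pregnancy_start=0.35, pregnancy_end=0.03,
        start_year=1991,
    ),
}


def preset(name: str, seed: Optional[int] = None) -> ManagedDeclineConfig:
    """A calibrated managed-decline configuration by name.

    Known names: ``orcat_like`` (455→206 cats, 22 years, fraction 0.22)
    and ``ucf_like`` (68→10 cats, 28 years, fraction 0.16). An optional
    seed replaces the preset's default seed 0.
    """
    if name not in _PRESETS:
        raise DataValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    cfg = _PRESETS[name]
    return cfg if seed is None else replace(cfg, seed=seed)
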