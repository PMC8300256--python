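"""The Ricker map and the quantities derived from it.

The model is the classic discrete-time scramble-competition map from
fisheries stock–recruitment theory,

    N_{t+1} = N_t · e^{r_m (1 − N_t / K)},

where r_m is the maximum per-capita rate of increase (the growth rate at
vanishing density), K the carrying capacity, and the annual multiplier
R_t = e^{r_m (1 − N_t/K)} equals 1 exactly at N_t = K. The Malthusian
multiplier R_m = e^{r_m} is the low-density annual multiplication factor;
a population governed by the model declines only when its realized
multiplier is below 1.

From R_m and an annual survival rate p (approximated from lifespan as
p = 1 − 1/lifespan) follow the sterilization thresholds used to judge
TNR effort:

* critical overall neutering rate  s   = (R_m − 1) / (R_m − p)
* critical annual neutering rate   s_a = s (1 − p)

Simulation state is real-valued throughout; integer rounding is a display
concern only, since rounding during iteration would perturb trajectories.
Dynamical regimes follow the standard Ricker bifurcation thresholds:
monotone approach for r_m ≤ 1, damped (alternating) approach for
1 < r_m < 2, periodic orbits from r_m = 2, chaos from r_m ≈ 2.6924.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import AnalysisPreconditionError, DataValidationError

__all__ = [
    "RickerParams",
    "SurvivalParams",
    "CriticalRates",
    "Trajectory",
    "malthusian_multiplier",
    "survival_from_lifespan",
    "critical_neutering_rate",
    "critical_annual_rate",
    "critical_rates",
    "scale_carrying_capacity",
    "simulate",
    "classify_dynamics",
    "CHAOS_ONSET",
]

#: onset of the period-doubling cascade and of chaos for the Ricker map
PERIOD_DOUBLING_ONSET = 2.0
CHAOS_ONSET = 2.6924


@dataclass
class RickerParams:
    """Parameters of a fitted or assumed Ricker model.

    ``K_index`` is the carrying capacity on whatever index scale the
    counts live on (here: annual surgeries); ``K_actual`` is on the
    cat-count scale when a census allows the conversion.
    """

    r_m: float
    R_m: float
    K_index: float
    K_actual: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isclose(self.R_m, math.exp(self.r_m), rel_tol=1e-9):
            raise DataValidationError(
                f"inconsistent parameters: R_m={self.R_m} but e^r_m="
                f"{math.exp(self.r_m)}"
            )
        if self.K_index <= 0:
            raise DataValidationError("K_index must be positive")
        if self.K_actual is not None and self.K_actual <= 0:
            raise DataValidationError("K_actual must be positive")

    @classmethod
    def from_r_m(cls, r_m: float, K_index: float,
                 K_actual: Optional[float] = None) -> "RickerParams":
        return cls(r_m=r_m, R_m=math.exp(r_m), K_index=K_index, K_actual=K_actual)

    @classmethod
    def from_R_m(cls, R_m: float, K_index: float,
                 K_actual: Optional[float] = None) -> "RickerParams":
        if R_m <= 0:
            raise DataValidationError("R_m must be positive")
        return cls(r_m=math.log(R_m), R_m=R_m, K_index=K_index, K_actual=K_actual)


@dataclass(frozen=True)
class SurvivalParams:
    """Annual survival rate derived from a lifespan estimate."""

    lifespan_years: float
    basis: str  # "mean" | "median"
    p: float


@dataclass(frozen=True)
class CriticalRates:
    """Sterilization thresholds for population decline.

    ``s`` is the overall (cumulative) fraction of the population that must
    be sterile; ``s_a`` the fraction that must be newly sterilized each
    year, s_a = s(1 − p).
    """

    s: float
    s_a: float


@dataclass
class Trajectory:
    """A simulated population path.

    ``N[t]`` is the population in year ``years[t]`` (years run 1..T);
    ``R[t]`` is the annual multiplier applied between years t+1 and t+2,
    so ``N[t+1] = N[t] * R[t]`` and ``len(R) == len(N) − 1``.
    """

    years: list[int]
    N: list[float]
    R: list[float]
    r_m: float
    K: float
    regime: str = ""
    notes: list[str] = field(default_factory=list)

    def final(self) -> float:
        return self.N[-1]

    def to_frame(self) -> pd.DataFrame:
        R_col = [*self.R, float("nan")]
        return pd.DataFrame({"year": self.years, "N": self.N, "R": R_col})

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def malthusian_multiplier(r_m: float) -> float:
    """R_m = e^{r_m}: the annual multiplication factor at low density."""
    if not math.isfinite(r_m):
        raise DataValidationError("r_m must be finite")
    return math.exp(r_m)


def survival_from_lifespan(lifespan_years: float, basis: str = "median") -> SurvivalParams:
    """Annual survival p = 1 − 1/lifespan (lifespan in years, ≥ 1)."""
    if basis not in ("mean", "median"):
        raise DataValidationError(f"unknown lifespan basis {basis!r}")
    if lifespan_years < 1:
        raise DataValidationError(
            f"lifespan {lifespan_years} < 1 year would imply negative survival"
        )
    return SurvivalParams(
        lifespan_years=float(lifespan_years),
        basis=basis,
        p=1.0 - 1.0 / float(lifespan_years),
    )


def critical_neutering_rate(R_m: float, p: float) -> float:
    """Critical overall neutering fraction s = (R_m − 1)/(R_m − p).

    Defined for R_m > p; between 0 and 1 whenever p ≤ 1 ≤ R_m. Returned
    at full precision — rounding to display percent happens elsewhere.
    """
    if not 0 <= p <= 1:
        raise DataValidationError(f"survival rate p={p} outside [0, 1]")
    if R_m <= p:
        raise AnalysisPreconditionError(
            f"critical neutering rate undefined for R_m={R_m} <= p={p}"
        )
    return (R_m - 1.0) / (R_m - p)


def critical_annual_rate(s: float, p: float) -> float:
    """Critical annual neutering fraction s_a = s(1 − p)."""
    if not 0 <= s <= 1:
        raise DataValidationError(f"overall rate s={s} outside [0, 1]")
    if not 0 <= p < 1:
        raise DataValidationError(f"survival rate p={p} outside [0, 1)")
    return s * (1.0 - p)


def critical_rates(R_m: float, p: float) -> CriticalRates:
    """Both thresholds from (R_m, p), s carried unrounded into s_a.

    The raw formula goes negative for R_m < 1 (a population already
    declining needs no sterilization); here s is clamped into [0, 1] so
    the pair always satisfies s_a = s(1 − p).
    """
    s = critical_neutering_rate(R_m, p)
    s = min(max(s, 0.0), 1.0)
    return CriticalRates(s=s, s_a=critical_annual_rate(s, p))


def scale_carrying_capacity(
    K_index: float, final_population: int, final_surgeries: int
) -> float:
    """Convert an index-scale K to the cat-count scale.

    Multiplies the index carrying capacity by the final-year census
    population and divides by the final-year surgeries — i.e. rescales by
    the last observed cats-per-surgery ratio.
    """
    if K_index <= 0:
        raise DataValidationError("K_index must be positive")
    if final_surgeries <= 0:
        raise DataValidationError(
            "cannot scale the index carrying capacity in a zero-surgery year"
        )
    if final_population < 0:
        raise DataValidationError("final population must be >= 0")
    return K_index * final_population / final_surgeries


def classify_dynamics(r_m: float) -> str:
    """Qualitative regime of the Ricker map at growth rate r_m.

    Uses the standard bifurcation thresholds: the fixed point at K is
    approached monotonically for 0 < r_m ≤ 1, through damped
    oscillations for 1 < r_m < 2; stable cycles exist for
    2 ≤ r_m < 2.6924 and chaos beyond. Negative r_m means monotone
    decline toward zero.
    """
    if not math.isfinite(r_m):
        raise DataValidationError("r_m must be finite")
    if r_m == 0:
        return "constant"
    if r_m < 0 or r_m <= 1.0:
        return "monotone"
    if r_m < PERIOD_DOUBLING_ONSET:
        return "damped_oscillation"
    if r_m < CHAOS_ONSET:
        return "periodic"
    return "chaotic"


def simulate(
    params: RickerParams,
    N_1: float,
    T: int = 20,
    use: str = "index",
) -> Trajectory:
    """Iterate the Ricker map for T years from N_1.

    ``use`` selects the carrying-capacity scale: ``"index"`` (default)
    takes ``params.K_index``, ``"actual"`` takes ``params.K_actual``.
    State is real-valued and unrounded throughout; the trajectory has T
    entries (years 1..T), hence T − 1 map applications.
    """
    if use == "index":
        K = params.K_index
    elif use == "actual":
        if params.K_actual is None:
            raise DataValidationError("params carry no K_actual")
        K = params.K_actual
    else:
        raise DataValidationError(f"unknown carrying-capacity choice {use!r}")
    if N_1 <= 0:
        raise DataValidationError("N_1 must be positive")
    if T < 1:
        raise DataValidationError("T must be >= 1")
    r_m = params.r_m
    N = [float(N_1)]
    R: list[float] = []
    for _ in range(T - 1):
        Rt = math.exp(r_m * (1.0 - N[-1] / K))
        R.append(Rt)
        N.append(N[-1] * Rt)
    return Trajectory(
        years=list(range(1, T + 1)), N=N, R=R, r_m=r_m, K=K,
        regime=classify_dynamics(r_m),
    )
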