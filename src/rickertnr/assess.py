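"""Program assessment: the four-criteria report card.

The assessment applies, to one program's data, the four criteria used to
judge TNR effectiveness under the Ricker framework:

1. density-dependent population regulation — regression of per-capita
   growth rate over time;
2. fecundity change — regression of the monthly pregnant-female
   proportion over time (when per-cat records exist);
3. the Malthusian multiplier R_m (must be < 1 for decline under the
   model), derived from the growth-vs-surgeries regression: y-intercept
   = r_m, x-intercept = index carrying capacity K;
4. the critical neutering rates s and s_a implied by R_m and survival,
   compared with the observed annual neutering fractions
   (surgeries ÷ estimated population).

Every criterion the input data cannot support is reported as
``not_available`` — never silently fabricated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Sequence

import numpy as np

from .config import RunConfig
from .errors import AnalysisPreconditionError, DataValidationError
from .growth import per_capita_growth_rates
from .io import CatRecord, ProgramTimeSeries
from .pregnancy import aggregate_pregnancy, pregnancy_trend_test
from .regression import RegressionFit, fit_linear, fit_with_outlier_exclusion, lowess_curve
from .ricker import (
    CriticalRates,
    RickerParams,
    SurvivalParams,
    critical_rates,
    scale_carrying_capacity,
    survival_from_lifespan,
)

__all__ = [
    "NeuteringSeries",
    "AssessmentReport",
    "annual_neutering_fractions",
    "assess_program",
    "render_report",
    "report_from_json",
]

CRITERIA = ("growth_vs_time", "growth_vs_surgeries", "growth_vs_population", "pregnancy")


@dataclass
class NeuteringSeries:
    """Observed annual neutering fractions (surgeries ÷ population).

    A fraction is absent (``None``) where no population estimate exists;
    a zero-surgery year is a valid observation with fraction 0.
    """

    years: list[int]
    fractions: list[Optional[float]]
    median_fraction: Optional[float]
    population_model: str = "census_regression"

    def present(self) -> list[float]:
        return [f for f in self.fractions if f is not None]


@dataclass
class AssessmentReport:
    """The full report card for one program (Table-3-style)."""

    program_id: str
    config: dict[str, Any]
    growth_vs_time: Optional[RegressionFit]
    growth_vs_surgeries: Optional[RegressionFit]
    growth_vs_population: Optional[RegressionFit]
    pregnancy: Optional[RegressionFit]
    ricker: Optional[RickerParams]
    survival: Optional[SurvivalParams]
    critical: Optional[CriticalRates]
    observed_neutering: Optional[NeuteringSeries]
    verdicts: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def annual_neutering_fractions(
    series: ProgramTimeSeries, population_model: str = "census_regression"
) -> NeuteringSeries:
    """Annual surgeries divided by the estimated population.

    ``census_regression`` (the default) fits a least-squares line to the
    census counts over the years that have one and evaluates it in every
    program year (floored at 1 cat); ``census_raw`` uses the census
    counts directly and leaves other years absent.
    """
    pairs = series.census_years()
    if population_model == "census_regression":
        if len(pairs) < 2:
            raise AnalysisPreconditionError(
                "census_regression needs census counts in at least 2 years"
            )
        yrs = np.array([y for y, _ in pairs], dtype=float)
        cts = np.array([c for _, c in pairs], dtype=float)
        slope, intercept = np.polyfit(yrs, cts, 1)
        estimates: list[Optional[float]] = [
            max(intercept + slope * y, 1.0) for y in series.years
        ]
    elif population_model == "census_raw":
        if not pairs:
            raise AnalysisPreconditionError(
                "no census data: supply population estimates to compute "
                "neutering fractions"
            )
        estimates = [
            float(c) if (c is not None and c > 0) else None for c in series.census
        ]
    else:
        raise DataValidationError(f"unknown population model {population_model!r}")
    fractions = [
        (s / e if e is not None else None)
        for s, e in zip(series.surgeries, estimates)
    ]
    present = [f for f in fractions if f is not None]
    median = float(np.median(present)) if present else None
    return NeuteringSeries(
        years=list(series.years),
        fractions=fractions,
        median_fraction=median,
        population_model=population_model,
    )


def _rate_pairs(
    counts: Sequence[Optional[float]],
) -> tuple[list[float], list[float]]:
    """(N_t, r_t) pairs: each growth rate against the count it started from."""
    xs, ys = [], []
    for i in range(len(counts) - 1):
        n0, n1 = counts[i], counts[i + 1]
        if n0 and n1:
            xs.append(float(n0))
            ys.append(math.log(n1 / n0))
    return xs, ys


def _try_fit(fn, *args, notes: list[str], label: str):
    try:
        return fn(*args)
    except AnalysisPreconditionError as exc:
        notes.append(f"{label}: {exc}")
        return None


def _fit_rates_on_counts(xs, ys, threshold, notes, label):
    """Growth rates regressed on counts, tolerating the fully constant
    program: identical counts with identical rates carry no trend (slope
    0, p = 1) rather than no answer."""
    if len(xs) >= 3 and len(set(xs)) == 1 and len(set(ys)) == 1:
        notes.append(f"{label}: constant counts and rates; no trend by construction")
        return RegressionFit(
            slope=0.0, intercept=float(ys[0]), p_value=1.0,
            stderr_slope=0.0, n_used=len(xs),
            notes=["degenerate fit: constant predictor and response"],
        )
    return _try_fit(
        fit_with_outlier_exclusion, xs, ys, threshold, notes=notes, label=label
    )


def _verdict(fit: Optional[RegressionFit], alpha: float) -> str:
    if fit is None:
        return "not_available"
    if fit.slope < 0 and fit.p_value < alpha:
        return "significant_decline"
    return "not_significant"


def assess_program(
    series: ProgramTimeSeries,
    records: Optional[Iterable[CatRecord]] = None,
    lifespan: float = 5.0,
    basis: str = "mean",
    config: Optional[RunConfig] = None,
) -> AssessmentReport:
    """Run the full four-criteria assessment on one program.

    ``lifespan``/``basis`` give the lifespan estimate (years; mean or
    median) from which annual survival p = 1 − 1/lifespan is derived.
    Ricker parameters always come from the growth-vs-surgeries
    regression; the census, when present, contributes the
    growth-vs-population criterion, the carrying-capacity rescaling and
    the observed neutering fractions.
    """
    cfg = config or RunConfig()
    notes: list[str] = []

    rates = per_capita_growth_rates(
        series, basis="surgeries", convention=cfg.rate_year_convention
    )
    notes.extend(rates.notes)
    ry, rv = rates.present()

    growth_vs_time = _try_fit(
        fit_linear, ry, rv, notes=notes, label="growth_vs_time"
    )

    xs, ys = _rate_pairs([float(s) for s in series.surgeries])
    growth_vs_surgeries = _fit_rates_on_counts(
        xs, ys, cfg.outlier_threshold, notes, "growth_vs_surgeries"
    )
    if growth_vs_surgeries is not None and len(xs) >= 5:
        growth_vs_surgeries.smoother = lowess_curve(
            xs, ys, bandwidth=cfg.lowess_bandwidth,
            robust_iters=cfg.lowess_robust_iters,
        )

    growth_vs_population = None
    if series.has_census:
        cx, cy = _rate_pairs(
            [None if c is None else float(c) for c in series.census]
        )
        growth_vs_population = _fit_rates_on_counts(
            cx, cy, cfg.outlier_threshold, notes, "growth_vs_population"
        )
    else:
        notes.append("growth_vs_population: no census data")

    pregnancy = None
    if records is not None:
        recs = list(records)
        if recs:
            preg_series = aggregate_pregnancy(recs)
            pregnancy = _try_fit(
                pregnancy_trend_test, preg_series, notes=notes, label="pregnancy"
            )
    else:
        notes.append("pregnancy: no per-cat records supplied")

    ricker: Optional[RickerParams] = None
    if growth_vs_surgeries is not None:
        if growth_vs_surgeries.slope >= 0:
            notes.append(
                "growth-vs-surgeries slope is non-negative: no carrying "
                "capacity crossing, Ricker parameters not available"
            )
        elif growth_vs_surgeries.x_intercept is None or growth_vs_surgeries.x_intercept <= 0:
            notes.append(
                "growth-vs-surgeries x-intercept non-positive: index "
                "carrying capacity not interpretable"
            )
        else:
            ricker = RickerParams.from_r_m(
                r_m=growth_vs_surgeries.intercept,
                K_index=growth_vs_surgeries.x_intercept,
            )

    if ricker is not None:
        final = [
            (y, c, s)
            for y, c, s in zip(series.years, series.census, series.surgeries)
            if c is not None
        ]
        if final:
            y_f, c_f, s_f = final[-1]
            if s_f > 0:
                ricker.K_actual = scale_carrying_capacity(ricker.K_index, c_f, s_f)
                notes.append(
                    f"actual K scaled using final census year {y_f} "
                    f"(population {c_f}, surgeries {s_f})"
                )
            else:
                notes.append(
                    f"actual K not scaled: zero surgeries in final census year {y_f}"
                )

    survival = survival_from_lifespan(lifespan, basis=basis)

    critical: Optional[CriticalRates] = None
    if ricker is not None:
        if ricker.R_m > survival.p:
            critical = critical_rates(ricker.R_m, survival.p)
        else:
            notes.append(
                f"critical rates undefined: R_m={ricker.R_m:.3g} <= "
                f"p={survival.p:.3g}"
            )
    else:
        notes.append("critical rates not available without Ricker parameters")

    observed = None
    if len(series.census_years()) >= 2:
        observed = annual_neutering_fractions(series, "census_regression")
    else:
        notes.append("observed neutering fractions: insufficient census data")

    fits = {
        "growth_vs_time": growth_vs_time,
        "growth_vs_surgeries": growth_vs_surgeries,
        "growth_vs_population": growth_vs_population,
        "pregnancy": pregnancy,
    }
    verdicts = {k: _verdict(v, cfg.alpha) for k, v in fits.items()}

    return AssessmentReport(
        program_id=series.program_id,
        config=cfg.to_dict(),
        growth_vs_time=growth_vs_time,
        growth_vs_surgeries=growth_vs_surgeries,
        growth_vs_population=growth_vs_population,
        pregnancy=pregnancy,
        ricker=ricker,
        survival=survival,
        critical=critical,
        observed_neutering=observed,
        verdicts=verdicts,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# serialization


def _fit_to_dict(fit: Optional[RegressionFit]) -> Optional[dict[str, Any]]:
    if fit is None:
        return None
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "p_value": fit.p_value,
        "stderr_slope": fit.stderr_slope,
        "n_used": fit.n_used,
        "x_intercept": fit.x_intercept,
        "excluded": [list(p) for p in fit.excluded],
        "smoother": None if fit.smoother is None else [list(p) for p in fit.smoother],
        "notes": list(fit.notes),
    }


def _fit_from_dict(d: Optional[dict[str, Any]]) -> Optional[RegressionFit]:
    if d is None:
        return None
    return RegressionFit(
        slope=d["slope"],
        intercept=d["intercept"],
        p_value=d["p_value"],
        stderr_slope=d["stderr_slope"],
        n_used=d["n_used"],
        x_intercept=d["x_intercept"],
        excluded=[tuple(p) for p in d["excluded"]],
        smoother=None if d["smoother"] is None else [tuple(p) for p in d["smoother"]],
        notes=list(d["notes"]),
    )


def report_to_dict(report: AssessmentReport) -> dict[str, Any]:
    r = report
    return {
        "program_id": r.program_id,
        "config": dict(r.config),
        "growth_vs_time": _fit_to_dict(r.growth_vs_time),
        "growth_vs_surgeries": _fit_to_dict(r.growth_vs_surgeries),
        "growth_vs_population": _fit_to_dict(r.growth_vs_population),
        "pregnancy": _fit_to_dict(r.pregnancy),
        "ricker": None if r.ricker is None else {
            "r_m": r.ricker.r_m, "R_m": r.ricker.R_m,
            "K_index": r.ricker.K_index, "K_actual": r.ricker.K_actual,
        },
        "survival": None if r.survival is None else {
            "lifespan_years": r.survival.lifespan_years,
            "basis": r.survival.basis, "p": r.survival.p,
        },
        "critical": None if r.critical is None else {
            "s": r.critical.s, "s_a": r.critical.s_a,
        },
        "observed_neutering": None if r.observed_neutering is None else {
            "years": list(r.observed_neutering.years),
            "fractions": list(r.observed_neutering.fractions),
            "median_fraction": r.observed_neutering.median_fraction,
            "population_model": r.observed_neutering.population_model,
        },
        "verdicts": dict(r.verdicts),
        "notes": list(r.notes),
    }


def report_from_json(text: str) -> AssessmentReport:
    """Rebuild an AssessmentReport from its JSON rendering."""
    d = json.loads(text)
    obs = d["observed_neutering"]
    return AssessmentReport(
        program_id=d["program_id"],
        config=d["config"],
        growth_vs_time=_fit_from_dict(d["growth_vs_time"]),
        growth_vs_surgeries=_fit_from_dict(d["growth_vs_surgeries"]),
        growth_vs_population=_fit_from_dict(d["growth_vs_population"]),
        pregnancy=_fit_from_dict(d["pregnancy"]),
        ricker=None if d["ricker"] is None else RickerParams(**d["ricker"]),
        survival=None if d["survival"] is None else SurvivalParams(**d["survival"]),
        critical=None if d["critical"] is None else CriticalRates(**d["critical"]),
        observed_neutering=None if obs is None else NeuteringSeries(
            years=obs["years"], fractions=obs["fractions"],
            median_fraction=obs["median_fraction"],
            population_model=obs["population_model"],
        ),
        verdicts=d["verdicts"],
        notes=d["notes"],
    )


def _fmt_p(p: float) -> str:
    if p < 0.005:
        return "p < 0.01"
    return f"p = {p:.2f}"


def _fmt_verdict(fit: Optional[RegressionFit], verdict: str) -> str:
    if verdict == "not_available" or fit is None:
        return "N/A"
    label = "significant decline" if verdict == "significant_decline" else "not significant"
    return f"{label} ({_fmt_p(fit.p_value)})"


def _fmt_opt(value: Optional[float], nd: int = 2) -> str:
    return "N/A" if value is None else f"{value:.{nd}f}"


def render_report(report: AssessmentReport, format: str = "text") -> str:
    """Serialize a report as ``text`` (Table-3-style), ``csv`` or ``json``.

    Identical reports render byte-identically; p-values and rates are
    displayed at 2 decimals, full precision is preserved in JSON.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)

    r = report
    rows = [
        ("Per capita growth rate over time",
         _fmt_verdict(r.growth_vs_time, r.verdicts["growth_vs_time"])),
        ("Per capita growth vs annual surgeries",
         _fmt_verdict(r.growth_vs_surgeries, r.verdicts["growth_vs_surgeries"])),
        ("Per capita growth vs population",
         _fmt_verdict(r.growth_vs_population, r.verdicts["growth_vs_population"])),
        ("Proportion of female cats pregnant",
         _fmt_verdict(r.pregnancy, r.verdicts["pregnancy"])),
        ("Maximum per capita growth rate, r_m",
         _fmt_opt(None if r.ricker is None else r.ricker.r_m)),
        ("Malthusian multiplier, R_m",
         _fmt_opt(None if r.ricker is None else r.ricker.R_m)),
        ("Index carrying capacity, K",
         _fmt_opt(None if r.ricker is None else r.ricker.K_index, 1)),
        ("Actual carrying capacity",
         _fmt_opt(None if r.ricker is None else r.ricker.K_actual, 1)),
        ("Annual survival rate, p",
         "N/A" if r.survival is None else
         f"{r.survival.p:.2f} ({r.survival.basis} lifespan "
         f"{r.survival.lifespan_years:g} y)"),
        ("Critical overall neutering rate",
         _fmt_opt(None if r.critical is None else r.critical.s)),
        ("Critical annual neutering rate",
         _fmt_opt(None if r.critical is None else r.critical.s_a)),
        ("Observed median annual neutering rate",
         _fmt_opt(None if r.observed_neutering is None
                  else r.observed_neutering.median_fraction)),
    ]

    if format == "csv":
        lines = ["metric,value"]
        for name, value in rows:
            lines.append(f"\"{name}\",\"{value}\"")
        return "\n".join(lines) + "\n"

    if format != "text":
        raise DataValidationError(f"unknown report format {format!r}")

    cfg = " | ".join(f"{k}={v}" for k, v in sorted(report.config.items()))
    width = max(len(name) for name, _ in rows) + 2
    lines = [
        f"Program assessment: {r.program_id}",
        f"config: {cfg}",
        "-" * 72,
    ]
    for name, value in rows:
        lines.append(f"{name:<{width}}{value}")
    if r.notes:
        lines.append("-" * 72)
        lines.extend(f"note: {n}" for n in r.notes)
    return "\n".join(lines) + "\n"
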