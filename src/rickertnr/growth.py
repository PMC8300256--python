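"""Annual per-capita growth rates from yearly count series.

The per-capita growth rate between consecutive years is the natural-log
ratio r_t = ln(N_{t+1} / N_t): dimensionless, per year, positive exactly
when the count grew. By default the rate is indexed by the *earlier* year
of the pair (r_1993 compares 1993 with 1994); the convention is recorded
on the output and can be flipped.

Pairs touching a zero or missing count have no defined log-ratio; those
rates are emitted as absent (``None``) with a note, never as ±inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .errors import AnalysisPreconditionError, DataValidationError
from .io import ProgramTimeSeries

__all__ = ["GrowthRateSeries", "per_capita_growth_rates"]


@dataclass
class GrowthRateSeries:
    """Per-capita growth rates aligned to years.

    ``basis`` records which counts were used (``"surgeries"`` or
    ``"census"``); ``convention`` records the year a rate is indexed by
    (``"earlier"``: r_t uses N_t and N_{t+1}).
    """

    years: list[int]
    rates: list[Optional[float]]
    basis: str = "surgeries"
    convention: str = "earlier"
    notes: list[str] = field(default_factory=list)

    def present(self) -> tuple[list[int], list[float]]:
        """Years and rates with absent entries dropped."""
        ys, rs = [], []
        for y, r in zip(self.years, self.rates):
            if r is not None:
                ys.append(y)
                rs.append(r)
        return ys, rs

    def __len__(self) -> int:
        return len(self.years)


def per_capita_growth_rates(
    counts: Union[ProgramTimeSeries, Sequence[Optional[float]]],
    years: Optional[Sequence[int]] = None,
    basis: str = "surgeries",
    convention: str = "earlier",
) -> GrowthRateSeries:
    """Compute r_t = ln(N_{t+1}/N_t) for consecutive year pairs.

    ``counts`` may be a :class:`~rickertnr.io.ProgramTimeSeries` (the
    column named by ``basis`` is used) or a plain sequence of counts with
    optional ``years``. A series of n counts yields n−1 rates; a rate is
    absent wherever either count in its pair is zero or missing.
    """
    if convention not in ("earlier", "later"):
        raise DataValidationError(f"unknown convention {convention!r}")
    if isinstance(counts, ProgramTimeSeries):
        if basis == "surgeries":
            values: list[Optional[float]] = [float(s) for s in counts.surgeries]
        elif basis == "census":
            values = [None if c is None else float(c) for c in counts.census]
        else:
            raise DataValidationError(f"unknown basis {basis!r}")
        yrs = list(counts.years)
    else:
        values = [None if v is None else float(v) for v in counts]
        yrs = list(years) if years is not None else list(range(1, len(values) + 1))
    if len(values) != len(yrs):
        raise DataValidationError("counts and years must have equal length")
    if len(values) < 2:
        raise AnalysisPreconditionError(
            "need at least 2 years of counts to compute a growth rate"
        )
    out_years: list[int] = []
    out_rates: list[Optional[float]] = []
    notes: list[str] = []
    for i in range(len(values) - 1):
        n0, n1 = values[i], values[i + 1]
        year = yrs[i] if convention == "earlier" else yrs[i + 1]
        if n0 is None or n1 is None or n0 == 0 or n1 == 0:
            out_rates.append(None)
            notes.append(
                f"rate for {year} absent: pair ({n0}, {n1}) contains a zero "
                "or missing count"
            )
        else:
            out_rates.append(math.log(n1 / n0))
        out_years.append(year)
    return GrowthRateSeries(
        years=out_years, rates=out_rates, basis=basis,
        convention=convention, notes=notes,
    )
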