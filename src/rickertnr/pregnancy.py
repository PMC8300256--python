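"""Monthly pregnancy proportions from per-cat surgery records.

Fecundity change is one of the four assessment criteria: if sterilization
is suppressing reproduction, the fraction of female cats found pregnant
at surgery should fall over the life of a program. Records are aggregated
per calendar month; the denominator is *all* females surgered that month
regardless of age (kittens included), males are never counted, and months
without a female surgery are simply absent.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import AnalysisPreconditionError, DataValidationError
from .io import CatRecord
from .regression import RegressionFit, proportion_trend

__all__ = ["PregnancySeries", "aggregate_pregnancy", "pregnancy_trend_test"]


@dataclass
class PregnancySeries:
    """Per-month female and pregnant-female surgery counts.

    ``periods`` are (year, month) pairs in chronological order; each
    period has at least one female record.
    """

    periods: list[tuple[int, int]]
    n_female: list[int]
    n_pregnant: list[int]

    def __post_init__(self) -> None:
        for (y, m), nf, np_ in zip(self.periods, self.n_female, self.n_pregnant):
            if not 0 <= np_ <= nf:
                raise DataValidationError(
                    f"period {y}-{m:02d}: pregnant count {np_} outside [0, {nf}]"
                )

    def month_index(self) -> list[int]:
        """Months elapsed since the first period (continuous time axis)."""
        y0, m0 = self.periods[0]
        return [(y - y0) * 12 + (m - m0) for y, m in self.periods]

    def proportions(self) -> list[float]:
        return [p / f for p, f in zip(self.n_pregnant, self.n_female)]

    def __len__(self) -> int:
        return len(self.periods)


def aggregate_pregnancy(records: Iterable[CatRecord]) -> PregnancySeries:
    """Aggregate surgery records into a monthly pregnancy series.

    One row per calendar month containing at least one female surgery.
    """
    females: dict[tuple[int, int], int] = defaultdict(int)
    pregnant: dict[tuple[int, int], int] = defaultdict(int)
    n = 0
    for rec in records:
        n += 1
        if rec.sex != "female":
            continue
        key = (rec.year, rec.month)
        females[key] += 1
        if rec.pregnant:
            pregnant[key] += 1
    if n == 0:
        raise DataValidationError("no records supplied")
    periods = sorted(females)
    return PregnancySeries(
        periods=periods,
        n_female=[females[p] for p in periods],
        n_pregnant=[pregnant[p] for p in periods],
    )


def pregnancy_trend_test(
    series: PregnancySeries, yearly: bool = False
) -> RegressionFit:
    """OLS trend of the pregnancy proportion over time.

    Time is a continuous month index by default; with ``yearly=True``
    the counts are first pooled per calendar year.
    """
    if len(series) < 3:
        raise AnalysisPreconditionError(
            f"need at least 3 periods for a trend test, got {len(series)}"
        )
    if yearly:
        fem: dict[int, int] = defaultdict(int)
        preg: dict[int, int] = defaultdict(int)
        for (y, _m), nf, np_ in zip(series.periods, series.n_female, series.n_pregnant):
            fem[y] += nf
            preg[y] += np_
        years = sorted(fem)
        return proportion_trend(
            [preg[y] for y in years], [fem[y] for y in years], years
        )
    return proportion_trend(series.n_pregnant, series.n_female, series.month_index())
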