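"""Reading, writing and bundled fixtures for TNR program data.

Two plain-text formats are supported, both comma-separated with a header
row and case-insensitive column names:

* **program series** — one row per calendar year with columns
  ``year``, ``surgeries`` and optional ``census`` / ``removals``.
  Surgeries are the annual sterilization count, used throughout the
  pipeline as the population index N_t; census is a direct count of the
  free-roaming population where one exists.
* **per-cat records** — one row per surgery with columns
  ``year``, ``month``, ``sex``, ``pregnant``, ``age_months``, ``outcome``.

Empty cells mean *missing*; the string ``"0"`` always means a true zero
count. Typographic minus signs (U+2212), as used in the source tables,
are normalized to ASCII on read.

The bundled fixtures encode the published San Diego / Alachua surgery
tables (with their printed growth-rate columns kept verbatim) and the
four named Ricker simulation parameter sets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import DataValidationError

__all__ = [
    "ProgramTimeSeries",
    "CatRecord",
    "SimulationInputs",
    "read_program_series",
    "write_program_series",
    "read_cat_records",
    "write_cat_records",
    "load_fixture",
    "printed_growth_rates",
    "available_fixtures",
    "fixture_path",
    "fixture_checksum",
]

_MINUS = "−"

_PROGRAM_FIXTURES = ("san_diego", "alachua")
_ALL_FIXTURES = _PROGRAM_FIXTURES + ("table2_params",)


@dataclass
class ProgramTimeSeries:
    """Annual records of a TNR program.

    ``surgeries`` must be present for every year and serves as the
    population index N_t. ``census`` and ``removals`` are optional
    per-year counts; a ``None`` entry means the value was not recorded
    that year (never an implicit zero).
    """

    program_id: str
    years: list[int]
    surgeries: list[int]
    census: list[Optional[int]] = field(default=None)  # type: ignore[assignment]
    removals: list[Optional[int]] = field(default=None)  # type: ignore[assignment]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.years)
        self.years = [int(y) for y in self.years]
        if len(self.surgeries) != n:
            raise DataValidationError(
                f"surgeries has {len(self.surgeries)} entries for {n} years"
            )
        if self.census is None:
            self.census = [None] * n
        if self.removals is None:
            self.removals = [None] * n
        if len(self.census) != n or len(self.removals) != n:
            raise DataValidationError("census/removals length must match years")
        seen: set[int] = set()
        for y in self.years:
            if y in seen:
                raise DataValidationError(f"duplicate year {y} in program series")
            seen.add(y)
        order = sorted(range(n), key=lambda i: self.years[i])
        if order != list(range(n)):
            self.years = [self.years[i] for i in order]
            self.surgeries = [self.surgeries[i] for i in order]
            self.census = [self.census[i] for i in order]
            self.removals = [self.removals[i] for i in order]
        for label, col in (("surgeries", self.surgeries),
                           ("census", self.census),
                           ("removals", self.removals)):
            for y, v in zip(self.years, col):
                if v is not None and v < 0:
                    raise DataValidationError(
                        f"negative {label} count {v} in year {y}"
                    )
        gaps = [
            (a, b) for a, b in zip(self.years, self.years[1:]) if b != a + 1
        ]
        for a, b in gaps:
            msg = f"non-consecutive years: gap between {a} and {b}"
            if msg not in self.notes:
                self.notes.append(msg)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def has_census(self) -> bool:
        return any(c is not None for c in self.census)

    def census_years(self) -> list[tuple[int, int]]:
        """(year, count) pairs for the years with a census."""
        return [(y, c) for y, c in zip(self.years, self.census) if c is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "surgeries": self.surgeries,
                "census": [c if c is not None else pd.NA for c in self.census],
                "removals": [r if r is not None else pd.NA for r in self.removals],
            }
        )


@dataclass(frozen=True)
class CatRecord:
    """A single sterilization surgery record.

    ``pregnant`` is meaningful only for females at time of surgery; it is
    always False for males. Ages are in months (kittens included).
    """

    year: int
    month: int
    sex: str  # "female" | "male"
    pregnant: bool
    age_months: float
    outcome: str  # "returned" | "adopted" | "euthanized" | "died"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise DataValidationError(f"unknown sex {self.sex!r}")
        if self.pregnant and self.sex != "female":
            raise DataValidationError("pregnant=True requires sex=female")
        if self.age_months < 0:
            raise DataValidationError("age_months must be >= 0")
        if not 1 <= self.month <= 12:
            raise DataValidationError(f"month {self.month} outside 1..12")


@dataclass(frozen=True)
class SimulationInputs:
    """One row of the published simulation-parameter table."""

    program: str
    R_m: float
    K: float
    N_1: float


def _normalize(text: str) -> str:
    return text.replace(_MINUS, "-").strip()


def _read_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    return df.map(_normalize)


def _parse_count(cell: str, column: str, year: str) -> Optional[int]:
    if cell == "":
        return None
    try:
        value = int(float(cell))
    except ValueError as exc:
        raise DataValidationError(
            f"non-numeric {column} value {cell!r} in year {year}"
        ) from exc
    return value


def read_program_series(
    path: Union[str, Path], program_id: Optional[str] = None
) -> ProgramTimeSeries:
    """Read a program time series from a CSV file.

    The header must name ``year`` and ``surgeries`` columns (any case);
    ``census`` and ``removals`` are optional. Rows are sorted by year.
    Duplicate years and negative counts raise
    :class:`~rickertnr.errors.DataValidationError`; year gaps are recorded
    as a note on the returned series, not silently filled.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    df = _read_csv(path)
    for required in ("year", "surgeries"):
        if required not in df.columns:
            raise DataValidationError(
                f"{path}: missing required column {required!r} "
                f"(found {list(df.columns)})"
            )
    years, surgeries, census, removals = [], [], [], []
    for _, row in df.iterrows():
        ytxt = row["year"]
        try:
            year = int(ytxt)
        except ValueError as exc:
            raise DataValidationError(f"{path}: non-integer year {ytxt!r}") from exc
        surg = _parse_count(row["surgeries"], "surgeries", ytxt)
        if surg is None:
            raise DataValidationError(f"{path}: missing surgeries in year {year}")
        years.append(year)
        surgeries.append(surg)
        census.append(
            _parse_count(row["census"], "census", ytxt) if "census" in df.columns else None
        )
        removals.append(
            _parse_count(row["removals"], "removals", ytxt)
            if "removals" in df.columns
            else None
        )
    return ProgramTimeSeries(
        program_id=program_id or path.stem,
        years=years,
        surgeries=surgeries,
        census=census,
        removals=removals,
    )


def write_program_series(series: ProgramTimeSeries, path: Union[str, Path]) -> None:
    """Write a program series as CSV (empty cells for missing values)."""
    lines = ["year,surgeries,census,removals"]
    for y, s, c, r in zip(series.years, series.surgeries, series.census, series.removals):
        cc = "" if c is None else str(c)
        rr = "" if r is None else str(r)
        lines.append(f"{y},{s},{cc},{rr}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_cat_records(path: Union[str, Path]) -> list[CatRecord]:
    """Read per-cat surgery records from CSV."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    df = _read_csv(path)
    required = ("year", "month", "sex", "pregnant", "age_months", "outcome")
    for col in required:
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        preg = row["pregnant"].lower()
        if preg in _TRUE:
            pregnant = True
        elif preg in _FALSE:
            pregnant = False
        else:
            raise DataValidationError(f"{path}: bad pregnant value {row['pregnant']!r}")
        records.append(
            CatRecord(
                year=int(row["year"]),
                month=int(row["month"]),
                sex=row["sex"].lower(),
                pregnant=pregnant,
                age_months=float(row["age_months"]),
                outcome=row["outcome"].lower(),
            )
        )
    return records


def write_cat_records(records: Iterable[CatRecord], path: Union[str, Path]) -> None:
    lines = ["year,month,sex,pregnant,age_months,outcome"]
    for r in records:
        lines.append(
            f"{r.year},{r.month},{r.sex},{str(r.pregnant).lower()},"
            f"{r.age_months:g},{r.outcome}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# bundled fixtures


def fixture_path(name: str) -> Path:
    if name not in _ALL_FIXTURES:
        raise DataValidationError(
            f"unknown fixture {name!r}; available: {', '.join(_ALL_FIXTURES)}"
        )
    return Path(str(resources.files("rickertnr").joinpath(f"data/{name}.csv")))


def available_fixtures() -> tuple[str, ...]:
    return _ALL_FIXTURES


def load_fixture(
    name: str,
) -> Union[ProgramTimeSeries, dict[str, SimulationInputs]]:
    """Load a bundled fixture by name.

    ``san_diego`` and ``alachua`` return the published surgery series as a
    :class:`ProgramTimeSeries`; ``table2_params`` returns the four named
    simulation parameter sets as a mapping
    ``program -> SimulationInputs(R_m, K, N_1)``.
    """
    path = fixture_path(name)
    if name in _PROGRAM_FIXTURES:
        return read_program_series(path, program_id=name)
    df = _read_csv(path)
    return {
        row["program"]: SimulationInputs(
            program=row["program"],
            R_m=float(row["r_m"]),
            K=float(row["k"]),
            N_1=float(row["n_1"]),
        )
        for _, row in df.iterrows()
    }


def printed_growth_rates(name: str) -> dict[int, float]:
    """The growth-rate column printed alongside a fixture's surgeries.

    These are the *published* per-year rates, stored verbatim. For some
    years they are inconsistent with the published surgeries column (a
    documented defect of the source tables); they are kept for comparison,
    never used as analysis input.
    """
    if name not in _PROGRAM_FIXTURES:
        raise DataValidationError(
            f"no printed growth-rate column for fixture {name!r}"
        )
    df = _read_csv(fixture_path(name))
    out: dict[int, float] = {}
    for _, row in df.iterrows():
        if row["growth_rate"] != "":
            out[int(row["year"])] = float(row["growth_rate"])
    return out


def fixture_checksum(name: str) -> str:
    """SHA-256 of the raw fixture file, for immutability checks."""
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
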