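"""Tabular input formats, ICD-10 cause grouping, and death-count aggregation.

Death records arrive as individual registrations (sex, completed age at
death, ICD-10 cause, municipality of registration, date). Population
denominators arrive as registry counts by district, sex, single year of age
and calendar year, following the March-31 registry convention. Municipalities
are consolidated into analysis districts through a :class:`DistrictMap`, and
deaths are aggregated into a :class:`DeathCountCube` indexed by analysis
period, district, sex, age and cause group.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MAX_AGE = 110

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")

#: Sentinel cause labels used alongside configured groups in count cubes.
ALL_CAUSES = "all"
OTHER_CAUSES = "other"


class SchemaError(ValueError):
    """Input file does not match the expected column layout."""


class RowError(ValueError):
    """A data row failed validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class DeathRecord:
    """One registered death."""

    sex: str
    age_at_death: int
    icd10: str
    municipality: str
    death_date: _dt.date

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0 <= self.age_at_death <= MAX_AGE):
            raise ValueError(f"age_at_death {self.age_at_death} outside [0, {MAX_AGE}]")
        if not ICD10_PATTERN.match(self.icd10):
            raise ValueError(f"malformed ICD-10 code {self.icd10!r}")


@dataclass(frozen=True)
class CauseGroup:
    """A named group of inclusive 3-character ICD-10 ranges.

    Ranges are pairs of 3-character codes sharing the same letter, e.g.
    ``("I05", "I09")``. Subcodes beyond the 3-character root never affect
    membership.
    """

    name: str
    ranges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seen: list[tuple[str, int, int]] = []
        for lo, hi in self.ranges:
            if not (re.match(r"^[A-Z][0-9]{2}$", lo) and re.match(r"^[A-Z][0-9]{2}$", hi)):
                raise ValueError(f"range endpoints must be 3-character codes: {lo}-{hi}")
            if lo[0] != hi[0]:
                raise ValueError(f"range endpoints must share a letter: {lo}-{hi}")
            a, b = int(lo[1:]), int(hi[1:])
            if a > b:
                raise ValueError(f"descending range {lo}-{hi}")
            for letter, x, y in seen:
                if letter == lo[0] and not (b < x or a > y):
                    raise ValueError(f"overlapping ranges within group {self.name!r}")
            seen.append((lo[0], a, b))


#: The four major cause-of-death groups analysed, at 3-character resolution:
#: heart diseases I05–I09, I20–I25, I30–I52; cerebrovascular disease I60–I69;
#: pneumonia J12–J18; all cancers C00–C97.
DEFAULT_CAUSE_GROUPS: tuple[CauseGroup, ...] = (
    CauseGroup("cancer", (("C00", "C97"),)),
    CauseGroup("heart", (("I05", "I09"), ("I20", "I25"), ("I30", "I52"))),
    CauseGroup("cerebrovascular", (("I60", "I69"),)),
    CauseGroup("pneumonia", (("J12", "J18"),)),
)


def match_cause_group(icd10: str, group: CauseGroup) -> bool:
    """Return True iff the 3-character root of *icd10* falls in any of the
    group's inclusive ranges. Subcodes (e.g. ``C34.1``) are ignored."""
    root = icd10.split(".")[0]
    if not re.match(r"^[A-Z][0-9]{2}$", root):
        raise ValueError(f"malformed ICD-10 code {icd10!r}")
    letter, num = root[0], int(root[1:])
    for lo, hi in group.ranges:
        if letter == lo[0] and int(lo[1:]) <= num <= int(hi[1:]):
            return True
    return False


def classify_cause(icd10: str, groups: Sequence[CauseGroup]) -> str:
    """First matching group's name, or ``"other"``. Groups are validated to be
    disjoint at configuration time, so first-match-wins is deterministic."""
    for g in groups:
        if match_cause_group(icd10, g):
            return g.name
    return OTHER_CAUSES


def validate_disjoint(groups: Sequence[CauseGroup]) -> None:
    """Raise if any 3-character code belongs to more than one group."""
    for letter_num in _all_roots(groups):
        hits = [g.name for g in groups if match_cause_group(letter_num, g)]
        if len(hits) > 1:
            raise ValueError(f"code {letter_num} matched by multiple groups: {hits}")


def _all_roots(groups: Sequence[CauseGroup]) -> Iterable[str]:
    for g in groups:
        for lo, hi in g.ranges:
            for n in range(int(lo[1:]), int(hi[1:]) + 1):
                yield f"{lo[0]}{n:02d}"


@dataclass
class DistrictMap:
    """Municipality → district assignment plus per-district evacuation flags."""

    municipality_to_district: dict[str, int]
    evacuation: dict[int, bool]

    def __post_init__(self):
        mapped = set(self.municipality_to_district.values())
        flagged = set(self.evacuation)
        if mapped != flagged:
            raise ValueError(
                f"district ids in mapping {sorted(mapped)} != ids with evacuation "
                f"flags {sorted(flagged)}"
            )

    @property
    def districts(self) -> list[int]:
        return sorted(self.evacuation)

    def district_of(self, municipality: str) -> int:
        try:
            return self.municipality_to_district[municipality]
        except KeyError:
            raise KeyError(f"unknown municipality code {municipality!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DistrictMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        m2d = {str(k): int(v) for k, v in raw["municipality_to_district"].items()}
        evac = {int(k): bool(v) for k, v in raw["evacuation"].items()}
        return cls(m2d, evac)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "municipality_to_district": self.municipality_to_district,
                    "evacuation": {k: bool(v) for k, v in self.evacuation.items()},
                },
                fh,
            )


class PopulationTable:
    """Registry population counts keyed by (district, sex, age, year).

    Counts follow the resident-registry convention (head count as of March 31
    of each calendar year, foreign residents included).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"district", "sex", "age", "year", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"population table missing columns {sorted(missing)}")
        if (frame["count"] < 0).any():
            bad = frame.loc[frame["count"] < 0].iloc[0]
            raise ValueError(f"negative population count at {tuple(bad[:4])}")
        keys = frame[["district", "sex", "age", "year"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate population cell {tuple(dup)}")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def counts_by_age(
        self,
        sex: str,
        years: Iterable[int],
        district: int | None = None,
        max_age: int = MAX_AGE,
    ) -> "pd.DataFrame":
        """Age × year matrix of counts (ages 0..max_age), summed over districts
        when *district* is None (prefecture level)."""
        f = self._frame
        sel = (f["sex"] == sex) & f["year"].isin(list(years))
        if district is not None:
            sel &= f["district"] == district
        sub = f.loc[sel]
        mat = sub.pivot_table(index="age", columns="year", values="count", aggfunc="sum")
        mat = mat.reindex(range(max_age + 1), fill_value=0).fillna(0.0)
        return mat

    def write_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PopulationTable":
        return read_population(path)


def read_population(path: str | Path) -> PopulationTable:
    """Read a population CSV with columns district,sex,age,year,count."""
    frame = pd.read_csv(path)
    return PopulationTable(frame)


class DeathCountCube:
    """Death counts keyed by (period, district, sex, age, cause bucket).

    Cause buckets are the configured group names plus ``other``; ``all`` holds
    the all-cause count and always equals the sum of the named groups and
    ``other`` for the same cell.
    """

    def __init__(self, cause_names: Sequence[str]):
        self.cause_names = list(cause_names)
        self._counts: dict[tuple, int] = {}

    def add(self, period: str, district: int, sex: str, age: int, cause: str, n: int = 1):
        if cause not in self.cause_names and cause not in (ALL_CAUSES, OTHER_CAUSES):
            raise KeyError(f"unknown cause bucket {cause!r}")
        key = (period, district, sex, age, cause)
        self._counts[key] = self._counts.get(key, 0) + n

    def get(self, period: str, district: int | None, sex: str, age: int, cause: str) -> int:
        """Count for one cell; district None sums over districts."""
        if district is not None:
            return self._counts.get((period, district, sex, age, cause), 0)
        return sum(
            v
            for (p, _d, s, a, c), v in self._counts.items()
            if p == period and s == sex and a == age and c == cause
        )

    def counts_by_age(
        self,
        period: str,
        sex: str,
        cause: str = ALL_CAUSES,
        district: int | None = None,
        max_age: int = MAX_AGE,
    ):
        import numpy as np

        out = np.zeros(max_age + 1)
        for (p, d, s, a, c), v in self._counts.items():
            if p == period and s == sex and c == cause and (district is None or d == district):
                out[min(a, max_age)] += v
        return out

    def total(self, period: str | None = None, cause: str = ALL_CAUSES) -> int:
        return sum(
            v
            for (p, _d, _s, _a, c), v in self._counts.items()
            if c == cause and (period is None or p == period)
        )

    def validate(self) -> None:
        """Check the cause-decomposition identity for every populated cell."""
        cells = {(p, d, s, a) for (p, d, s, a, _c) in self._counts}
        for p, d, s, a in cells:
            parts = sum(
                self._counts.get((p, d, s, a, c), 0)
                for c in (*self.cause_names, OTHER_CAUSES)
            )
            allc = self._counts.get((p, d, s, a, ALL_CAUSES), 0)
            if parts != allc:
                raise ValueError(
                    f"cause decomposition broken at {(p, d, s, a)}: "
                    f"groups+other={parts} != all={allc}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"period": p, "district": d, "sex": s, "age": a, "cause": c, "count": v}
            for (p, d, s, a, c), v in sorted(self._counts.items())
        ]
        return pd.DataFrame(rows, columns=["period", "district", "sex", "age", "cause", "count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cause_names: Sequence[str]) -> "DeathCountCube":
        cube = cls(cause_names)
        for row in frame.itertuples(index=False):
            cube.add(row.period, row.district, row.sex, int(row.age), row.cause, int(row.count))
        return cube


def cube_from_counts(
    counts: pd.DataFrame,
    periods: Mapping[str, tuple[int, int]],
    cause_names: Sequence[str],
) -> DeathCountCube:
    """Build a DeathCountCube from annual cell counts.

    ``counts`` has columns district, sex, age, year, cause, count, with cause
    in the configured group names plus ``other``. Years are mapped to
    periods; out-of-period rows are dropped. The ``all`` bucket is derived.
    """
    spans = list(periods.items())
    cube = DeathCountCube(list(cause_names))
    for row in counts.itertuples(index=False):
        period = next((n for n, (lo, hi) in spans if lo <= int(row.year) <= hi), None)
        if period is None:
            continue
        n = int(row.count)
        cube.add(period, int(row.district), row.sex, int(row.age), row.cause, n)
        cube.add(period, int(row.district), row.sex, int(row.age), ALL_CAUSES, n)
    cube.validate()
    return cube


DEFAULT_DEATH_SCHEMA: Mapping[str, str] = {
    "sex": "sex",
    "age": "age",
    "icd10": "icd10",
    "municipality": "municipality",
    "date": "date",
}


def read_death_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    excluded_years: frozenset[int] | set[int] = frozenset({2011}),
    strict: bool = True,
) -> list[DeathRecord]:
    """Read individual death registrations from CSV.

    Rows whose death year falls in *excluded_years* are dropped (and counted
    in a log summary); the registry's disaster year is excluded by default so
    the pre- and post-disaster periods can be contrasted cleanly. In strict
    mode any unparseable row raises :class:`RowError` with its line number;
    otherwise bad rows are skipped and logged.
    """
    schema = dict(DEFAULT_DEATH_SCHEMA if schema is None else schema)
    frame = pd.read_csv(path, dtype=str)
    missing = set(schema.values()) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    records: list[DeathRecord] = []
    n_excluded = 0
    n_bad = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        try:
            raw = {k: getattr(row, col) for k, col in schema.items()}
            date = _dt.date.fromisoformat(str(raw["date"]))
            if date.year in excluded_years:
                n_excluded += 1
                continue
            rec = DeathRecord(
                sex=str(raw["sex"]).strip().lower(),
                age_at_death=int(raw["age"]),
                icd10=str(raw["icd10"]).strip(),
                municipality=str(raw["municipality"]).strip(),
                death_date=date,
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowError(line, str(exc)) from exc
            n_bad += 1
            logger.warning("skipping bad row at line %d: %s", line, exc)
            continue
        records.append(rec)
    logger.info(
        "read %d death records from %s (%d excluded by year, %d bad rows skipped)",
        len(records),
        path,
        n_excluded,
        n_bad,
    )
    return records


def write_death_records(records: Iterable[DeathRecord], path: str | Path) -> None:
    rows = [
        {
            "sex": r.sex,
            "age": r.age_at_death,
            "icd10": r.icd10,
            "municipality": r.municipality,
            "date": r.death_date.isoformat(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["sex", "age", "icd10", "municipality", "date"]).to_csv(
        path, index=False
    )


def aggregate_deaths(
    records: Iterable[DeathRecord],
    dmap: DistrictMap,
    periods: Mapping[str, tuple[int, int]],
    groups: Sequence[CauseGroup] = DEFAULT_CAUSE_GROUPS,
) -> DeathCountCube:
    """Consolidate individual records into a period × district × sex × age ×
    cause count cube.

    Each in-period record increments the ``all`` bucket and exactly one cause
    bucket (first matching configured group, else ``other``). All deaths count
    toward all-cause regardless of cause group. Records dated outside every
    period are dropped with a logged count.
    """
    validate_disjoint(groups)
    spans = list(periods.items())
    for i, (_na, (a0, a1)) in enumerate(spans):
        if a0 > a1:
            raise ValueError(f"descending period {a0}-{a1}")
        for _nb, (b0, b1) in spans[i + 1 :]:
            if not (a1 < b0 or b1 < a0):
                raise ValueError("periods must be disjoint")

    cube = DeathCountCube([g.name for g in groups])
    n_out = 0
    for rec in records:
        year = rec.death_date.year
        period = next((name for name, (lo, hi) in spans if lo <= year <= hi), None)
        if period is None:
            n_out += 1
            continue
        district = dmap.district_of(rec.municipality)
        cause = classify_cause(rec.icd10, groups)
        cube.add(period, district, rec.sex, rec.age_at_death, ALL_CAUSES)
        cube.add(period, district, rec.sex, rec.age_at_death, cause)
    if n_out:
        logger.info("dropped %d records outside all analysis periods", n_out)
    cube.validate()
    return cube
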