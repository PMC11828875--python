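"""Cause-deleted life tables and years of life lost (YLL).

A cause's age-specific share of mortality f_x = (cause-i deaths)/(all deaths)
is removed from the all-cause schedule with Chiang's proportional-elimination
formula

    q_x^{-i} = 1 - (1 - q_x)^{1 - f_x},

the standard cause-eliminated life-table construction: it corresponds to
scaling the age-x force of mortality by (1 - f_x), i.e. drawing the survival
curve the population would follow if the cause did not operate. YLL at age x
is the gap between the two expectancies,

    YLL(x) = e_x^{-i} - e_x,

equivalently the area between the cause-deleted and all-cause survival
curves above x (per survivor at x). It is non-negative by construction.

A naive alternative that subtracts the cause's deaths from the numerator of
q_x (``method="subtract"``) is provided for sensitivity only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from lifeyears.io_formats import ALL_CAUSES, CauseGroup, DeathCountCube
from lifeyears.lifetable import LifeTable, QSchedule, build_life_table

YLL_AGES_DEFAULT: tuple[int, ...] = (0, 40, 65)


@dataclass
class CauseFractions:
    """Per-age share of all-cause deaths attributable to one cause."""

    f: np.ndarray
    cause: str
    stratum: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("cause fractions must lie in [0, 1]")


def cause_fraction_arrays(
    cause_deaths: np.ndarray,
    all_deaths: np.ndarray,
    cause: str = "",
    stratum: Mapping[str, object] | None = None,
) -> CauseFractions:
    """f_x = cause deaths / all deaths, with f_x = 0 where no deaths occurred."""
    c = np.asarray(cause_deaths, dtype=float)
    a = np.asarray(all_deaths, dtype=float)
    if c.shape != a.shape:
        raise ValueError("cause and all-cause arrays must have identical shape")
    if np.any(c > a):
        bad = int(np.argmax(c > a))
        raise ValueError(f"age {bad}: cause deaths {c[bad]:g} exceed all-cause {a[bad]:g}")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(a > 0, c / np.where(a > 0, a, 1.0), 0.0)
    return CauseFractions(f=f, cause=cause, stratum=dict(stratum or {}))


def cause_fraction(
    cube: DeathCountCube,
    period: str,
    sex: str,
    group: CauseGroup | str,
    district: int | None = None,
    max_age: int = 110,
    carry_from: int = 94,
) -> CauseFractions:
    """Cause fractions for one stratum of a death-count cube.

    Above ``carry_from`` (where the mortality schedule itself is extrapolated
    and cause-specific counts are sparse) the fraction observed at the last
    reliable age is carried forward.
    """
    name = group.name if isinstance(group, CauseGroup) else group
    c = cube.counts_by_age(period, sex, cause=name, district=district, max_age=max_age)
    a = cube.counts_by_age(period, sex, cause=ALL_CAUSES, district=district, max_age=max_age)
    cf = cause_fraction_arrays(c, a, cause=name, stratum={"period": period, "sex": sex})
    if carry_from is not None and carry_from < max_age:
        cf.f[carry_from + 1 :] = cf.f[carry_from]
    return cf


def delete_cause(qs: QSchedule, fractions: CauseFractions, method: str = "chiang") -> QSchedule:
    """Build the cause-deleted mortality schedule.

    The open-age closure q_omega = 1 is preserved: the deleted population
    still dies eventually, it just escapes the deleted cause before omega.
    """
    f = np.asarray(fractions.f, dtype=float)
    if f.shape != qs.q.shape:
        raise ValueError("fractions must cover the same ages as the schedule")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("cause fractions must lie in [0, 1]")
    out = qs.copy()
    if method == "chiang":
        out.q = 1.0 - np.power(1.0 - qs.q, 1.0 - f)
    elif method == "subtract":
        out.q = np.clip(qs.q * (1.0 - f), 0.0, 1.0)
    else:
        raise ValueError(f"unknown deletion method {method!r}")
    if qs.q[-1] == 1.0:
        out.q[-1] = 1.0
    out.stratum = dict(qs.stratum)
    out.stratum["deleted_cause"] = fractions.cause
    return out


@dataclass
class YLLResult:
    """Years of life lost to one cause at the reporting ages."""

    cause: str
    yll: dict[int, float]
    table_all: LifeTable
    table_deleted: LifeTable
    stratum: Mapping[str, object] = field(default_factory=dict)


def yll(
    qs_all: QSchedule,
    qs_deleted: QSchedule,
    ages: Sequence[int] = YLL_AGES_DEFAULT,
    radix: float = 100_000.0,
    a_schedule: np.ndarray | None = None,
    cause: str = "",
) -> YLLResult:
    """YLL(x) = e_x(deleted) - e_x(all-cause), both tables built with
    identical radix and a-schedule conventions."""
    if qs_all.omega != qs_deleted.omega:
        raise ValueError("schedules must share the open age omega")
    if qs_all.stratum and qs_deleted.stratum:
        keys = ("period", "sex", "district")
        for k in keys:
            va, vd = qs_all.stratum.get(k), qs_deleted.stratum.get(k)
            if va is not None and vd is not None and va != vd:
                raise ValueError(f"mismatched strata: {k} {va!r} vs {vd!r}")
    lt_all = build_life_table(qs_all, radix=radix, a_schedule=a_schedule)
    lt_del = build_life_table(qs_deleted, radix=radix, a_schedule=a_schedule)
    out = {int(x): float(lt_del.e[x] - lt_all.e[x]) for x in ages}
    label = cause or str(qs_deleted.stratum.get("deleted_cause", ""))
    return YLLResult(
        cause=label,
        yll=out,
        table_all=lt_all,
        table_deleted=lt_del,
        stratum=dict(qs_all.stratum),
    )


def write_yll_csv(results: Sequence[YLLResult], path) -> None:
    """CSV rows (stratum labels, cause, age, yll_years)."""
    import pandas as pd

    rows = []
    for r in results:
        for age, value in sorted(r.yll.items()):
            rows.append(
                {
                    "period": r.stratum.get("period", ""),
                    "sex": r.stratum.get("sex", ""),
                    "district": r.stratum.get("district", ""),
                    "cause": r.cause,
                    "age": age,
                    "yll_years": value,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
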