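"""District characteristics, period changes, and effect sizes.

Municipality-level characteristics (2010 baseline) are consolidated to
analysis districts by population-weighted averaging, except the financial
capability index which is a simple mean of municipal values. Changes in LE
and YLL relative to the pre-disaster period are compared across districts
with Pearson correlations; the evacuation/non-evacuation contrast uses the
pooled-variance two-sample t and its point-biserial correlation

    r = t / sqrt(t^2 + df),   df = n1 + n2 - 2,

which equals the Pearson correlation of the outcome against the 0/1
evacuation code. An effect is flagged as meaningful when |r| > 0.5; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifeyears.io_formats import DistrictMap

#: Characteristics averaged with population weights; the financial capability
#: index is deliberately excluded (simple mean of municipal values).
WEIGHTED_FIELDS = (
    "population_density",
    "income_per_capita",
    "medical_professionals",
    "medical_institutions",
    "pct_primary_industry",
    "pct_aged_65plus",
    "natural_growth_rate",
    "net_migration_rate",
)
SIMPLE_MEAN_FIELDS = ("financial_capability_index",)

EFFECT_SIZE_THRESHOLD = 0.5


@dataclass(frozen=True)
class EffectSizeResult:
    variable: str
    outcome: str
    r: float
    t: float
    df: int
    p: float

    def __post_init__(self):
        if not -1.0000001 <= self.r <= 1.0000001:
            raise ValueError("correlation outside [-1, 1]")

    @property
    def significant(self) -> bool:
        """The |r| > 0.5 large-effect rule."""
        return abs(self.r) > EFFECT_SIZE_THRESHOLD


def aggregate_characteristics(
    muni_table: pd.DataFrame,
    dmap: DistrictMap,
) -> pd.DataFrame:
    """Consolidate municipality characteristics to districts.

    ``muni_table`` needs columns ``municipality``, ``population``, and the
    characteristic fields. Returns one row per district with the evacuation
    indicator attached.
    """
    required = {"municipality", "population", *WEIGHTED_FIELDS, *SIMPLE_MEAN_FIELDS}
    missing = required - set(muni_table.columns)
    if missing:
        raise ValueError(f"municipality table missing columns {sorted(missing)}")
    t = muni_table.copy()
    t["district"] = [dmap.district_of(str(m)) for m in t["municipality"]]

    rows = []
    for district, sub in t.groupby("district"):
        w = sub["population"].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"district {district}: zero total population")
        row: dict[str, object] = {"district": int(district), "population": float(w.sum())}
        for fieldname in WEIGHTED_FIELDS:
            row[fieldname] = float(np.average(sub[fieldname], weights=w))
        for fieldname in SIMPLE_MEAN_FIELDS:
            row[fieldname] = float(sub[fieldname].mean())
        row["evacuation"] = int(dmap.evacuation[int(district)])
        rows.append(row)
    return pd.DataFrame(rows).sort_values("district").reset_index(drop=True)


def delta_vs_pre(metric_by_period: Mapping[str, float], pre: str = "pre") -> dict[str, float]:
    """Change of each post period relative to the pre-disaster value."""
    if pre not in metric_by_period:
        raise KeyError(f"missing pre-disaster period {pre!r}")
    base = metric_by_period[pre]
    return {p: v - base for p, v in metric_by_period.items() if p != pre}


def effect_size_continuous(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "x",
    outcome: str = "y",
) -> EffectSizeResult:
    """Pearson correlation of a district characteristic against a change,
    with its t statistic (df = n - 2) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 districts")
    if np.ptp(x) == 0:
        raise ValueError(f"characteristic {variable!r} is constant")
    r, p = stats.pearsonr(x, y)
    df = n - 2
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0:
        t = r * np.sqrt(df / (1.0 - r * r))
    else:
        t = np.inf * np.sign(r)
    return EffectSizeResult(variable=variable, outcome=outcome, r=r, t=float(t), df=df, p=float(p))


def group_compare(
    evac: Sequence[float],
    nonevac: Sequence[float],
    outcome: str = "y",
) -> EffectSizeResult:
    """Pooled-variance two-sample t and point-biserial r for the evacuation
    contrast.

    r > 0 means the evacuation group's outcome is larger; numerically
    identical to :func:`effect_size_continuous` with a 0/1 evacuation code.
    """
    a = np.asarray(evac, dtype=float)
    b = np.asarray(nonevac, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 districts")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    r = float(t / np.sqrt(t * t + df)) if np.isfinite(t) else float(np.sign(t))
    return EffectSizeResult(
        variable="evacuation", outcome=outcome, r=r, t=float(t), df=df, p=float(p)
    )


def values_from_summary(mean: float, sd: float, n: int) -> np.ndarray:
    """A value set with exactly the given mean and sample SD (n-1 denominator).

    Used to reconstruct group samples from published summary statistics:
    symmetric +/- sd pairs around the mean (plus a centre point when n is
    odd) reproduce the summary exactly, and the pooled t depends on the
    groups only through these summaries.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    half = n // 2
    vals = [mean + sd, mean - sd] * half
    if n % 2:
        vals.append(mean)
    v = np.array(vals, dtype=float)
    # symmetric pairs give sum of squared deviations 2*half*sd^2; rescale so
    # the sample SD is exact for any n
    dev = v - mean
    ss = np.sum(dev**2)
    target = (n - 1) * sd**2
    if ss > 0:
        v = mean + dev * np.sqrt(target / ss)
    return v


def effects_table(
    characteristics: pd.DataFrame,
    deltas: pd.DataFrame,
    char_fields: Sequence[str] = (*WEIGHTED_FIELDS, *SIMPLE_MEAN_FIELDS, "evacuation"),
) -> pd.DataFrame:
    """Effect sizes of each district characteristic on each change column.

    ``deltas`` has a ``district`` column plus one column per outcome (e.g.
    ``male_LE_early``); rows of the output mirror a characteristics × outcome
    correlation table with r, t, df, p and the |r| > 0.5 flag.
    """
    merged = characteristics.merge(deltas, on="district", validate="1:1")
    outcomes = [c for c in deltas.columns if c != "district"]
    rows = []
    for ch in char_fields:
        for oc in outcomes:
            res = effect_size_continuous(merged[ch], merged[oc], variable=ch, outcome=oc)
            rows.append(
                {
                    "characteristic": ch,
                    "outcome": oc,
                    "r": res.r,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def group_compare_table(
    deltas: pd.DataFrame,
    evacuation_by_district: Mapping[int, bool],
) -> pd.DataFrame:
    """Evacuation vs non-evacuation group comparison for each change column,
    reporting group means/SDs, pooled t, p, and point-biserial r."""
    evac_mask = deltas["district"].map(lambda d: bool(evacuation_by_district[int(d)]))
    rows = []
    for oc in [c for c in deltas.columns if c != "district"]:
        a = deltas.loc[evac_mask, oc].to_numpy(dtype=float)
        b = deltas.loc[~evac_mask, oc].to_numpy(dtype=float)
        res = group_compare(a, b, outcome=oc)
        rows.append(
            {
                "outcome": oc,
                "evac_mean": a.mean(),
                "evac_sd": a.std(ddof=1),
                "evac_n": a.size,
                "nonevac_mean": b.mean(),
                "nonevac_sd": b.std(ddof=1),
                "nonevac_n": b.size,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "r": res.r,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
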