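"""Synthetic vital-registration generator and the printed-count fixture.

The real prefecture-level vital statistics behind this kind of analysis are
restricted, so this module generates registry-shaped data with the
statistical structure the pipeline assumes: 59 municipalities consolidated
into 14 districts (three of which flag evacuation-order areas), two sexes,
single ages 0–110, three multi-year analysis periods with the disaster year
excluded, four ICD-10 cause groups plus "other", and genuine year-to-year
variation so the uncertainty machinery has annual SDs to estimate.

Deaths follow a Gompertz–Makeham hazard h(x) = lambda + alpha * exp(beta*x)
(a constant background plus an exponentially age-increasing senescent term —
the standard shape of adult human mortality), with an optional additive
infant bump at age 0, district-level multipliers, and per-period per-cause
multipliers that can be targeted at evacuation districts to emulate
post-disaster cause-specific change. Cell death counts are binomial with
q_x = 1 - exp(-h(x)); causes are assigned from age-band mixes.

``make_table1_fixture`` returns the published prefecture-level age-bin death
counts used by the internal-consistency checks, with a documented geometric
within-bin split to single years for plumbing tests (approximate by
construction; never a basis for comparing expectancies to published values).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from lifeyears.io_formats import (
    ALL_CAUSES,
    DEFAULT_CAUSE_GROUPS,
    OTHER_CAUSES,
    CauseGroup,
    DeathCountCube,
    DeathRecord,
    DistrictMap,
    PopulationTable,
)

MAX_AGE = 110

AGE_BANDS: tuple[tuple[int, int], ...] = (
    (0, 9), (10, 19), (20, 29), (30, 39), (40, 49), (50, 59),
    (60, 69), (70, 79), (80, 89), (90, 99), (100, MAX_AGE),
)
AGE_BAND_LABELS: tuple[str, ...] = (
    "0-9", "10-19", "20-29", "30-39", "40-49", "50-59",
    "60-69", "70-79", "80-89", "90-99", "100-",
)

CAUSES = ("cancer", "heart", "cerebrovascular", "pneumonia", OTHER_CAUSES)

# Cause-of-death mix by 10-year age band (fractions over the four groups +
# other): cancer peaks in midlife, circulatory disease and pneumonia grow in
# old age, external/other causes dominate the young.
DEFAULT_CAUSE_MIX: dict[str, dict[str, float]] = {
    "0-9":   {"cancer": 0.05, "heart": 0.03, "cerebrovascular": 0.01, "pneumonia": 0.03, OTHER_CAUSES: 0.88},
    "10-19": {"cancer": 0.10, "heart": 0.04, "cerebrovascular": 0.02, "pneumonia": 0.02, OTHER_CAUSES: 0.82},
    "20-29": {"cancer": 0.10, "heart": 0.05, "cerebrovascular": 0.03, "pneumonia": 0.02, OTHER_CAUSES: 0.80},
    "30-39": {"cancer": 0.20, "heart": 0.07, "cerebrovascular": 0.05, "pneumonia": 0.02, OTHER_CAUSES: 0.66},
    "40-49": {"cancer": 0.30, "heart": 0.10, "cerebrovascular": 0.08, "pneumonia": 0.02, OTHER_CAUSES: 0.50},
    "50-59": {"cancer": 0.40, "heart": 0.12, "cerebrovascular": 0.08, "pneumonia": 0.02, OTHER_CAUSES: 0.38},
    "60-69": {"cancer": 0.45, "heart": 0.12, "cerebrovascular": 0.08, "pneumonia": 0.03, OTHER_CAUSES: 0.32},
    "70-79": {"cancer": 0.38, "heart": 0.14, "cerebrovascular": 0.09, "pneumonia": 0.06, OTHER_CAUSES: 0.33},
    "80-89": {"cancer": 0.25, "heart": 0.16, "cerebrovascular": 0.10, "pneumonia": 0.10, OTHER_CAUSES: 0.39},
    "90-99": {"cancer": 0.13, "heart": 0.18, "cerebrovascular": 0.10, "pneumonia": 0.13, OTHER_CAUSES: 0.46},
    "100-":  {"cancer": 0.07, "heart": 0.20, "cerebrovascular": 0.09, "pneumonia": 0.15, OTHER_CAUSES: 0.49},
}

# ICD-10 roots outside all four groups, used for "other" deaths.
_OTHER_CODES = ("A09", "E11", "E14", "G30", "J44", "K70", "N18", "R99", "W19", "X59")


def band_of(age: int) -> str:
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside 0..{MAX_AGE}")


@dataclass
class MortalityModel:
    """Gompertz–Makeham generating law with cause structure.

    ``makeham`` maps sex to (lambda, alpha, beta): background hazard,
    senescent level at age 0, and log-slope per year of age. The default
    parameters give adult expectancies in the high-70s (male) / mid-80s
    (female), the range typical of contemporary Japan.

    ``cause_period_multipliers`` scales a cause's hazard share in a given
    period; values may be a scalar (all districts) or a (evacuation,
    non-evacuation) pair to concentrate change in flagged districts.
    """

    makeham: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "male": (2.5e-4, 1.2e-5, 0.108),
            "female": (1.2e-4, 3.5e-6, 0.115),
        }
    )
    infant_bump: float = 0.0
    cause_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(m) for b, m in DEFAULT_CAUSE_MIX.items()}
    )
    district_multipliers: dict[int, float] = field(default_factory=dict)
    period_multipliers: dict[str, float] = field(default_factory=dict)
    cause_period_multipliers: dict[tuple[str, str], object] = field(default_factory=dict)

    def __post_init__(self):
        for sex, (lam, alpha, beta) in self.makeham.items():
            if lam < 0 or alpha < 0 or beta < 0:
                raise ValueError(f"{sex}: need lambda, alpha, beta >= 0")
        for band, mix in self.cause_mix.items():
            total = sum(mix.values())
            if any(v < 0 for v in mix.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"cause mix for band {band} must be >= 0 and sum to 1")

    def _cause_mult(self, period: str | None, cause: str, evacuation: bool) -> float:
        if period is None:
            return 1.0
        m = self.cause_period_multipliers.get((period, cause), 1.0)
        if isinstance(m, (tuple, list)):
            return float(m[0] if evacuation else m[1])
        return float(m)

    def cause_hazards(
        self,
        sex: str,
        ages: np.ndarray,
        district: int | None = None,
        period: str | None = None,
        evacuation: bool = False,
    ) -> dict[str, np.ndarray]:
        """Cause-specific hazards per single year of age; their sum is the
        total hazard."""
        ages = np.asarray(ages)
        lam, alpha, beta = self.makeham[sex]
        base = lam + alpha * np.exp(beta * ages.astype(float))
        base = base + np.where(ages == 0, self.infant_bump, 0.0)
        if district is not None:
            base = base * self.district_multipliers.get(district, 1.0)
        if period is not None:
            base = base * self.period_multipliers.get(period, 1.0)
        shares = np.array(
            [[self.cause_mix[band_of(int(a))][c] for c in CAUSES] for a in ages]
        )
        out = {}
        for j, cause in enumerate(CAUSES):
            mult = self._cause_mult(period, cause, evacuation)
            out[cause] = base * shares[:, j] * mult
        return out

    def total_hazard(self, sex, ages, district=None, period=None, evacuation=False):
        hz = self.cause_hazards(sex, ages, district, period, evacuation)
        return sum(hz.values())

    def q_schedule(self, sex, district=None, period=None, evacuation=False) -> np.ndarray:
        ages = np.arange(MAX_AGE + 1)
        return 1.0 - np.exp(-self.total_hazard(sex, ages, district, period, evacuation))

    def analytic_life_expectancy(
        self,
        sex: str,
        district: int | None = None,
        period: str | None = None,
        evacuation: bool = False,
        age: float = 0.0,
        dx: float = 0.01,
        horizon: float = 130.0,
    ) -> float:
        """LE at *age* by numerical integration of exp(-cumulative hazard).

        Uses the continuous hazard with the cause-mix multipliers held at the
        single-year-of-age resolution of the discrete model, so it is the
        exact expectation of the generating law and serves as an oracle for
        estimates recovered from simulated data.
        """
        grid = np.arange(age, horizon, dx)
        h = self.total_hazard(sex, np.minimum(grid.astype(int), MAX_AGE), district, period, evacuation)
        # piecewise-constant hazard across each dx step
        H = np.concatenate([[0.0], np.cumsum(h * dx)])[:-1]
        surv = np.exp(-H)
        return float(np.trapezoid(surv, dx=dx))


DEFAULT_PERIODS: dict[str, tuple[int, int]] = {
    "pre": (2006, 2010),
    "early": (2012, 2015),
    "late": (2016, 2018),
}


def default_district_layout(n_districts: int = 14, n_municipalities: int = 59) -> dict[int, list[str]]:
    """Distribute municipality codes M01..M59 over districts as evenly as the
    counts allow."""
    base, extra = divmod(n_municipalities, n_districts)
    layout: dict[int, list[str]] = {}
    m = 1
    for d in range(1, n_districts + 1):
        size = base + (1 if d <= extra else 0)
        layout[d] = [f"M{m + i:02d}" for i in range(size)]
        m += size
    return layout


@dataclass
class ScenarioConfig:
    """Everything the generator needs; the seed fixes all randomness."""

    seed: int = 0
    districts: dict[int, list[str]] = field(default_factory=default_district_layout)
    evacuation_districts: frozenset[int] = frozenset({2, 3, 4})
    periods: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PERIODS)
    )
    excluded_years: frozenset[int] = frozenset({2011})
    district_population: float = 140_000.0  # both sexes, per district-year
    male_fraction: float = 0.486
    model: MortalityModel = field(default_factory=MortalityModel)
    pop_noise_sd: float = 0.01  # lognormal cell-level wobble in the pyramid
    year_effect_sd: float = 0.02  # lognormal year effect on hazards
    include_excluded_years: bool = False  # also simulate the dropped year(s)

    def __post_init__(self):
        for name, (lo, hi) in self.periods.items():
            if hi - lo + 1 < 2:
                raise ValueError(f"period {name!r} must span >= 2 years")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")

    @property
    def district_map(self) -> DistrictMap:
        m2d = {m: d for d, ms in self.districts.items() for m in ms}
        evac = {d: (d in self.evacuation_districts) for d in self.districts}
        return DistrictMap(m2d, evac)

    @property
    def years(self) -> list[int]:
        ys: set[int] = set()
        for lo, hi in self.periods.values():
            ys.update(range(lo, hi + 1))
        if self.include_excluded_years:
            ys.update(self.excluded_years)
        return sorted(ys)

    def period_of(self, year: int) -> str | None:
        for name, (lo, hi) in self.periods.items():
            if lo <= year <= hi:
                return name
        return None


def _pyramid_weights(model: MortalityModel, sex: str) -> np.ndarray:
    """Stationary-population age weights implied by the mortality law."""
    q = model.q_schedule(sex)
    l = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
    return l / l.sum()


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(raw - counts)[::-1]
        counts[order[:short]] += 1
    return counts


def generate_population(cfg: ScenarioConfig) -> PopulationTable:
    """Registry counts for every (district, sex, age 0..110, year).

    Each district-year total is held exactly at ``district_population`` split
    by ``male_fraction``; the age pyramid is the stationary population of the
    mortality law with small lognormal cell-level wobble, rounded by largest
    remainder so totals are conserved. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    rows = []
    for sex in ("male", "female"):
        frac = cfg.male_fraction if sex == "male" else 1.0 - cfg.male_fraction
        total = int(round(cfg.district_population * frac))
        base_w = _pyramid_weights(cfg.model, sex)
        for district in sorted(cfg.districts):
            for year in cfg.years:
                w = base_w * np.exp(rng.normal(0.0, cfg.pop_noise_sd, size=base_w.size))
                counts = _largest_remainder(w, total)
                for age in range(MAX_AGE + 1):
                    rows.append(
                        {
                            "district": district,
                            "sex": sex,
                            "age": age,
                            "year": year,
                            "count": int(counts[age]),
                        }
                    )
    return PopulationTable(pd.DataFrame(rows))


def simulate_death_counts(
    pop: PopulationTable,
    cfg: ScenarioConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annual death counts by (district, sex, age, year, cause).

    Per cell, deaths ~ Binomial(count, q_x) with q_x = 1 - exp(-h(x)) under
    the scenario's hazard (including period/district/cause multipliers and
    the lognormal year effect); the cause split is multinomial with
    probabilities proportional to the cause-specific hazards.
    """
    model = cfg.model
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 202])
    )
    ages = np.arange(MAX_AGE + 1)
    frame = pop.frame
    rows = []
    for (district, sex, year), sub in frame.groupby(["district", "sex", "year"]):
        counts = (
            sub.set_index("age")["count"].reindex(ages, fill_value=0).to_numpy(dtype=int)
        )
        period = cfg.period_of(int(year))
        evac = int(district) in cfg.evacuation_districts
        hz = model.cause_hazards(sex, ages, int(district), period, evac)
        h_total = sum(hz.values())
        year_factor = np.exp(rng.normal(0.0, cfg.year_effect_sd)) if cfg.year_effect_sd else 1.0
        q = 1.0 - np.exp(-h_total * year_factor)
        q = np.clip(q, 0.0, 1.0)
        deaths = rng.binomial(counts, q)
        probs = np.column_stack([hz[c] for c in CAUSES])
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(h_total[:, None] > 0, probs / h_total[:, None], 0.0)
        for age in ages:
            n = int(deaths[age])
            if n == 0:
                continue
            p = probs[age]
            split = rng.multinomial(n, p / p.sum()) if p.sum() > 0 else None
            if split is None:
                rows.append(
                    {"district": int(district), "sex": sex, "age": int(age),
                     "year": int(year), "cause": OTHER_CAUSES, "count": n}
                )
                continue
            for cause, k in zip(CAUSES, split):
                if k:
                    rows.append(
                        {"district": int(district), "sex": sex, "age": int(age),
                         "year": int(year), "cause": cause, "count": int(k)}
                    )
    return pd.DataFrame(
        rows, columns=["district", "sex", "age", "year", "cause", "count"]
    )


def _icd_code_for(cause: str, rng: np.random.Generator,
                  groups: Sequence[CauseGroup] = DEFAULT_CAUSE_GROUPS) -> str:
    if cause == OTHER_CAUSES:
        return str(rng.choice(_OTHER_CODES))
    group = next(g for g in groups if g.name == cause)
    roots = [
        f"{lo[0]}{n:02d}"
        for lo, hi in group.ranges
        for n in range(int(lo[1:]), int(hi[1:]) + 1)
    ]
    return str(rng.choice(roots))


def simulate_deaths(
    pop: PopulationTable,
    cfg: ScenarioConfig,
    seed: int | None = None,
) -> list[DeathRecord]:
    """Individual death records expanded from :func:`simulate_death_counts`.

    Each death gets an ICD-10 code sampled from its cause group's ranges, a
    municipality sampled uniformly within its district, and a date uniform
    within its calendar year.
    """
    counts = simulate_death_counts(pop, cfg, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 303])
    )
    records: list[DeathRecord] = []
    for row in counts.itertuples(index=False):
        munis = cfg.districts[int(row.district)]
        start = _dt.date(int(row.year), 1, 1).toordinal()
        days = 366 if _dt.date(int(row.year), 12, 31).toordinal() - start == 365 else 365
        for _ in range(int(row.count)):
            records.append(
                DeathRecord(
                    sex=row.sex,
                    age_at_death=int(row.age),
                    icd10=_icd_code_for(row.cause, rng),
                    municipality=str(rng.choice(munis)),
                    death_date=_dt.date.fromordinal(start + int(rng.integers(0, days))),
                )
            )
    return records


# --------------------------------------------------------------------------
# Published prefecture-level fixture: age-bin death counts by sex and period.

_TABLE1_COUNTS: dict[str, dict[str, tuple[int, ...]]] = {
    # per period: counts per AGE_BAND_LABELS order
    "pre": {
        "male": (182, 125, 411, 729, 1487, 4509, 7894, 16545, 19204, 5849, 192),
        "female": (154, 56, 180, 333, 719, 1910, 3378, 9232, 20347, 13457, 934),
    },
    "early": {
        "male": (127, 96, 280, 432, 931, 2616, 6795, 11601, 19129, 6186, 211),
        "female": (79, 39, 95, 200, 499, 1191, 2913, 6558, 18730, 14823, 1239),
    },
    "late": {
        "male": (67, 63, 155, 305, 686, 1710, 5366, 8277, 14088, 5985, 227),
        "female": (64, 37, 59, 149, 365, 796, 2240, 4415, 14008, 13507, 1148),
    },
}

_TABLE1_POPULATIONS: dict[str, dict[str, tuple[int, int]]] = {
    # (head count, reference year)
    "pre": {"male": (1_016_045, 2006), "female": (1_074_062, 2006)},
    "early": {"male": (963_776, 2012), "female": (1_019_215, 2012)},
    "late": {"male": (945_024, 2016), "female": (966_909, 2016)},
}


@dataclass
class Table1Fixture:
    """Prefecture-level all-cause death counts by sex and 10-year age bin for
    the three analysis periods, plus the reference-year populations."""

    counts: pd.DataFrame  # columns: period, sex, age_bin, count
    populations: dict[str, dict[str, tuple[int, int]]]

    def total(self, period: str | None = None) -> int:
        c = self.counts
        if period is not None:
            c = c[c["period"] == period]
        return int(c["count"].sum())

    def female_fraction(self, period: str) -> float:
        c = self.counts[self.counts["period"] == period]
        return float(c.loc[c["sex"] == "female", "count"].sum() / c["count"].sum())

    def cell(self, period: str, sex: str, age_bin: str) -> int:
        c = self.counts
        sel = (c["period"] == period) & (c["sex"] == sex) & (c["age_bin"] == age_bin)
        return int(c.loc[sel, "count"].iloc[0])

    def to_cube(self, growth: float = 1.08, district: int = 0) -> DeathCountCube:
        """Disaggregate bins to single years with a geometric within-bin split
        (each successive year of age weighted ``growth`` times the previous),
        rounded by largest remainder so bin totals are conserved exactly.

        The split is a documented approximation for plumbing only; results
        derived from it are approximate by construction.
        """
        cube = DeathCountCube([])
        for row in self.counts.itertuples(index=False):
            lo, hi = AGE_BANDS[AGE_BAND_LABELS.index(row.age_bin)]
            n_ages = hi - lo + 1
            w = growth ** np.arange(n_ages)
            split = _largest_remainder(w, int(row.count))
            for j, k in enumerate(split):
                if k:
                    cube.add(row.period, district, row.sex, lo + j, ALL_CAUSES, int(k))
                    cube.add(row.period, district, row.sex, lo + j, OTHER_CAUSES, int(k))
        cube.validate()
        return cube


def make_table1_fixture() -> Table1Fixture:
    """The published age- and sex-specific death counts for the pre-disaster
    (2006–2010), early post-disaster (2012–2015) and late post-disaster
    (2016–2018) periods, exactly as printed."""
    rows = [
        {"period": period, "sex": sex, "age_bin": label, "count": n}
        for period, by_sex in _TABLE1_COUNTS.items()
        for sex, values in by_sex.items()
        for label, n in zip(AGE_BAND_LABELS, values)
    ]
    return Table1Fixture(
        counts=pd.DataFrame(rows, columns=["period", "sex", "age_bin", "count"]),
        populations={p: dict(v) for p, v in _TABLE1_POPULATIONS.items()},
    )


def generate_characteristics(cfg: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Municipality-level 2010-baseline characteristics with district-level
    structure: evacuation (coastal) districts lean rural — lower population
    density and income, fewer medical professionals and institutions, more
    primary industry, an older population.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 404])
    )
    rows = []
    for district, munis in sorted(cfg.districts.items()):
        evac = district in cfg.evacuation_districts
        shift = -1.0 if evac else 0.0
        for m in munis:
            rows.append(
                {
                    "municipality": m,
                    "population": float(cfg.district_population / len(munis)),
                    "population_density": float(np.exp(5.5 + 0.6 * shift + rng.normal(0, 0.4))),
                    "income_per_capita": float(2.6e6 * np.exp(0.08 * shift + rng.normal(0, 0.05))),
                    "medical_professionals": float(np.exp(5.9 + 0.25 * shift + rng.normal(0, 0.2))),
                    "medical_institutions": float(np.exp(4.2 + 0.15 * shift + rng.normal(0, 0.2))),
                    "pct_primary_industry": float(np.clip(8 - 3 * shift + rng.normal(0, 2), 0.5, 60)),
                    "pct_aged_65plus": float(np.clip(26 - 2 * shift + rng.normal(0, 2), 10, 50)),
                    "financial_capability_index": float(np.clip(0.55 + 0.08 * shift + rng.normal(0, 0.08), 0.1, 1.5)),
                    "natural_growth_rate": float(rng.normal(-4.0 + shift, 0.8)),
                    "net_migration_rate": float(rng.normal(-1.0 + 0.5 * shift, 0.8)),
                }
            )
    return pd.DataFrame(rows)


def disaster_scenario(seed: int = 0, district_population: float = 140_000.0) -> ScenarioConfig:
    """A scenario emulating the study's qualitative structure: post-disaster
    reduction of cerebrovascular (and, less strongly, heart) mortality
    concentrated in the evacuation districts, with slightly elevated
    pre-disaster circulatory mortality there."""
    model = MortalityModel(
        district_multipliers={2: 1.05, 3: 1.05, 4: 1.05},
        cause_period_multipliers={
            ("early", "cerebrovascular"): (0.60, 0.95),
            ("late", "cerebrovascular"): (0.45, 0.90),
            ("early", "heart"): (0.80, 1.00),
            ("late", "heart"): (0.70, 0.95),
            ("early", "cancer"): (1.10, 0.95),
        },
    )
    return ScenarioConfig(seed=seed, model=model, district_population=district_population)
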