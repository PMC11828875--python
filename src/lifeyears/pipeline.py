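"""End-to-end orchestration: records and registry counts in, result bundle out.

A :class:`RunConfig` (usually loaded from YAML) names the inputs — either
CSV paths or a built-in synthetic scenario — and the analysis options. The
pipeline aggregates deaths, builds prefecture- and district-level life tables
for every period and sex, computes cause-deleted YLL at ages 0/40/65,
attaches Latin-hypercube Monte Carlo uncertainty intervals at prefecture
level, derives district changes relative to the pre-disaster period, and
writes effect-size and evacuation-contrast tables. Outputs are plain CSV
plus a JSON run manifest; the run is deterministic given config and seed,
with per-stage substreams derived from the root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from lifeyears import cause_yll, district_analysis, io_formats, lifetable, synthetic_data, uncertainty
from lifeyears.io_formats import ALL_CAUSES, DEFAULT_CAUSE_GROUPS, DistrictMap

logger = logging.getLogger(__name__)

YLL_AGES = (0, 40, 65)


@dataclass
class RunConfig:
    """Validated run configuration (YAML schema version 1)."""

    output_dir: str
    seed: int = 0
    # either explicit input paths ...
    deaths_path: str | None = None
    population_path: str | None = None
    district_map_path: str | None = None
    characteristics_path: str | None = None
    # ... or a synthetic scenario
    scenario: synthetic_data.ScenarioConfig | None = None
    periods: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(synthetic_data.DEFAULT_PERIODS)
    )
    excluded_years: frozenset[int] = frozenset({2011})
    cause_groups: tuple = DEFAULT_CAUSE_GROUPS
    method: str = "central"
    a0: float = 0.1
    omega: int = 110
    tail_fit: tuple[int, int] = (80, 94)
    n_trials: int = 10_000
    lhs_mode: str = "uniform"
    mc_district_medians: bool = False  # use MC medians as district points
    pre_period: str = "pre"

    def __post_init__(self):
        if self.n_trials < 100:
            raise ValueError("n_trials must be >= 100")
        spans = list(self.periods.values())
        for i, (a0_, a1) in enumerate(spans):
            for b0, b1 in spans[i + 1 :]:
                if not (a1 < b0 or b1 < a0_):
                    raise ValueError("periods must be disjoint")
        if self.scenario is None and not (
            self.deaths_path and self.population_path and self.district_map_path
        ):
            raise ValueError("either a scenario or all three input paths are required")

    @property
    def a_schedule(self) -> np.ndarray:
        return lifetable.default_a_schedule(self.omega, a0=self.a0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw.get("schema", 1) != 1:
            raise ValueError(f"unsupported config schema {raw.get('schema')!r}")
        kwargs: dict = {"output_dir": raw["output_dir"]}
        for key in (
            "seed", "deaths_path", "population_path", "district_map_path",
            "characteristics_path", "method", "a0", "omega", "n_trials",
            "lhs_mode", "mc_district_medians", "pre_period",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "periods" in raw:
            kwargs["periods"] = {k: tuple(v) for k, v in raw["periods"].items()}
        if "excluded_years" in raw:
            kwargs["excluded_years"] = frozenset(raw["excluded_years"])
        if "tail_fit" in raw:
            kwargs["tail_fit"] = tuple(raw["tail_fit"])
        if "scenario" in raw:
            sc = raw["scenario"] or {}
            kwargs["scenario"] = synthetic_data.ScenarioConfig(
                seed=sc.get("seed", kwargs.get("seed", 0)),
                district_population=sc.get("district_population", 140_000.0),
                year_effect_sd=sc.get("year_effect_sd", 0.02),
            )
        return cls(**kwargs)

    def digest(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _substream(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _period_stratum_inputs(
    cube: io_formats.DeathCountCube,
    pop: io_formats.PopulationTable,
    period: str,
    years: range,
    sex: str,
    district: int | None,
    cfg: RunConfig,
):
    """Pooled deaths, period-average population, and person-year span."""
    deaths = cube.counts_by_age(period, sex, cause=ALL_CAUSES, district=district, max_age=cfg.omega)
    pop_mat = pop.counts_by_age(sex, years, district=district, max_age=cfg.omega)
    avg_pop = pop_mat.mean(axis=1).to_numpy()
    return deaths, avg_pop, float(len(years))


def build_schedule(
    deaths: np.ndarray,
    avg_pop: np.ndarray,
    n_years: float,
    cfg: RunConfig,
    stratum: Mapping[str, object],
) -> lifetable.QSchedule:
    qs = lifetable.mortality_rates(
        deaths, avg_pop, years=n_years, method=cfg.method,
        a_schedule=cfg.a_schedule, omega=cfg.omega, stratum=stratum,
    )
    return lifetable.extend_tail(
        qs, fit_ages=range(cfg.tail_fit[0], cfg.tail_fit[1] + 1), a_schedule=cfg.a_schedule
    )


def stratum_estimates(
    cube: io_formats.DeathCountCube,
    pop: io_formats.PopulationTable,
    cfg: RunConfig,
    period: str,
    sex: str,
    district: int | None = None,
) -> dict:
    """Deterministic LE and per-cause YLL for one stratum."""
    lo, hi = cfg.periods[period]
    years = range(lo, hi + 1)
    stratum = {"period": period, "sex": sex, "district": district}
    deaths, avg_pop, n_years = _period_stratum_inputs(cube, pop, period, years, sex, district, cfg)
    qs = build_schedule(deaths, avg_pop, n_years, cfg, stratum)
    lt = lifetable.build_life_table(qs, a_schedule=cfg.a_schedule)
    out = {
        "lifetable": lt,
        "LE": {age: lifetable.life_expectancy(lt, age) for age in YLL_AGES},
        "YLL": {},
    }
    for group in cfg.cause_groups:
        cf = cause_yll.cause_fraction(cube, period, sex, group, district=district, max_age=cfg.omega)
        qs_del = cause_yll.delete_cause(qs, cf)
        res = cause_yll.yll(qs, qs_del, ages=YLL_AGES, a_schedule=cfg.a_schedule, cause=group.name)
        out["YLL"][group.name] = res
    return out


def _annual_matrices(
    records_counts: pd.DataFrame,
    pop: io_formats.PopulationTable,
    years: range,
    sex: str,
    district: int | None,
    cause_names: Sequence[str],
    omega: int,
):
    """Age × year matrices of population and deaths (all + per cause)."""
    pop_mat = pop.counts_by_age(sex, years, district=district, max_age=omega).to_numpy()
    c = records_counts
    sel = (c["sex"] == sex) & c["year"].isin(list(years))
    if district is not None:
        sel &= c["district"] == district
    sub = c.loc[sel]
    deaths = {}
    base = np.zeros((omega + 1, len(years)))
    ylist = list(years)
    for cause in (*cause_names, io_formats.OTHER_CAUSES):
        mat = base.copy()
        s2 = sub[sub["cause"] == cause]
        for row in s2.itertuples(index=False):
            mat[min(int(row.age), omega), ylist.index(int(row.year))] += row.count
        deaths[cause] = mat
    deaths["all"] = sum(deaths.values())
    return pop_mat, deaths


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    staged: list[Path] = []

    try:
        # ---- stage: inputs -------------------------------------------------
        if cfg.scenario is not None:
            scenario = cfg.scenario
            dmap = scenario.district_map
            pop = synthetic_data.generate_population(scenario)
            records = synthetic_data.simulate_deaths(pop, scenario)
            muni_chars = synthetic_data.generate_characteristics(scenario)
            n_excluded = sum(
                1 for r in records if r.death_date.year in cfg.excluded_years
            )
            records = [r for r in records if r.death_date.year not in cfg.excluded_years]
        else:
            for p in (cfg.deaths_path, cfg.population_path, cfg.district_map_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input not found: {p}")
            dmap = DistrictMap.from_yaml(cfg.district_map_path)
            pop = io_formats.read_population(cfg.population_path)
            before = pd.read_csv(cfg.deaths_path).shape[0]
            records = io_formats.read_death_records(
                cfg.deaths_path, excluded_years=cfg.excluded_years
            )
            n_excluded = before - len(records)
            muni_chars = (
                pd.read_csv(cfg.characteristics_path)
                if cfg.characteristics_path
                else None
            )

        cube = io_formats.aggregate_deaths(records, dmap, cfg.periods, cfg.cause_groups)

        # annual counts frame (district, sex, age, year, cause) for MC stats
        annual = pd.DataFrame(
            [
                {
                    "district": dmap.district_of(r.municipality),
                    "sex": r.sex,
                    "age": r.age_at_death,
                    "year": r.death_date.year,
                    "cause": io_formats.classify_cause(r.icd10, cfg.cause_groups),
                }
                for r in records
            ]
        )
        annual = (
            annual.groupby(["district", "sex", "age", "year", "cause"])
            .size()
            .reset_index(name="count")
        )

        cause_names = [g.name for g in cfg.cause_groups]
        periods = list(cfg.periods)
        sexes = ("male", "female")

        # ---- stage: prefecture life tables & YLL ---------------------------
        lt_dir = out_dir / "lifetables"
        lt_dir.mkdir(exist_ok=True)
        yll_rows = []
        point_le: dict[tuple[str, str], dict[int, float]] = {}
        for period in periods:
            for sex in sexes:
                est = stratum_estimates(cube, pop, cfg, period, sex, district=None)
                p = lt_dir / f"{period}_{sex}_prefecture.csv"
                est["lifetable"].write_csv(p, p.with_suffix(".json"))
                staged += [p, p.with_suffix(".json")]
                point_le[(period, sex)] = est["LE"]
                for cause, res in est["YLL"].items():
                    for age, v in res.yll.items():
                        yll_rows.append(
                            {"period": period, "sex": sex, "district": "prefecture",
                             "cause": cause, "age": age, "yll_years": v}
                        )
        yll_path = out_dir / "yll.csv"
        pd.DataFrame(yll_rows).to_csv(yll_path, index=False)
        staged.append(yll_path)

        # ---- stage: Monte Carlo uncertainty (prefecture) -------------------
        quantities = [("LE", None, a) for a in YLL_AGES] + [
            ("YLL", c, a) for c in cause_names for a in YLL_AGES
        ]
        mc_all: list[uncertainty.MCResult] = []
        trials_le0: dict[tuple[str, str], np.ndarray] = {}
        for period in periods:
            lo, hi = cfg.periods[period]
            years = range(lo, hi + 1)
            for sex in sexes:
                pop_mat, deaths = _annual_matrices(
                    annual, pop, years, sex, None, cause_names, cfg.omega
                )
                cs = uncertainty.cell_stats_from_annual(
                    pop_mat, deaths, stratum={"period": period, "sex": sex}
                )
                res = uncertainty.monte_carlo_estimates(
                    cs,
                    n_trials=cfg.n_trials,
                    seed=_substream(cfg.seed, f"mc:{period}:{sex}"),
                    quantities=quantities,
                    a_schedule=cfg.a_schedule,
                    fit_ages=range(cfg.tail_fit[0], cfg.tail_fit[1] + 1),
                    omega=cfg.omega,
                    lhs_mode=cfg.lhs_mode,
                )
                mc_all.extend(res)
                le0 = next(r for r in res if r.quantity == "LE" and r.age == 0)
                trials_le0[(period, sex)] = le0.trials
        for period in periods:
            if period == cfg.pre_period:
                continue
            for sex in sexes:
                diff = uncertainty.period_difference(
                    trials_le0[(cfg.pre_period, sex)], trials_le0[(period, sex)]
                )
                diff.stratum = {"period": f"{period}-vs-{cfg.pre_period}", "sex": sex}
                diff.quantity, diff.age = "delta_LE", 0
                mc_all.append(diff)
        mc_path = out_dir / "mc_results.csv"
        uncertainty.write_mc_results(mc_all, mc_path)
        staged.append(mc_path)

        # ---- stage: district estimates and effect sizes --------------------
        district_rows = []
        for district in dmap.districts:
            row: dict[str, object] = {"district": district}
            for period in periods:
                for sex in sexes:
                    est = stratum_estimates(cube, pop, cfg, period, sex, district=district)
                    row[f"LE_{sex}_{period}"] = est["LE"][0]
                    for cause, res in est["YLL"].items():
                        row[f"YLL_{cause}_{sex}_{period}"] = res.yll[0]
            district_rows.append(row)
        district_points = pd.DataFrame(district_rows)
        dp_path = out_dir / "district_points.csv"
        district_points.to_csv(dp_path, index=False)
        staged.append(dp_path)

        deltas = pd.DataFrame({"district": district_points["district"]})
        for col in district_points.columns:
            if col.endswith(f"_{cfg.pre_period}"):
                stem = col[: -len(cfg.pre_period) - 1]
                for period in periods:
                    if period == cfg.pre_period:
                        continue
                    deltas[f"d_{stem}_{period}"] = (
                        district_points[f"{stem}_{period}"] - district_points[col]
                    )

        effects_path = out_dir / "effects.csv"
        compare_path = out_dir / "group_compare.csv"
        if muni_chars is not None:
            chars = district_analysis.aggregate_characteristics(muni_chars, dmap)
            district_analysis.effects_table(chars, deltas).to_csv(effects_path, index=False)
            staged.append(effects_path)
        district_analysis.group_compare_table(deltas, dmap.evacuation).to_csv(
            compare_path, index=False
        )
        staged.append(compare_path)

        # ---- stage: manifest ----------------------------------------------
        manifest = {
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "n_records": len(records),
            "n_excluded_year": int(n_excluded),
            "cube_total": cube.total(),
            "period_totals": {p: cube.total(p) for p in periods},
            "n_trials": cfg.n_trials,
            "outputs": [str(p.relative_to(out_dir)) for p in staged],
        }
        assert manifest["cube_total"] == sum(manifest["period_totals"].values())
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        for p in staged:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed: {exc}") from exc
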