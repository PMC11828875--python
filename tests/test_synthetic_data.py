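import numpy as np
import pandas as pd
import pytest

from lifeyears.io_formats import ALL_CAUSES, DEFAULT_CAUSE_GROUPS, classify_cause
from lifeyears.synthetic_data import (
    AGE_BAND_LABELS,
    MortalityModel,
    ScenarioConfig,
    Table1Fixture,
    generate_characteristics,
    generate_population,
    make_table1_fixture,
    simulate_death_counts,
    simulate_deaths,
)


def _one_cell_scenario(q: float, count: int, age: int = 50) -> tuple:
    """Scenario with deterministic hazard giving probability q at every age,
    and a population concentrated at one age."""
    lam = -np.log(1.0 - q)
    model = MortalityModel(makeham={"male": (lam, 0.0, 0.0), "female": (lam, 0.0, 0.0)})
    cfg = ScenarioConfig(
        seed=1,
        districts={1: ["M01"]},
        evacuation_districts=frozenset(),
        periods={"pre": (2006, 2007)},
        district_population=count,
        male_fraction=0.999999,
        model=model,
        pop_noise_sd=0.0,
        year_effect_sd=0.0,
    )
    frame = pd.DataFrame(
        [{"district": 1, "sex": "male", "age": age, "year": 2006, "count": count}]
    )
    from lifeyears.io_formats import PopulationTable

    return cfg, PopulationTable(frame)


class TestGeneratePopulation:
    def test_district_year_totals_conserved(self, tiny_scenario):
        pop = generate_population(tiny_scenario)
        totals = pop.frame.groupby(["district", "year"])["count"].sum()
        expected = round(5000 * 0.486) + round(5000 * 0.514)
        assert (totals == expected).all()

    def test_same_seed_reproduces_identical_tables(self, tiny_scenario):
        a = generate_population(tiny_scenario)
        b = generate_population(tiny_scenario)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_different_seeds_differ(self, tiny_scenario):
        import dataclasses

        other = dataclasses.replace(tiny_scenario, seed=12)
        a = generate_population(tiny_scenario)
        b = generate_population(other)
        assert not a.frame["count"].equals(b.frame["count"])

    def test_every_stratum_is_covered(self, tiny_scenario):
        pop = generate_population(tiny_scenario)
        f = pop.frame
        assert set(f["district"]) == set(range(1, 15))
        assert set(f["sex"]) == {"male", "female"}
        assert f["age"].max() == 110 and f["age"].min() == 0


class TestSimulateDeaths:
    def test_zero_hazard_gives_zero_deaths(self):
        cfg, pop = _one_cell_scenario(q=0.0, count=1000)
        counts = simulate_death_counts(pop, cfg)
        assert counts.empty

    def test_certain_death_kills_whole_cell(self):
        cfg, pop = _one_cell_scenario(q=1.0 - 1e-15, count=1000)
        counts = simulate_death_counts(pop, cfg)
        assert counts["count"].sum() == 1000

    def test_binomial_mean_across_replicates(self):
        """Cell of 10,000 with q = 0.01 over 200 replicate seeds: the mean
        death count sits within 3 standard errors of 100."""
        cfg, pop = _one_cell_scenario(q=0.01, count=10_000)
        totals = [
            simulate_death_counts(pop, cfg, seed=s)["count"].sum() for s in range(200)
        ]
        se = np.sqrt(10_000 * 0.01 * 0.99 / 200)
        assert abs(np.mean(totals) - 100.0) < 3 * se

    def test_records_carry_consistent_causes_and_dates(self, tiny_scenario):
        pop = generate_population(tiny_scenario)
        records = simulate_deaths(pop, tiny_scenario)
        assert len(records) > 0
        dmap = tiny_scenario.district_map
        years = set(tiny_scenario.years)
        for r in records[:500]:
            assert r.death_date.year in years
            dmap.district_of(r.municipality)  # raises if unknown
            classify_cause(r.icd10, DEFAULT_CAUSE_GROUPS)

    def test_parameter_recovery_of_q(self):
        """Observed deaths / population recovers the generating q_x within
        binomial sampling error for at least 95% of ages (n = 1e5 per age)."""
        cfg = ScenarioConfig(
            seed=4,
            districts={1: ["M01"]},
            evacuation_districts=frozenset(),
            periods={"pre": (2006, 2007)},
            district_population=2e5,
            model=MortalityModel(),
            pop_noise_sd=0.0,
            year_effect_sd=0.0,
        )
        n = 100_000
        ages = np.arange(111)
        frame = pd.DataFrame(
            [
                {"district": 1, "sex": "male", "age": a, "year": y, "count": n}
                for a in ages
                for y in (2006,)
            ]
        )
        from lifeyears.io_formats import PopulationTable

        counts = simulate_death_counts(PopulationTable(frame), cfg)
        deaths = np.zeros(111)
        for row in counts.itertuples(index=False):
            deaths[row.age] += row.count
        q_true = cfg.model.q_schedule("male")
        q_hat = deaths / n
        tol = 4 * np.sqrt(q_true * (1 - q_true) / n)
        ok = np.abs(q_hat - q_true) < np.maximum(tol, 1e-12)
        assert ok.mean() >= 0.95


class TestTable1Fixture:
    def test_specific_printed_cells(self):
        fx = make_table1_fixture()
        assert fx.cell("pre", "male", "70-79") == 16_545
        assert fx.cell("late", "female", "100-") == 1_148

    def test_cube_disaggregation_conserves_bins(self):
        fx = make_table1_fixture()
        cube = fx.to_cube()
        assert cube.total() == fx.total()
        by_age = cube.counts_by_age("pre", "male", cause=ALL_CAUSES)
        assert by_age[70:80].sum() == fx.cell("pre", "male", "70-79")
        # geometric split weights later ages within each bin more heavily
        assert by_age[79] > by_age[70]

    def test_band_labels_cover_all_bins(self):
        fx = make_table1_fixture()
        assert set(fx.counts["age_bin"]) == set(AGE_BAND_LABELS)


def test_characteristics_have_expected_columns(tiny_scenario):
    chars = generate_characteristics(tiny_scenario)
    assert len(chars) == 59
    assert {"municipality", "population", "financial_capability_index"} <= set(chars.columns)


class TestAnalyticLE:
    def test_large_sample_life_expectancy_recovery(self):
        """Life tables estimated from simulated data at ~1e6 person-years per
        stratum land within 0.2 years of the generating law's analytic LE."""
        from lifeyears import pipeline
        from lifeyears.io_formats import cube_from_counts

        cfg = ScenarioConfig(
            seed=9,
            districts={1: ["M01"]},
            evacuation_districts=frozenset(),
            periods={"pre": (2006, 2010)},
            district_population=400_000,
        )
        pop = generate_population(cfg)
        counts = simulate_death_counts(pop, cfg)
        cube = cube_from_counts(
            counts, cfg.periods, [g.name for g in DEFAULT_CAUSE_GROUPS]
        )
        run = pipeline.RunConfig(
            output_dir="unused", scenario=cfg, periods=cfg.periods, a0=0.5, method="direct"
        )
        for sex in ("male", "female"):
            est = pipeline.stratum_estimates(cube, pop, run, "pre", sex, district=None)
            analytic = cfg.model.analytic_life_expectancy(sex)
            assert est["LE"][0] == pytest.approx(analytic, abs=0.2)
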