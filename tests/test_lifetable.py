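import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifeyears.lifetable import (
    FLAG_AGE0,
    FLAG_INTERPOLATED,
    FLAG_OBSERVED,
    FLAG_TAIL,
    QSchedule,
    build_life_table,
    complete_q_from_m,
    default_a_schedule,
    extend_tail,
    life_expectancy,
    m_to_q,
    mortality_rates,
    q_to_m,
)
from tests.conftest import expectancy_by_enumeration

OMEGA = 110


def _full_arrays(deaths_at=None, pop=1000.0):
    deaths = np.zeros(OMEGA + 1)
    pops = np.full(OMEGA + 1, pop)
    if deaths_at:
        for age, n in deaths_at.items():
            deaths[age] = n
    return deaths, pops


class TestMortalityRates:
    def test_central_rate_conversion_closed_form(self):
        deaths, pops = _full_arrays({50: 10})
        qs = mortality_rates(deaths, pops, years=1.0)
        m = 10 / 1000
        assert qs.q[50] == pytest.approx(m / (1 + 0.5 * m), abs=1e-10)
        assert qs.q[50] == pytest.approx(0.0099502, abs=1e-7)
        assert qs.flags[50] == FLAG_OBSERVED
        assert qs.flags[0] == FLAG_AGE0

    def test_zero_deaths_gives_zero_q(self):
        deaths, pops = _full_arrays()
        qs = mortality_rates(deaths, pops)
        assert np.all(qs.q[:95][~np.isnan(qs.q[:95])] == 0)

    def test_q_clipped_at_one(self):
        deaths, pops = _full_arrays({30: 1000})
        qs = mortality_rates(deaths, pops)
        assert qs.q[30] <= 1.0

    def test_multi_year_period_scales_exposure(self):
        deaths, pops = _full_arrays({50: 50})
        qs = mortality_rates(deaths, pops, years=5.0)
        m = 50 / (1000 * 5)
        assert qs.q[50] == pytest.approx(m / (1 + 0.5 * m))

    def test_direct_method(self):
        deaths, pops = _full_arrays({50: 10})
        qs = mortality_rates(deaths, pops, method="direct")
        assert qs.q[50] == pytest.approx(0.01)

    def test_deaths_without_population_is_error(self):
        deaths, pops = _full_arrays({40: 5})
        pops[40] = 0
        with pytest.raises(ValueError, match="zero population"):
            mortality_rates(deaths, pops)

    def test_empty_cell_interpolated_and_flagged(self):
        deaths, pops = _full_arrays({49: 10, 51: 40})
        pops[50] = 0
        qs = mortality_rates(deaths, pops)
        assert qs.flags[50] == FLAG_INTERPOLATED
        # log-linear: geometric mean of the neighbours
        assert qs.q[50] == pytest.approx(np.sqrt(qs.q[49] * qs.q[51]), rel=1e-6)


class TestExtendTail:
    def test_exact_gompertz_recovered(self):
        """Rates following m_x = 0.05 e^{0.09(x-80)} over the fit window
        extrapolate to the closed-form m_95 within 1e-6."""
        a = default_a_schedule(OMEGA)
        q = np.full(OMEGA + 1, np.nan)
        ages = np.arange(80, 95)
        m_fit = 0.05 * np.exp(0.09 * (ages - 80))
        q[ages] = m_to_q(m_fit, a[ages])
        q[:80] = 0.01
        flags = np.array([FLAG_OBSERVED] * (OMEGA + 1), dtype=object)
        qs = extend_tail(QSchedule(q, flags), a_schedule=a)
        m95 = q_to_m(qs.q[95], a[95])
        assert m95 == pytest.approx(0.05 * np.exp(0.09 * 15), abs=1e-6)
        assert qs.q[OMEGA] == 1.0
        assert all(f == FLAG_TAIL for f in qs.flags[95:])

    def test_constant_rates_extrapolate_flat(self):
        a = default_a_schedule(OMEGA)
        q = np.full(OMEGA + 1, np.nan)
        q[:95] = m_to_q(0.08, 0.5)
        flags = np.array([FLAG_OBSERVED] * (OMEGA + 1), dtype=object)
        qs = extend_tail(QSchedule(q, flags), a_schedule=a)
        m_ext = q_to_m(qs.q[95:110], a[95:110])
        assert np.allclose(m_ext, 0.08, rtol=1e-9)

    def test_too_few_usable_fit_ages_is_error(self):
        q = np.full(OMEGA + 1, np.nan)
        q[80:82] = 0.1
        flags = np.array(["missing"] * (OMEGA + 1), dtype=object)
        with pytest.raises(ValueError, match=">= 3"):
            extend_tail(QSchedule(q, flags))


def _const_schedule(qval, omega=OMEGA):
    q = np.full(omega + 1, float(qval))
    q[-1] = 1.0
    flags = np.array([FLAG_OBSERVED] * (omega + 1), dtype=object)
    return QSchedule(q, flags)


class TestBuildLifeTable:
    def test_constant_half_q_geometric_series(self, flat_q_schedule):
        lt = build_life_table(flat_q_schedule)
        assert life_expectancy(lt, 0) == pytest.approx(1.5, abs=1e-9)

    def test_certain_infant_death_leaves_only_a0(self):
        qs = _const_schedule(1.0)
        lt = build_life_table(qs)  # flat a = 0.5 default
        assert life_expectancy(lt, 0) == pytest.approx(0.5)

    def test_immortal_until_omega_bound(self):
        qs = _const_schedule(0.0)
        lt = build_life_table(qs)
        assert life_expectancy(lt, 0) == pytest.approx(OMEGA + 0.5)

    def test_columns_satisfy_bracketing_invariants(self, flat_q_schedule):
        lt = build_life_table(flat_q_schedule)
        assert np.all(np.diff(lt.l) <= 0)
        assert np.all(lt.L <= lt.l + 1e-9)
        assert np.all(lt.L >= np.append(lt.l[1:], 0.0) - 1e-9)
        alive = lt.l > 0
        assert np.all(lt.e[alive] > 0)

    def test_incomplete_schedule_rejected(self):
        q = np.full(OMEGA + 1, np.nan)
        flags = np.array(["missing"] * (OMEGA + 1), dtype=object)
        with pytest.raises(ValueError, match="unfilled"):
            build_life_table(QSchedule(q, flags))

    def test_open_schedule_without_closure_rejected(self):
        q = np.full(OMEGA + 1, 0.5)
        flags = np.array([FLAG_OBSERVED] * (OMEGA + 1), dtype=object)
        with pytest.raises(ValueError, match="q = 1"):
            build_life_table(QSchedule(q, flags))


class TestLifeExpectancy:
    def test_constant_q_is_memoryless(self, flat_q_schedule):
        lt = build_life_table(flat_q_schedule)
        assert life_expectancy(lt, 5) == pytest.approx(1.5, abs=1e-6)

    def test_open_age_expectancy_is_a_omega(self, flat_q_schedule):
        lt = build_life_table(flat_q_schedule)
        # l_110 is vanishingly small but positive; e_110 = a_110
        assert lt.e[OMEGA] == pytest.approx(0.5)

    def test_no_survivors_is_error(self):
        qs = _const_schedule(1.0)
        lt = build_life_table(qs)
        with pytest.raises(ValueError, match="survivors"):
            life_expectancy(lt, 1)


@st.composite
def q_schedules(draw):
    omega = draw(st.integers(min_value=5, max_value=40))
    q = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=omega + 1,
            max_size=omega + 1,
        )
    )
    q = np.asarray(q)
    q[-1] = 1.0
    return q


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q_schedules())
    def test_e0_matches_enumeration_oracle(self, q):
        """e_0 from the column construction equals the brute-force expected
        age at death to 1e-10, for arbitrary schedules."""
        a = np.full(len(q), 0.5)
        flags = np.array(["observed"] * len(q), dtype=object)
        lt = build_life_table(QSchedule(q, flags), a_schedule=a)
        assert life_expectancy(lt, 0) == pytest.approx(
            expectancy_by_enumeration(q, a), abs=1e-10
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(q_schedules(), st.data())
    def test_raising_any_q_never_raises_e0(self, q, data):
        if np.all(q[:-1] >= 1.0):
            return
        idx = data.draw(
            st.sampled_from([i for i in range(len(q) - 1) if q[i] < 1.0])
        )
        a = np.full(len(q), 0.5)
        flags = np.array(["observed"] * len(q), dtype=object)
        e_before = build_life_table(QSchedule(q, flags), a_schedule=a).e[0]
        q2 = q.copy()
        q2[idx] = min(1.0, q2[idx] + data.draw(st.floats(0.01, 0.5)))
        e_after = build_life_table(QSchedule(q2, flags), a_schedule=a).e[0]
        assert e_after <= e_before + 1e-12

    def test_e0_equals_trapezoid_of_survival_curve(self):
        """With flat a = 0.5 the expectancy is the trapezoidal integral of
        the survival curve."""
        rng = np.random.default_rng(5)
        q = np.clip(rng.uniform(0.0, 0.3, OMEGA + 1), 0, 1)
        q[-1] = 1.0
        flags = np.array(["observed"] * (OMEGA + 1), dtype=object)
        lt = build_life_table(QSchedule(q, flags))
        surv = np.append(lt.l, 0.0) / lt.radix
        trapz = np.sum(0.5 * (surv[:-1] + surv[1:]))
        assert lt.e[0] == pytest.approx(trapz, abs=1e-9)


def test_complete_q_from_m_matches_scalar_path():
    """The batched rate-to-schedule path agrees with mortality_rates +
    extend_tail run one stratum at a time."""
    rng = np.random.default_rng(7)
    a = default_a_schedule(OMEGA)
    m = 0.0002 + 0.00002 * np.exp(0.1 * np.arange(95)) * rng.uniform(0.9, 1.1, 95)
    q_batch = complete_q_from_m(m, a)
    deaths = m * 10_000
    qs = mortality_rates(deaths, np.full(OMEGA + 1, 10_000.0), a_schedule=a)
    qs = extend_tail(qs, a_schedule=a)
    assert np.allclose(q_batch[:95], qs.q[:95], atol=1e-12)
    assert np.allclose(q_batch[95:], qs.q[95:], rtol=1e-6)
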