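import numpy as np
import pytest

from lifeyears.io_formats import DistrictMap
from lifeyears.synthetic_data import MortalityModel, ScenarioConfig


@pytest.fixture
def small_dmap() -> DistrictMap:
    """Two districts (district 2 flagged as evacuation) over four municipalities."""
    return DistrictMap(
        municipality_to_district={"M01": 1, "M02": 1, "M03": 2, "M04": 2},
        evacuation={1: False, 2: True},
    )


@pytest.fixture
def tiny_scenario() -> ScenarioConfig:
    """Small but structurally complete scenario: 14 districts, 59
    municipalities, three periods, both sexes."""
    return ScenarioConfig(seed=11, district_population=5_000.0)


@pytest.fixture
def flat_q_schedule():
    """Constant q = 0.5 closed with q_omega = 1 (geometric-series oracle)."""
    from lifeyears.lifetable import QSchedule

    omega = 110
    q = np.full(omega + 1, 0.5)
    q[-1] = 1.0
    flags = np.array(["observed"] * (omega + 1), dtype=object)
    return QSchedule(q, flags, {"sex": "male", "period": "pre"})


def expectancy_by_enumeration(q: np.ndarray, a: np.ndarray) -> float:
    """Brute-force oracle for e_0: expected age at death via the death-age
    probability mass, E[x + a_x] = sum_x l_x q_x (x + a_x), computed by direct
    enumeration without any life-table columns."""
    surv = 1.0
    total = 0.0
    for x in range(len(q)):
        p_die = surv * q[x]
        total += p_die * (x + a[x])
        surv *= 1.0 - q[x]
    return total
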