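"""Single-year-of-age mortality schedules and complete period life tables.

The construction is the classical one. Occurrence–exposure (central) death
rates ``m_x`` are estimated from period death counts and registry population
denominators, converted to single-year death probabilities via

    q_x = m_x / (1 + (1 - a_x) * m_x)

where ``a_x`` is the average fraction of the year lived by those dying at age
x. Rates above the last reliably observed age are replaced by a Gompertz
(log-linear in age) least-squares extrapolation fitted over old ages, and the
table is closed with q = 1 at the open age ``omega`` (default 110). From the
completed schedule the table columns follow:

    l_{x+1} = l_x (1 - q_x),  d_x = l_x - l_{x+1},
    L_x = l_{x+1} + a_x d_x,  T_x = sum_{y >= x} L_y,  e_x = T_x / l_x.

``e_x`` is the life expectancy at exact age x; with a flat a = 0.5 it equals
the trapezoidal integral of the survival curve l(x), which is the quantity the
cause-deleted comparison differences to obtain years of life lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

OMEGA_DEFAULT = 110

FLAG_OBSERVED = "observed"
FLAG_AGE0 = "estimated-age0"
FLAG_TAIL = "estimated-tail"
FLAG_INTERPOLATED = "interpolated"
FLAG_MISSING = "missing"


def default_a_schedule(omega: int = OMEGA_DEFAULT, a0: float = 0.5) -> np.ndarray:
    """Fraction-of-year-lived schedule: flat 0.5, with an optional smaller a_0
    reflecting the concentration of infant deaths early in the first year of
    life (the analysis pipeline uses a0=0.1)."""
    a = np.full(omega + 1, 0.5)
    a[0] = a0
    return a


def m_to_q(m: np.ndarray, a: np.ndarray | float = 0.5) -> np.ndarray:
    """Convert central death rates to probabilities, clipped to [0, 1]."""
    m = np.asarray(m, dtype=float)
    q = m / (1.0 + (1.0 - a) * m)
    return np.clip(q, 0.0, 1.0)


def q_to_m(q: np.ndarray, a: np.ndarray | float = 0.5) -> np.ndarray:
    """Inverse of :func:`m_to_q` (q strictly below 1/(1-a) domain bound)."""
    q = np.asarray(q, dtype=float)
    return q / (1.0 - (1.0 - a) * q)


@dataclass
class QSchedule:
    """Mortality probabilities q_x for one stratum, ages 0..omega.

    ``flags`` records the provenance of each age's value: directly observed,
    estimated for age 0, extrapolated tail, interpolated across empty cells,
    or missing (not yet filled).
    """

    q: np.ndarray
    flags: np.ndarray
    stratum: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if self.q.shape != self.flags.shape:
            raise ValueError("q and flags must have identical shape")
        filled = ~np.isnan(self.q)
        if np.any((self.q[filled] < 0) | (self.q[filled] > 1)):
            raise ValueError("q values must lie in [0, 1]")

    @property
    def omega(self) -> int:
        return len(self.q) - 1

    def copy(self) -> "QSchedule":
        return QSchedule(self.q.copy(), self.flags.copy(), dict(self.stratum))

    def is_complete(self) -> bool:
        return bool(not np.isnan(self.q).any() and self.q[-1] == 1.0)


def mortality_rates(
    deaths_by_age: np.ndarray,
    pop_by_age: np.ndarray,
    years: float = 1.0,
    method: str = "central",
    a_schedule: np.ndarray | None = None,
    omega: int = OMEGA_DEFAULT,
    observed_ages: tuple[int, int] = (1, 94),
    stratum: Mapping[str, object] | None = None,
) -> QSchedule:
    """Estimate q_x for ages 0..94 from period deaths and average populations.

    Multi-year periods pool death counts and use the period-average population
    as the annual denominator, so exposure person-years are
    ``pop_by_age * years``. ``method="central"`` (default) forms the central
    rate m_x = deaths / exposure and converts with the a_x adjustment;
    ``method="direct"`` divides deaths by exposure directly as a probability.
    Ages above ``observed_ages[1]`` are left unfilled for
    :func:`extend_tail`. Empty cells (no population, no deaths) are
    interpolated log-linearly from the nearest observed neighbours and
    flagged.
    """
    deaths = np.asarray(deaths_by_age, dtype=float)
    pop = np.asarray(pop_by_age, dtype=float)
    if len(deaths) < observed_ages[1] + 1 or len(pop) < observed_ages[1] + 1:
        raise ValueError("deaths and population arrays must cover ages 0..94")
    if years <= 0:
        raise ValueError("period length must be positive")
    if a_schedule is None:
        a_schedule = default_a_schedule(omega)

    lo, hi = observed_ages
    q = np.full(omega + 1, np.nan)
    flags = np.array([FLAG_MISSING] * (omega + 1), dtype=object)

    for x in range(0, hi + 1):
        d, p = deaths[x], pop[x]
        if p <= 0:
            if d > 0:
                raise ValueError(f"age {x}: {d:g} deaths with zero population")
            continue  # empty cell, interpolate below
        exposure = p * years
        if method == "central":
            m = d / exposure
            q[x] = min(m / (1.0 + (1.0 - a_schedule[x]) * m), 1.0)
        elif method == "direct":
            q[x] = min(d / exposure, 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
        flags[x] = FLAG_AGE0 if x == 0 else FLAG_OBSERVED

    _interpolate_gaps(q, flags, hi)
    return QSchedule(q, flags, dict(stratum or {}))


def _interpolate_gaps(q: np.ndarray, flags: np.ndarray, hi: int) -> None:
    """Fill empty cells in 0..hi log-linearly from nearest filled neighbours."""
    filled = [x for x in range(hi + 1) if not np.isnan(q[x])]
    if not filled:
        return
    for x in range(hi + 1):
        if not np.isnan(q[x]):
            continue
        left = max((f for f in filled if f < x), default=None)
        right = min((f for f in filled if f > x), default=None)
        if left is None:
            q[x] = q[right]
        elif right is None:
            q[x] = q[left]
        else:
            ql, qr = q[left], q[right]
            w = (x - left) / (right - left)
            if ql > 0 and qr > 0:
                q[x] = float(np.exp((1 - w) * np.log(ql) + w * np.log(qr)))
            else:
                q[x] = (1 - w) * ql + w * qr
        flags[x] = FLAG_INTERPOLATED


def gompertz_fit(m_fit: np.ndarray, fit_ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of log m_x = a + b x.

    ``m_fit`` may be 1-D (one schedule) or 2-D (trials × fit ages); the fit is
    solved for all rows at once. Returns (intercept, slope) arrays.
    """
    m_fit = np.atleast_2d(np.asarray(m_fit, dtype=float))
    x = np.asarray(fit_ages, dtype=float)
    if m_fit.shape[1] != len(x):
        raise ValueError("m_fit columns must match fit_ages")
    if np.any(m_fit <= 0):
        raise ValueError("tail fit requires strictly positive rates")
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, np.log(m_fit).T, rcond=None)
    return coef[0], coef[1]


def extend_tail(
    qs: QSchedule,
    fit_ages: range = range(80, 95),
    target_ages: range | None = None,
    a_schedule: np.ndarray | None = None,
) -> QSchedule:
    """Replace old-age mortality with a Gompertz extrapolation.

    Rates are back-computed from the observed q over ``fit_ages`` (default
    80–94), log m is regressed on age, and the fitted line is extrapolated
    over ``target_ages`` (default 95..omega). The schedule is closed with
    q_omega = 1.
    """
    out = qs.copy()
    omega = out.omega
    if target_ages is None:
        target_ages = range(95, omega + 1)
    if a_schedule is None:
        a_schedule = default_a_schedule(omega)

    fit_idx = np.array(list(fit_ages))
    qf = out.q[fit_idx]
    usable = ~np.isnan(qf) & (qf > 0) & (qf < 1)
    if usable.sum() < 3:
        raise ValueError(
            f"tail fit needs >= 3 usable ages in {fit_ages}, got {int(usable.sum())}"
        )
    ages_u = fit_idx[usable]
    m_u = q_to_m(out.q[ages_u], a_schedule[ages_u])
    intercept, slope = gompertz_fit(m_u, ages_u)

    t = np.array(list(target_ages))
    m_ext = np.exp(intercept[0] + slope[0] * t)
    out.q[t] = m_to_q(m_ext, a_schedule[t])
    out.flags[t] = FLAG_TAIL
    out.q[omega] = 1.0
    out.flags[omega] = FLAG_TAIL
    return out


@dataclass
class LifeTable:
    """Complete period life table for one stratum."""

    q: np.ndarray
    l: np.ndarray  # survivors at exact age x (l_0 = radix)
    d: np.ndarray  # deaths between x and x+1
    L: np.ndarray  # person-years lived in [x, x+1)
    T: np.ndarray  # person-years lived above x
    e: np.ndarray  # expectancy at exact age x (nan where l_x = 0)
    a: np.ndarray
    radix: float
    stratum: Mapping[str, object] = field(default_factory=dict)

    @property
    def omega(self) -> int:
        return len(self.q) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age": np.arange(self.omega + 1),
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )

    def write_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if metadata_path is not None:
            import json

            with open(metadata_path, "w", encoding="utf-8") as fh:
                json.dump(
                    {"stratum": dict(self.stratum), "radix": self.radix, "omega": self.omega},
                    fh,
                    indent=2,
                )


def build_life_table(
    qs: QSchedule,
    radix: float = 100_000.0,
    a_schedule: np.ndarray | None = None,
) -> LifeTable:
    """Build the full life table from a complete mortality schedule.

    The terminal age is treated as an open interval with q = 1; its
    person-years are a_omega * l_omega (default a = 0.5).
    """
    q = np.asarray(qs.q, dtype=float)
    if np.isnan(q).any():
        raise ValueError("schedule has unfilled ages; run extend_tail first")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q values outside [0, 1]")
    if q[-1] != 1.0:
        raise ValueError("schedule must close with q = 1 at the open age")
    omega = len(q) - 1
    a = default_a_schedule(omega) if a_schedule is None else np.asarray(a_schedule, float)
    if len(a) != omega + 1:
        raise ValueError("a_schedule length must be omega + 1")

    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])  # length omega + 2
    l = radix * surv[:-1]
    l_next = radix * surv[1:]
    d = l - l_next
    L = l_next + a * d
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, np.nan)
    return LifeTable(q=q, l=l, d=d, L=L, T=T, e=e, a=a, radix=radix, stratum=dict(qs.stratum))


def life_expectancy(lt: LifeTable, age: int = 0) -> float:
    """Remaining life expectancy e_x = T_x / l_x at exact integer age."""
    if not (0 <= age <= lt.omega):
        raise ValueError(f"age {age} outside 0..{lt.omega}")
    if lt.l[age] <= 0:
        raise ValueError(f"no survivors at age {age}")
    return float(lt.e[age])


def batch_expectancies(
    q: np.ndarray,
    a_schedule: np.ndarray,
    ages: Sequence[int] = (0,),
) -> np.ndarray:
    """Life expectancies for a batch of schedules at once.

    ``q`` has shape (n_trials, omega+1), each row a complete schedule with
    q_omega = 1. Returns shape (n_trials, len(ages)). This is the vectorised
    core used by the Monte Carlo uncertainty machinery.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    n, w = q.shape
    a = np.asarray(a_schedule, dtype=float)
    surv = np.concatenate([np.ones((n, 1)), np.cumprod(1.0 - q, axis=1)], axis=1)
    l = surv[:, :-1]
    d = l - surv[:, 1:]
    L = surv[:, 1:] + a[None, :] * d
    T = np.cumsum(L[:, ::-1], axis=1)[:, ::-1]
    out = np.empty((n, len(ages)))
    for j, age in enumerate(ages):
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, j] = np.where(l[:, age] > 0, T[:, age] / l[:, age], np.nan)
    return out


def complete_q_from_m(
    m_low: np.ndarray,
    a_schedule: np.ndarray | None = None,
    fit_ages: range = range(80, 95),
    omega: int = OMEGA_DEFAULT,
    rate_floor: float = 1e-10,
) -> np.ndarray:
    """Turn central rates for ages 0..94 into complete q schedules 0..omega.

    Accepts 1-D (95,) or 2-D (n_trials, 95) input; the Gompertz tail fit is
    solved for all rows in a single least-squares call. Rates are floored at
    ``rate_floor`` so perturbed draws touching zero stay fittable.
    """
    m = np.atleast_2d(np.asarray(m_low, dtype=float))
    squeeze = np.asarray(m_low).ndim == 1
    if m.shape[1] != 95:
        raise ValueError("expected rates for ages 0..94")
    if a_schedule is None:
        a_schedule = default_a_schedule(omega)
    m = np.maximum(m, rate_floor)

    fit_idx = np.array(list(fit_ages))
    intercept, slope = gompertz_fit(m[:, fit_idx], fit_idx)
    t = np.arange(95, omega + 1)
    m_ext = np.exp(intercept[:, None] + slope[:, None] * t[None, :])

    q = np.empty((m.shape[0], omega + 1))
    q[:, :95] = m_to_q(m[:, :95], a_schedule[None, :95])
    q[:, 95:] = m_to_q(m_ext, a_schedule[None, 95:])
    q[:, omega] = 1.0
    return q[0] if squeeze else q
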