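"""Latin-hypercube Monte Carlo uncertainty intervals for LE and YLL.

Annual variation in registry populations and crude mortality rates over each
multi-year period is summarised as a per-age mean and sample standard
deviation and modelled as normal. Each Monte Carlo trial draws perturbed
populations and crude rates for ages 0–94 by Latin hypercube sampling
(one draw per equal-probability stratum per input dimension, independently
permuted across dimensions), truncates draws to their physical support
(populations >= 0, rates in [0, 1]), re-estimates the old-age tail of the
mortality schedule from the perturbed rates, rebuilds the life table, and
records life expectancy and YLL. Results are reported as the median and the
2.5th–97.5th percentile interval (95% UI) over trials, the reporting
convention standard in burden-of-disease work; the deterministic point
estimate from the period means is carried alongside.

Period contrasts use independently drawn trial sets per period (no pairing),
and district-group comparisons summarise district point estimates with a
normal-theory 95% CI from the across-district standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from lifeyears.lifetable import (
    OMEGA_DEFAULT,
    batch_expectancies,
    complete_q_from_m,
    default_a_schedule,
)

logger = logging.getLogger(__name__)

MC_AGES = 95  # perturbed input dimensions cover ages 0..94


def annual_variation(annual_values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a period's annual values."""
    v = np.asarray(annual_values, dtype=float)
    if v.size < 2:
        raise ValueError("annual variation needs at least 2 years")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class CellStats:
    """Per-age normal-perturbation inputs for one stratum and period.

    ``pop_mean``/``pop_sd`` and the per-cause ``rate_mean``/``rate_sd`` arrays
    cover ages 0..94; rates are annual crude rates deaths/population. The
    ``"all"`` cause key is mandatory.
    """

    pop_mean: np.ndarray
    pop_sd: np.ndarray
    rate_mean: dict[str, np.ndarray]
    rate_sd: dict[str, np.ndarray]
    stratum: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.pop_mean = np.asarray(self.pop_mean, dtype=float)
        self.pop_sd = np.asarray(self.pop_sd, dtype=float)
        for name, arr in (("pop_mean", self.pop_mean), ("pop_sd", self.pop_sd)):
            if arr.shape != (MC_AGES,):
                raise ValueError(f"{name} must cover ages 0..94")
        if "all" not in self.rate_mean:
            raise ValueError("rate stats must include the 'all' cause")
        for d in (self.rate_mean, self.rate_sd):
            for k in list(d):
                d[k] = np.asarray(d[k], dtype=float)
                if d[k].shape != (MC_AGES,):
                    raise ValueError(f"rate array for {k!r} must cover ages 0..94")
        if np.any(self.pop_sd < 0) or any(np.any(s < 0) for s in self.rate_sd.values()):
            raise ValueError("standard deviations must be non-negative")
        if np.any(self.pop_mean < 0):
            raise ValueError("population means must be non-negative")


def cell_stats_from_annual(
    pop_by_year: np.ndarray,
    deaths_by_year: Mapping[str, np.ndarray],
    stratum: Mapping[str, object] | None = None,
) -> CellStats:
    """Build CellStats from age × year matrices of populations and deaths.

    Annual crude rates are deaths/population per year; cells with zero
    population contribute a zero rate for that year. Matrices may cover more
    than 95 ages; only 0..94 are used.
    """
    pop = np.asarray(pop_by_year, dtype=float)[:MC_AGES]
    if pop.ndim != 2 or pop.shape[1] < 2:
        raise ValueError("need an age x year matrix with >= 2 years")
    pm = pop.mean(axis=1)
    ps = pop.std(axis=1, ddof=1)
    rate_mean, rate_sd = {}, {}
    for cause, dmat in deaths_by_year.items():
        d = np.asarray(dmat, dtype=float)[:MC_AGES]
        if d.shape != pop.shape:
            raise ValueError(f"deaths matrix for {cause!r} must match population shape")
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(pop > 0, d / np.where(pop > 0, pop, 1.0), 0.0)
        rate_mean[cause] = rates.mean(axis=1)
        rate_sd[cause] = rates.std(axis=1, ddof=1)
    return CellStats(pm, ps, rate_mean, rate_sd, dict(stratum or {}))


def lhs_normal_draws(
    means: np.ndarray,
    sds: np.ndarray,
    n_trials: int,
    seed: int,
    mode: str = "uniform",
) -> np.ndarray:
    """Latin hypercube draws from independent normals.

    For each dimension the n_trials draws occupy each probability stratum
    (k/n, (k+1)/n) exactly once — at a uniform position within the stratum by
    default, or at the stratum midpoint (``mode="midpoint"``) — mapped through
    the normal inverse CDF and independently permuted across dimensions.
    Returns shape (n_trials, n_dims); deterministic given seed.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    if means.shape != sds.shape:
        raise ValueError("means and sds must have identical shape")
    if np.any(sds < 0):
        raise ValueError("sds must be non-negative")
    d = means.size
    rng = np.random.default_rng(seed)
    strata = np.empty((n_trials, d))
    for j in range(d):
        perm = rng.permutation(n_trials)
        if mode == "uniform":
            u = (perm + rng.uniform(size=n_trials)) / n_trials
        elif mode == "midpoint":
            u = (perm + 0.5) / n_trials
        else:
            raise ValueError(f"unknown LHS mode {mode!r}")
        strata[:, j] = u
    z = stats.norm.ppf(strata)
    return means[None, :] + sds[None, :] * z


@dataclass
class MCResult:
    """Monte Carlo summary for one quantity (LE or a cause's YLL at an age)."""

    quantity: str
    cause: str | None
    age: int
    point: float
    median: float
    ui: tuple[float, float]
    n_trials: int
    seed: int
    trials: np.ndarray = field(repr=False, default=None)
    n_rejected: int = 0
    stratum: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.trials is not None and len(self.trials):
            lo, med, hi = self.ui[0], self.median, self.ui[1]
            if not (lo <= med + 1e-12 and med <= hi + 1e-12):
                raise ValueError("percentiles must be monotone: 2.5th <= median <= 97.5th")

    @property
    def significant(self) -> bool:
        """For difference quantities: UI excludes zero."""
        return self.ui[0] > 0 or self.ui[1] < 0


def _summarise(trials: np.ndarray) -> tuple[float, tuple[float, float]]:
    med = float(np.median(trials))
    lo, hi = np.percentile(trials, [2.5, 97.5])
    return med, (float(lo), float(hi))


def monte_carlo_estimates(
    cell_stats: CellStats,
    n_trials: int = 10_000,
    seed: int = 0,
    quantities: Sequence[tuple[str, str | None, int]] = (("LE", None, 0),),
    a_schedule: np.ndarray | None = None,
    fit_ages: range = range(80, 95),
    omega: int = OMEGA_DEFAULT,
    lhs_mode: str = "uniform",
    deletion_method: str = "chiang",
    max_reject_frac: float = 0.01,
) -> list[MCResult]:
    """Monte Carlo LE/YLL estimates with 95% uncertainty intervals.

    ``quantities`` is a sequence of ("LE", None, age) or ("YLL", cause, age)
    labels. Distinct LHS random-number sets are generated for the all-cause
    schedule and for each cause's rates. Per trial the full estimation path is
    re-run: perturbed crude rates (truncated to [0, 1]) are converted to
    probabilities, the Gompertz tail is refitted, and expectancies are read
    from the rebuilt tables. Trials whose population draws are all zero are
    rejected and logged; more than ``max_reject_frac`` rejections is an error.
    """
    if a_schedule is None:
        a_schedule = default_a_schedule(omega)
    root = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(root.integers(0, 2**31 - 1))

    # population draws: shared across quantities; used for the degeneracy
    # check (rates are perturbed directly, so populations cancel out of the
    # rate-based schedule — see docs/methods.md)
    pop_draws = lhs_normal_draws(
        cell_stats.pop_mean, cell_stats.pop_sd, n_trials, child_seed(), lhs_mode
    )
    pop_draws = np.maximum(pop_draws, 0.0)
    keep = pop_draws.sum(axis=1) > 0
    n_rej = int((~keep).sum())
    if n_rej:
        logger.warning("rejected %d/%d trials with all-zero population draws", n_rej, n_trials)
    if n_rej > max_reject_frac * n_trials:
        raise RuntimeError(
            f"{n_rej}/{n_trials} trials rejected (> {max_reject_frac:.0%}); "
            "perturbation SDs are implausibly large relative to the means"
        )

    causes_needed = sorted({c for kind, c, _ in quantities if kind == "YLL"})

    def draw_rates(cause: str) -> np.ndarray:
        r = lhs_normal_draws(
            cell_stats.rate_mean[cause],
            cell_stats.rate_sd[cause],
            n_trials,
            child_seed(),
            lhs_mode,
        )
        return np.clip(r, 0.0, 1.0)

    # all-cause trial schedules for LE quantities
    m_all_le = draw_rates("all")[keep]
    q_all_le = complete_q_from_m(m_all_le, a_schedule, fit_ages, omega)
    le_ages = sorted({age for kind, _c, age in quantities if kind == "LE"})
    e_le = batch_expectancies(q_all_le, a_schedule, le_ages) if le_ages else None

    # point estimates from period means (the deterministic path)
    q_point = complete_q_from_m(cell_stats.rate_mean["all"], a_schedule, fit_ages, omega)
    all_ages = sorted({age for _k, _c, age in quantities})
    e_point = batch_expectancies(q_point, a_schedule, all_ages)[0]
    e_point = dict(zip(all_ages, e_point))

    # per-cause: distinct all-cause and cause-specific random-number sets
    yll_trials: dict[tuple[str, int], np.ndarray] = {}
    yll_points: dict[tuple[str, int], float] = {}
    for cause in causes_needed:
        m_all = draw_rates("all")[keep]
        m_cause = draw_rates(cause)[keep]
        yll_ages = sorted({age for kind, c, age in quantities if kind == "YLL" and c == cause})
        e_all, e_del = _yll_expectancies(
            m_all, m_cause, a_schedule, fit_ages, omega, yll_ages, deletion_method
        )
        for j, age in enumerate(yll_ages):
            yll_trials[(cause, age)] = e_del[:, j] - e_all[:, j]
        pa, pd_ = _yll_expectancies(
            cell_stats.rate_mean["all"][None, :],
            cell_stats.rate_mean[cause][None, :],
            a_schedule,
            fit_ages,
            omega,
            yll_ages,
            deletion_method,
        )
        for j, age in enumerate(yll_ages):
            yll_points[(cause, age)] = float(pd_[0, j] - pa[0, j])

    results: list[MCResult] = []
    for kind, cause, age in quantities:
        if kind == "LE":
            trials = e_le[:, le_ages.index(age)]
            point = e_point[age]
        elif kind == "YLL":
            trials = yll_trials[(cause, age)]
            point = yll_points[(cause, age)]
        else:
            raise ValueError(f"unknown quantity kind {kind!r}")
        med, ui = _summarise(trials)
        results.append(
            MCResult(
                quantity=kind,
                cause=cause,
                age=age,
                point=point,
                median=med,
                ui=ui,
                n_trials=int(keep.sum()),
                seed=seed,
                trials=trials,
                n_rejected=n_rej,
                stratum=dict(cell_stats.stratum),
            )
        )
    return results


def _yll_expectancies(m_all, m_cause, a_schedule, fit_ages, omega, ages, method):
    """All-cause and cause-deleted expectancies for batches of rate draws.

    The cause fraction f_x = m_cause/m_all (clipped to [0,1]; 0 where the
    all-cause rate is 0) is carried forward from age 94 into the extrapolated
    tail, then Chiang's proportional elimination is applied age by age.
    """
    q_all = complete_q_from_m(m_all, a_schedule, fit_ages, omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_low = np.where(m_all > 0, m_cause / np.where(m_all > 0, m_all, 1.0), 0.0)
    f_low = np.clip(f_low, 0.0, 1.0)
    f = np.concatenate(
        [f_low, np.repeat(f_low[:, -1:], omega + 1 - f_low.shape[1], axis=1)], axis=1
    )
    if method == "chiang":
        q_del = 1.0 - np.power(1.0 - q_all, 1.0 - f)
    elif method == "subtract":
        q_del = np.clip(q_all * (1.0 - f), 0.0, 1.0)
    else:
        raise ValueError(f"unknown deletion method {method!r}")
    q_del[:, -1] = 1.0
    e_all = batch_expectancies(q_all, a_schedule, ages)
    e_del = batch_expectancies(q_del, a_schedule, ages)
    return e_all, e_del


def period_difference(mc_a: MCResult | np.ndarray, mc_b: MCResult | np.ndarray) -> MCResult:
    """Trial-wise difference (b - a) of two independently drawn trial sets.

    The median and 95% UI of the differences are reported; ``significant`` is
    set when the UI excludes zero.
    """
    ta = mc_a.trials if isinstance(mc_a, MCResult) else np.asarray(mc_a, dtype=float)
    tb = mc_b.trials if isinstance(mc_b, MCResult) else np.asarray(mc_b, dtype=float)
    if len(ta) != len(tb):
        raise ValueError(f"trial sets differ in length: {len(ta)} vs {len(tb)}")
    diff = tb - ta
    med, ui = _summarise(diff)
    point = (
        (mc_b.point if isinstance(mc_b, MCResult) else float(np.mean(tb)))
        - (mc_a.point if isinstance(mc_a, MCResult) else float(np.mean(ta)))
    )
    meta = mc_b if isinstance(mc_b, MCResult) else None
    return MCResult(
        quantity=f"delta_{meta.quantity}" if meta else "delta",
        cause=meta.cause if meta else None,
        age=meta.age if meta else -1,
        point=point,
        median=med,
        ui=ui,
        n_trials=len(diff),
        seed=meta.seed if meta else -1,
        trials=diff,
        stratum=dict(meta.stratum) if meta else {},
    )


@dataclass
class GroupCI:
    """Across-district mean of point estimates with a normal 95% CI."""

    mean: float
    se: float
    n: int
    ci: tuple[float, float]


def group_ci(
    point_estimates_by_district: Sequence[float],
    group_mask: Sequence[bool],
) -> dict[bool, GroupCI]:
    """Mean, standard error, and mean +/- 1.96 SE for each district group.

    ``group_mask`` flags membership (e.g. True = includes an evacuation-order
    zone); both groups must contain at least 2 districts.
    """
    values = np.asarray(point_estimates_by_district, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must align")
    out: dict[bool, GroupCI] = {}
    for flag in (True, False):
        v = values[mask == flag]
        if v.size < 2:
            raise ValueError(f"group {flag} has fewer than 2 districts")
        mean = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(v.size))
        out[flag] = GroupCI(mean=mean, se=se, n=int(v.size), ci=(mean - 1.96 * se, mean + 1.96 * se))
    return out


def write_mc_results(results: Sequence[MCResult], path) -> None:
    """CSV writer: quantity, stratum, cause, age, point, median, UI, n, seed."""
    import pandas as pd

    rows = [
        {
            "quantity": r.quantity,
            "period": r.stratum.get("period", ""),
            "sex": r.stratum.get("sex", ""),
            "district": r.stratum.get("district", ""),
            "cause": r.cause or "",
            "age": r.age,
            "point": r.point,
            "median": r.median,
            "ui_low": r.ui[0],
            "ui_high": r.ui[1],
            "n_trials": r.n_trials,
            "seed": r.seed,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
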