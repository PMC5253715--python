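"""Six-month-cycle Markov cohort model extrapolating cost-effectiveness.

State space: four GSS2-derived glaucoma severity stages (PAC/normal, mild,
moderate, severe) crossed with a pre/post subsequent-surgery flag, plus an
absorbing dead state.  Each cycle the cohort faces, in order, all-cause
mortality (age/sex life table, independent of severity and treatment),
a time-dependent transition to glaucoma/cataract surgery (Weibull survival
fitted to the trial's observed time to surgery; exponential available as a
scenario), and severity progression of at most one stage (constant 6-month
probabilities derived from the logistic 36-month progression fit).

State costs and utilities are period-specific for the six trial cycles
(0-6 ... 30-36 months); beyond 36 months the 30-36-month values apply.
Surgery incurs a one-off transition cost.  Standard-care patients who
transit to surgery take the lens-extraction arm's stage utilities from
that point on.  Costs and QALYs are discounted at the cycle-start time;
no half-cycle correction by default.

``run_microsim`` is an individual-level simulation of the identical
process, used as an independent oracle for the cohort trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    ARM_LENS,
    ARM_STANDARD,
    LifeTable,
    PatientRecord,
    SeverityStage,
    ValidationError,
)
from .trial import icer

__all__ = [
    "gss2_stage", "to_cycle_probability", "weibull_cycle_tp",
    "cycle_mortality", "MarkovSpec", "CohortTrace", "run_cohort",
    "run_microsim", "ProgressionFit", "SurgeryFit", "fit_progression",
    "fit_surgery_time", "SURGERY_KINDS", "surgery_durations",
]

N_STAGES = 4
N_PERIODS = 6  # six 6-month periods cover the 36-month trial window

#: Eligible-eye procedure kinds counted as the "subsequent glaucoma or
#: cataract surgery" transition.
SURGERY_KINDS = ("trabeculectomy", "cataract_surgery",
                 "other_glaucoma_procedure")


def gss2_stage(score: int) -> SeverityStage:
    """Severity stage from a GSS2 visual-field score: 0 -> PAC/normal,
    1-4 -> mild, 5-10 -> moderate, 11-16 -> severe."""
    if not 0 <= score <= 16:
        raise ValidationError(f"GSS2 score {score} outside [0, 16]")
    if score == 0:
        return SeverityStage.PAC_normal
    if score <= 4:
        return SeverityStage.mild
    if score <= 10:
        return SeverityStage.moderate
    return SeverityStage.severe


def to_cycle_probability(p36: float) -> float:
    """Constant per-cycle probability whose compounding over the six
    6-month cycles of the trial window equals the 36-month probability:
    p6 = 1 - (1 - p36)^(1/6)."""
    if not 0 <= p36 <= 1:
        raise ValidationError(f"p36={p36} outside [0, 1]")
    return 1.0 - (1.0 - p36) ** (1.0 / 6.0)


def weibull_cycle_tp(t: float, u: float, gamma: float, lam: float) -> float:
    """Time-dependent transition probability over (t, t+u) for Weibull
    survival S(t) = exp(-lam * t^gamma): 1 - S(t+u)/S(t).  Collapses to the
    memoryless 1 - exp(-lam*u) at gamma = 1."""
    if t < 0 or u <= 0:
        raise ValidationError("need t >= 0 and u > 0")
    return 1.0 - math.exp(lam * t ** gamma - lam * (t + u) ** gamma)


def cycle_mortality(age: float, sex: str, life_table: LifeTable,
                    u: float) -> float:
    """Per-cycle death probability from the annual life-table q:
    1 - (1-q)^u."""
    q = life_table.annual_q(age, sex)
    return 1.0 - (1.0 - q) ** u


# -- parameter fitting from trial data ------------------------------------

@dataclass
class ProgressionFit:
    """Saturated logistic fit of 36-month severity progression.

    ``p36[arm][stage]`` are fitted cell probabilities; ``coef``/``cov`` hold
    the cell logits and their covariance for probabilistic analysis.  Cells
    with no observations fall back to the arm's pooled probability.
    """

    p36: dict[str, dict[str, float]]
    coef: np.ndarray
    cov: np.ndarray
    cells: list[tuple[str, str]]
    flagged: list[str] = field(default_factory=list)


def fit_progression(records: Sequence[PatientRecord]) -> ProgressionFit:
    """Logistic regression of "progressed one stage or more by 36 months"
    on arm x baseline stage (saturated, so fitted cell probabilities equal
    empirical proportions).  Severe-stage patients cannot progress further
    and are excluded from the fit."""
    import statsmodels.api as sm
    rows = []
    for rec in records:
        if rec.baseline_stage is None or rec.stage_36m is None:
            continue
        if rec.baseline_stage == SeverityStage.severe:
            continue
        rows.append((rec.arm, rec.baseline_stage.name,
                     int(rec.stage_36m > rec.baseline_stage)))
    if not rows:
        raise ValidationError("no usable records for the progression fit")
    df = pd.DataFrame(rows, columns=["arm", "stage", "prog"])
    grouped = df.groupby(["arm", "stage"])["prog"].agg(["sum", "count"])
    cells = list(grouped.index)
    k = len(cells)
    # identity (one-indicator-per-cell) design => coefficients are cell logits
    successes = grouped["sum"].to_numpy(dtype=float)
    totals = grouped["count"].to_numpy(dtype=float)
    flagged = []
    # continuity correction for separated cells (0 or all progressed)
    sep = (successes == 0) | (successes == totals)
    adj_s = successes + 0.5 * sep
    adj_n = totals + 1.0 * sep
    for (arm, stage), is_sep in zip(cells, sep):
        if is_sep:
            flagged.append(f"separation in cell ({arm}, {stage}); "
                           "continuity-corrected")
    X = np.eye(k)
    model = sm.GLM(np.column_stack([adj_s, adj_n - adj_s]), X,
                   family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    coef = np.asarray(res.params)
    cov = np.asarray(res.cov_params())

    p36: dict[str, dict[str, float]] = {ARM_LENS: {}, ARM_STANDARD: {}}
    pooled = {arm: df[df["arm"] == arm]["prog"].mean()
              for arm in (ARM_LENS, ARM_STANDARD)}
    stage_names = [s.name for s in SeverityStage if s != SeverityStage.severe]
    for arm in (ARM_LENS, ARM_STANDARD):
        for stage in stage_names:
            if (arm, stage) in cells:
                i = cells.index((arm, stage))
                p36[arm][stage] = float(1 / (1 + np.exp(-coef[i])))
            else:
                flagged.append(f"empty cell ({arm}, {stage}); pooled "
                               "probability used")
                p36[arm][stage] = float(pooled[arm])
        p36[arm]["severe"] = 0.0
    return ProgressionFit(p36=p36, coef=coef, cov=cov, cells=cells,
                          flagged=flagged)


@dataclass
class SurgeryFit:
    """Weibull (and nested exponential) fit of time to subsequent surgery.

    The Weibull has a common shape ``gamma`` with an arm effect on scale;
    ``lam`` maps arm -> rate parameter of S(t) = exp(-lam t^gamma) with t in
    **years**.  ``coef``/``cov`` are the AFT parameters (log-scale
    intercept, arm effect, log-shape) for probabilistic analysis.
    ``bic_weibull``/``bic_exponential`` compare the two candidate models.
    """

    gamma: float
    lam: dict[str, float]
    exp_rate: dict[str, float]
    coef: np.ndarray
    cov: np.ndarray
    bic_weibull: float
    bic_exponential: float
    n: int
    n_events: int

    @property
    def preferred(self) -> str:
        return ("weibull" if self.bic_weibull <= self.bic_exponential
                else "exponential")


def surgery_durations(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient time (months) to first subsequent glaucoma/cataract
    surgery in an eligible eye, right-censored at 36 months or death."""
    rows = []
    for rec in records:
        times = [ev.time for ev in rec.events
                 if ev.kind in SURGERY_KINDS and ev.eye != "non_eligible"]
        horizon = 36.0 if rec.death_time is None else min(36.0,
                                                          rec.death_time)
        if times and min(times) <= horizon:
            rows.append((rec.id, rec.arm, max(min(times), 1e-6), 1))
        else:
            rows.append((rec.id, rec.arm, max(horizon, 1e-6), 0))
    return pd.DataFrame(rows, columns=["id", "arm", "time", "event"])


def fit_surgery_time(durations: pd.DataFrame) -> SurgeryFit:
    """Maximum-likelihood Weibull regression (arm on scale, common shape)
    via an accelerated-failure-time fit, with a nested exponential
    regression and BIC for both."""
    from lifelines import WeibullAFTFitter
    df = durations.copy()
    if df["event"].sum() == 0:
        raise ValidationError("no surgery events observed; fit impossible")
    df["standard"] = (df["arm"] == ARM_STANDARD).astype(float)
    aft = WeibullAFTFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aft.fit(df[["time", "event", "standard"]], duration_col="time",
                event_col="event")
    gamma = float(aft.summary.loc[("rho_", "Intercept"), "coef"])
    gamma = float(np.exp(gamma))
    b0 = float(aft.summary.loc[("lambda_", "Intercept"), "coef"])
    b1 = float(aft.summary.loc[("lambda_", "standard"), "coef"])
    # lifelines: S(t) = exp(-(t/exp(Xb))^rho), t in months here
    scale = {ARM_LENS: math.exp(b0), ARM_STANDARD: math.exp(b0 + b1)}
    lam = {a: (12.0 / s) ** gamma for a, s in scale.items()}  # per year^gamma
    n = len(df)
    ll_w = float(aft.log_likelihood_)
    bic_w = -2.0 * ll_w + 3.0 * math.log(n)

    # nested exponential: constant hazard per arm (MLE = events / exposure)
    t = df["time"].to_numpy()
    d = df["event"].to_numpy()
    s_ind = df["standard"].to_numpy()
    exp_rate = {}
    ll_e = 0.0
    for arm, mask in ((ARM_LENS, s_ind == 0), (ARM_STANDARD, s_ind == 1)):
        exposure = t[mask].sum()
        events = d[mask].sum()
        rate_m = events / exposure if exposure > 0 else 0.0  # per month
        exp_rate[arm] = rate_m * 12.0  # per year
        if rate_m > 0:
            ll_e += events * math.log(rate_m) - rate_m * exposure
        else:
            ll_e += 0.0
    bic_e = -2.0 * ll_e + 2.0 * math.log(n)

    params = np.array([b0, b1, math.log(gamma)])
    cov = np.asarray(aft.variance_matrix_)
    return SurgeryFit(gamma=gamma, lam=lam, exp_rate=exp_rate, coef=params,
                      cov=cov, bic_weibull=bic_w, bic_exponential=bic_e,
                      n=n, n_events=int(d.sum()))


# -- the cohort engine -----------------------------------------------------

@dataclass
class MarkovSpec:
    """Everything needed to run one strategy's cohort.

    ``cycle_costs`` and ``cycle_utilities`` are (stage x period) arrays for
    the six trial periods; column 5 also applies beyond 36 months.
    ``post_surgery_utilities`` is the (stage x period) utility array applied
    after the surgery transition (for standard care this is the
    lens-extraction arm's array; for lens extraction it is its own).
    ``surgery_gamma``/``surgery_lam`` parameterise S(t)=exp(-lam t^gamma)
    in years; when ``use_exponential`` the ``surgery_exp_rate`` (per year)
    is used instead.
    """

    arm: str
    entry_stage_dist: np.ndarray  # length 4, sums to 1
    entry_age: float
    female_share: float
    p6: np.ndarray  # per-stage 6-month progression probability
    surgery_gamma: float
    surgery_lam: float
    surgery_exp_rate: float
    surgery_cost: float
    entry_cost: float  # one-off initial intervention cost at model entry
    cycle_costs: np.ndarray  # (4 stages, 6 periods), GBP per cycle
    cycle_utilities: np.ndarray  # (4, 6)
    post_surgery_utilities: np.ndarray  # (4, 6)
    life_table: LifeTable
    discount_rate: float = 0.035
    cycle_length: float = 0.5
    use_exponential: bool = False

    def validate(self) -> None:
        if not math.isclose(float(self.entry_stage_dist.sum()), 1.0,
                            abs_tol=1e-9):
            raise ValidationError("entry stage distribution must sum to 1")
        if np.any((self.p6 < 0) | (self.p6 > 1)):
            raise ValidationError("p6 outside [0, 1]")
        if self.surgery_gamma <= 0 or self.surgery_lam < 0:
            raise ValidationError("Weibull parameters must be positive")

    def surgery_tp(self, t: float) -> float:
        if self.use_exponential:
            return 1.0 - math.exp(-self.surgery_exp_rate * self.cycle_length)
        return weibull_cycle_tp(t, self.cycle_length, self.surgery_gamma,
                                self.surgery_lam)

    def mortality_q(self, t: float) -> float:
        age = self.entry_age + t
        qf = self.life_table.annual_q(age, "F")
        qm = self.life_table.annual_q(age, "M")
        q_mix = self.female_share * qf + (1.0 - self.female_share) * qm
        return 1.0 - (1.0 - q_mix) ** self.cycle_length


@dataclass
class CohortTrace:
    """Per-cycle occupancy (4 pre-surgery + 4 post-surgery stages + dead)
    and discounted cost/QALY increments."""

    occupancy: np.ndarray  # (cycles+1, 9)
    cost_increments: np.ndarray
    qaly_increments: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_increments.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_increments.sum())

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, -1]


def _period_index(k: int) -> int:
    return min(k, N_PERIODS - 1)


def run_cohort_arm(spec: MarkovSpec, horizon_years: float) -> CohortTrace:
    """Deterministic cohort trace for one strategy."""
    spec.validate()
    u = spec.cycle_length
    K = int(round(horizon_years / u))
    occ = np.zeros((K + 1, 2 * N_STAGES + 1))
    occ[0, :N_STAGES] = spec.entry_stage_dist
    costs = np.zeros(K)
    qalys = np.zeros(K)
    r = spec.discount_rate
    costs[0] += spec.entry_cost  # whole cohort, undiscounted at entry
    for k in range(K):
        t = k * u
        disc = (1.0 + r) ** (-t)
        p = _period_index(k)
        pre = occ[k, :N_STAGES].copy()
        post = occ[k, N_STAGES:2 * N_STAGES].copy()
        dead = occ[k, -1]
        # accrual at cycle start, on start-of-cycle occupancy
        costs[k] += disc * (pre @ spec.cycle_costs[:, p]
                            + post @ spec.cycle_costs[:, p])
        qalys[k] = disc * u * (pre @ spec.cycle_utilities[:, p]
                               + post @ spec.post_surgery_utilities[:, p])
        # transitions: mortality -> surgery -> progression
        q = spec.mortality_q(t)
        tp_s = spec.surgery_tp(t)
        new_pre = np.zeros(N_STAGES)
        new_post = np.zeros(N_STAGES)
        new_dead = dead + q * (pre.sum() + post.sum())
        surg_flow = 0.0
        for s in range(N_STAGES):
            alive_pre = pre[s] * (1.0 - q)
            alive_post = post[s] * (1.0 - q)
            to_surg = alive_pre * tp_s
            stay_pre = alive_pre - to_surg
            surg_flow += to_surg
            pp = spec.p6[s] if s < N_STAGES - 1 else 0.0
            # progression among survivors (at most one stage per cycle)
            tgt = min(s + 1, N_STAGES - 1)
            new_pre[s] += stay_pre * (1.0 - pp)
            new_pre[tgt] += stay_pre * pp
            new_post[s] += (alive_post + to_surg) * (1.0 - pp)
            new_post[tgt] += (alive_post + to_surg) * pp
        costs[k] += disc * surg_flow * spec.surgery_cost
        occ[k + 1, :N_STAGES] = new_pre
        occ[k + 1, N_STAGES:2 * N_STAGES] = new_post
        occ[k + 1, -1] = new_dead
        total = occ[k + 1].sum()
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            occ[k + 1] /= total  # guard against accumulated round-off
    return CohortTrace(occupancy=occ, cost_increments=costs,
                       qaly_increments=qalys)


def run_cohort(spec_lens: MarkovSpec, spec_standard: MarkovSpec,
               horizon_years: float) -> dict:
    """Run both strategies and summarise: per-arm discounted totals, ΔC,
    ΔE, and the ICER or dominance label."""
    tr_l = run_cohort_arm(spec_lens, horizon_years)
    tr_s = run_cohort_arm(spec_standard, horizon_years)
    dc = tr_l.total_cost - tr_s.total_cost
    de = tr_l.total_qalys - tr_s.total_qalys
    return {
        "horizon_years": horizon_years,
        "cost_lens": tr_l.total_cost, "cost_standard": tr_s.total_cost,
        "qaly_lens": tr_l.total_qalys, "qaly_standard": tr_s.total_qalys,
        "delta_cost": dc, "delta_qaly": de, "icer": icer(dc, de),
        "trace_lens": tr_l, "trace_standard": tr_s,
    }


def run_microsim_arm(spec: MarkovSpec, horizon_years: float,
                     n_walkers: int, rng: np.random.Generator
                     ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Individual-level simulation of the identical process (oracle).

    Returns mean discounted (cost, qalys) per walker plus the per-walker
    totals for Monte Carlo error estimation."""
    spec.validate()
    u = spec.cycle_length
    K = int(round(horizon_years / u))
    stage = rng.choice(N_STAGES, size=n_walkers, p=spec.entry_stage_dist)
    post = np.zeros(n_walkers, dtype=bool)
    alive = np.ones(n_walkers, dtype=bool)
    cost = np.zeros(n_walkers) + spec.entry_cost
    qaly = np.zeros(n_walkers)
    r = spec.discount_rate
    for k in range(K):
        t = k * u
        disc = (1.0 + r) ** (-t)
        p = _period_index(k)
        # accrual at cycle start
        cost[alive] += disc * spec.cycle_costs[stage[alive], p]
        util_pre = spec.cycle_utilities[stage, p]
        util_post = spec.post_surgery_utilities[stage, p]
        util = np.where(post, util_post, util_pre)
        qaly[alive] += disc * u * util[alive]
        # mortality -> surgery -> progression
        q = spec.mortality_q(t)
        tp_s = spec.surgery_tp(t)
        dies = alive & (rng.random(n_walkers) < q)
        alive = alive & ~dies
        surg = alive & ~post & (rng.random(n_walkers) < tp_s)
        cost[surg] += disc * spec.surgery_cost
        post = post | surg
        pp = np.where(stage < N_STAGES - 1, spec.p6[stage], 0.0)
        prog = alive & (rng.random(n_walkers) < pp)
        stage = np.where(prog, np.minimum(stage + 1, N_STAGES - 1), stage)
    return float(cost.mean()), float(qaly.mean()), cost, qaly


def run_microsim(spec_lens: MarkovSpec, spec_standard: MarkovSpec,
                 horizon_years: float, n_walkers: int, seed: int) -> dict:
    """Microsimulation of both strategies; ``delta_*_se`` are Monte Carlo
    standard errors of the incremental estimates."""
    rng = np.random.default_rng(seed)
    cl, ql, cl_all, ql_all = run_microsim_arm(spec_lens, horizon_years,
                                              n_walkers, rng)
    cs, qs, cs_all, qs_all = run_microsim_arm(spec_standard, horizon_years,
                                              n_walkers, rng)
    dc_se = math.sqrt(cl_all.var(ddof=1) / n_walkers
                      + cs_all.var(ddof=1) / n_walkers)
    de_se = math.sqrt(ql_all.var(ddof=1) / n_walkers
                      + qs_all.var(ddof=1) / n_walkers)
    dc = cl - cs
    de = ql - qs
    return {
        "cost_lens": cl, "cost_standard": cs,
        "qaly_lens": ql, "qaly_standard": qs,
        "delta_cost": dc, "delta_qaly": de,
        "delta_cost_se": dc_se, "delta_qaly_se": de_se,
        "icer": icer(dc, de),
    }
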