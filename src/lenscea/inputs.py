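"""Populate the Markov model from trial data.

State costs reflect mean monitoring (ophthalmology outpatient + primary
care) and medication costs per 6-month window, disaggregated from the
trial's 36-month follow-up to capture the post-intervention trend; state
utilities are per-arm means of the EQ-5D trajectory interpolated at window
midpoints.  Beyond 36 months the 30-36-month values carry forward.
Severity progression and the surgery transition come from the logistic and
Weibull fits in :mod:`lenscea.markov`.

Standard errors are retained per cell so the probabilistic analysis can
assign gamma (costs) and beta (utilities) distributions by method of
moments, and multinormal distributions to the regression coefficient
vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .markov import (
    MarkovSpec,
    N_PERIODS,
    N_STAGES,
    ProgressionFit,
    SurgeryFit,
    fit_progression,
    fit_surgery_time,
    surgery_durations,
    to_cycle_probability,
)
from .records import (
    ARM_LENS,
    ARM_STANDARD,
    ARMS,
    AnalysisConfig,
    LifeTable,
    PatientRecord,
    SeverityStage,
    UnitCostTable,
)

__all__ = ["ModelInputs", "fit_model_inputs", "build_specs"]

#: Model 6-month windows mapped to questionnaire periods: (period index
#: 1..4, share of that period's counts falling in the window).
_WINDOW_PERIOD = [(1, 1.0), (2, 1.0), (3, 0.5), (3, 0.5), (4, 0.5), (4, 0.5)]
_WINDOW_BOUNDS = [(6 * w, 6 * (w + 1)) for w in range(N_PERIODS)]
_WINDOW_MID = [6 * w + 3 for w in range(N_PERIODS)]


@dataclass
class ModelInputs:
    """Point estimates and uncertainty for every model parameter."""

    entry_stage_dist: np.ndarray
    entry_age: float
    female_share: float
    progression: ProgressionFit
    surgery: SurgeryFit
    entry_cost_mean: dict[str, float]  # initial intervention cost per arm
    entry_cost_se: dict[str, float]
    cycle_cost_mean: dict[str, np.ndarray]  # arm -> (6,)
    cycle_cost_se: dict[str, np.ndarray]
    cycle_utility_mean: dict[str, np.ndarray]
    cycle_utility_se: dict[str, np.ndarray]
    surgery_cost_mean: float
    surgery_cost_se: float
    notes: list[str] = field(default_factory=list)


def _interp_utility(rec: PatientRecord, month: float) -> Optional[float]:
    """Linear interpolation of one patient's utility at ``month``; dead
    patients contribute zero; missing neighbours make the value missing."""
    if rec.death_time is not None and month >= rec.death_time:
        return 0.0
    pts = [(0.0, rec.baseline_utility)]
    for m in (6, 12, 24, 36):
        u = rec.utilities.get(m)
        if u is not None:
            pts.append((float(m), u))
    if rec.death_time is not None:
        pts.append((float(rec.death_time), 0.0))
    lo = [(t, u) for t, u in pts if t <= month]
    hi = [(t, u) for t, u in pts if t >= month]
    if not lo or not hi:
        return None
    t0, u0 = lo[-1]
    t1, u1 = hi[0]
    # require adjacent scheduled visits to actually be observed
    sched = [m for m in (0, 6, 12, 24, 36) if t0 < m < t1]
    if any(rec.utilities.get(m) is None
           and (rec.death_time is None or m < rec.death_time)
           for m in sched):
        return None
    if t1 == t0:
        return u0
    return u0 + (u1 - u0) * (month - t0) / (t1 - t0)


def _window_cost(rec: PatientRecord, unit_costs: UnitCostTable, w: int,
                 exclude_non_eligible: bool,
                 include_participant: bool) -> Optional[float]:
    """Monitoring + medication cost of window ``w`` for one patient, or
    ``None`` if the questionnaire cell is missing."""
    from .costing import _classify
    from .markov import SURGERY_KINDS

    lo, hi = _WINDOW_BOUNDS[w]
    if rec.death_time is not None and rec.death_time <= lo:
        return 0.0
    total = 0.0
    # dated events in the window: monitoring attendances and the smaller
    # subsequent procedures.  The initial intervention (entry cost) and the
    # eligible-eye surgery transition (transition cost) are modelled
    # separately and skipped here.
    arm = rec.arm or ARM_STANDARD
    for ev in rec.events:
        if not lo <= ev.time < hi:
            continue
        cat = _classify(ev, arm)
        if cat == "intervention_eligible":
            continue
        if ev.kind in SURGERY_KINDS and ev.eye != "non_eligible":
            continue
        if exclude_non_eligible and ev.eye == "non_eligible":
            continue
        total += unit_costs.procedure_cost(ev.kind)
    # primary care: questionnaire period counts, split across windows
    pidx, share = _WINDOW_PERIOD[w]
    for (ctype, period), count in rec.primary_care.items():
        if period != pidx:
            continue
        if count is None:
            return None
        total += count * unit_costs.contact_cost(ctype) * share
    # medication: months on treatment overlapping the window
    for med in rec.medication_episodes:
        if exclude_non_eligible and med.eye == "non_eligible":
            continue
        overlap = max(0.0, min(med.duration_months, hi) - lo)
        total += overlap * unit_costs.medications_monthly.get(
            med.drug_class, 0.0)
    if include_participant:
        if rec.selfpurchase_cost is None or rec.hours_paid_lost is None:
            return None
        participant = (rec.selfpurchase_cost
                       + rec.travel_cost_per_visit * rec.travel_visits)
        indirect = (rec.hours_paid_lost * unit_costs.wage_paid_hourly
                    + rec.hours_unpaid_lost * unit_costs.value_unpaid_hourly)
        total += (participant + indirect) / N_PERIODS
    return total


def fit_model_inputs(records: Sequence[PatientRecord],
                     unit_costs: UnitCostTable,
                     config: Optional[AnalysisConfig] = None,
                     surgery_cost_mix: Optional[dict[str, float]] = None
                     ) -> ModelInputs:
    """Estimate every Markov input from a trial data set.

    ``surgery_cost_mix`` weights procedure tariffs composing the one-off
    surgery transition cost (default: equal trabeculectomy / day-case
    cataract mix)."""
    config = config or AnalysisConfig()
    records = [r for r in records if r.arm is not None]
    stages = np.zeros(N_STAGES)
    for rec in records:
        if rec.baseline_stage is not None:
            stages[int(rec.baseline_stage)] += 1
    entry_stage_dist = stages / stages.sum()
    entry_age = float(np.mean([r.age for r in records]))
    female_share = float(np.mean([r.sex == "F" for r in records]))

    progression = fit_progression(records)
    surgery = fit_surgery_time(surgery_durations(records))

    from .costing import compute_costs

    cost_mean, cost_se, util_mean, util_se = {}, {}, {}, {}
    entry_mean, entry_se = {}, {}
    notes = []
    for arm in ARMS:
        arm_recs = [r for r in records if r.arm == arm]
        entry = np.array([
            compute_costs(r, unit_costs).intervention_eligible
            for r in arm_recs])
        entry_mean[arm] = float(entry.mean())
        entry_se[arm] = float(entry.std(ddof=1) / math.sqrt(len(entry)))
        cm = np.zeros(N_PERIODS)
        cs = np.zeros(N_PERIODS)
        um = np.zeros(N_PERIODS)
        us = np.zeros(N_PERIODS)
        for w in range(N_PERIODS):
            vals = [_window_cost(r, unit_costs, w,
                                 config.exclude_non_eligible,
                                 config.include_participant_costs)
                    for r in arm_recs]
            vals = np.array([v for v in vals if v is not None])
            cm[w] = vals.mean()
            cs[w] = vals.std(ddof=1) / math.sqrt(len(vals))
            uvals = [_interp_utility(r, _WINDOW_MID[w]) for r in arm_recs]
            uvals = np.array([v for v in uvals if v is not None])
            um[w] = uvals.mean()
            us[w] = uvals.std(ddof=1) / math.sqrt(len(uvals))
        cost_mean[arm], cost_se[arm] = cm, cs
        util_mean[arm], util_se[arm] = um, us

    mix = surgery_cost_mix or {"trabeculectomy": 0.5, "cataract_surgery": 0.5}
    sc = sum(unit_costs.procedure_cost(k) * wgt for k, wgt in mix.items())
    notes.append(f"surgery transition cost = tariff mix {mix}")
    return ModelInputs(
        entry_stage_dist=entry_stage_dist, entry_age=entry_age,
        female_share=female_share, progression=progression, surgery=surgery,
        entry_cost_mean=entry_mean, entry_cost_se=entry_se,
        cycle_cost_mean=cost_mean, cycle_cost_se=cost_se,
        cycle_utility_mean=util_mean, cycle_utility_se=util_se,
        surgery_cost_mean=float(sc), surgery_cost_se=0.1 * float(sc),
        notes=notes,
    )


def _p6_array(p36_by_stage: dict[str, float]) -> np.ndarray:
    return np.array([to_cycle_probability(p36_by_stage[s.name])
                     for s in SeverityStage])


def build_specs(inputs: ModelInputs, life_table: LifeTable,
                config: Optional[AnalysisConfig] = None,
                entry_age: Optional[float] = None,
                use_exponential: Optional[bool] = None
                ) -> tuple[MarkovSpec, MarkovSpec]:
    """Assemble per-arm Markov specs from fitted inputs.

    Stage utilities/costs are window-specific and (absent stage-resolved
    trial estimates) constant across stages within an arm; the standard-care
    spec carries the lens-extraction utility array as its post-surgery
    utility source."""
    config = config or AnalysisConfig()
    if use_exponential is None:
        use_exponential = config.exponential_surgery
    if entry_age is None:
        entry_age = 50.0 if config.entry_age_50 else inputs.entry_age

    def stageify(per_window: np.ndarray) -> np.ndarray:
        return np.tile(per_window, (N_STAGES, 1))

    util = {a: stageify(inputs.cycle_utility_mean[a]) for a in ARMS}
    specs = {}
    for arm in ARMS:
        specs[arm] = MarkovSpec(
            arm=arm,
            entry_stage_dist=inputs.entry_stage_dist.copy(),
            entry_age=entry_age,
            female_share=inputs.female_share,
            p6=_p6_array(inputs.progression.p36[arm]),
            surgery_gamma=inputs.surgery.gamma,
            surgery_lam=inputs.surgery.lam[arm],
            surgery_exp_rate=inputs.surgery.exp_rate[arm],
            surgery_cost=inputs.surgery_cost_mean,
            entry_cost=inputs.entry_cost_mean[arm],
            cycle_costs=stageify(inputs.cycle_cost_mean[arm]),
            cycle_utilities=util[arm],
            post_surgery_utilities=util[ARM_LENS].copy(),
            life_table=life_table,
            discount_rate=config.discount_rate,
            cycle_length=config.cycle_length,
            use_exponential=use_exponential,
        )
    return specs[ARM_LENS], specs[ARM_STANDARD]
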