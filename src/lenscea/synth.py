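"""Synthetic trial-data generator with known ground truth.

The generator emulates the UK cohort of a two-arm pragmatic trial of early
lens extraction versus standard care for primary angle closure (glaucoma):
n=285, minimisation-allocated arms, EQ-5D measured at 0/6/12/24/36 months,
GSS2 severity stages at baseline and 36 months, Weibull-distributed time to
subsequent glaucoma/cataract surgery, Poisson resource-use counts, and
cell-wise missingness at follow-up driven by a logistic
missing-at-random model on arm and prior utility.

Calibration notes
-----------------
* Baseline covariate distributions and per-arm utility trajectory targets
  are the trial's published summary statistics.
* Utilities are drawn from a **censored (clipped) normal** on the EQ-5D
  index range with the location numerically corrected so the post-clipping
  mean equals the target — clipping at 1 reproduces the ceiling effect of
  real EQ-5D data while keeping the sample mean on target.
* Resource-use event rates are back-solved from mean per-category costs
  divided by unit costs and are therefore approximate.
* The single "subsequent surgery" transition (used by the Markov module) is
  drawn from a per-arm Weibull; its kind is then drawn from a per-arm mix so
  category costs still line up.

All draws flow from one ``numpy.random.Generator``; the same seed gives a
bit-identical cohort.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .records import (
    ARM_LENS,
    ARM_STANDARD,
    ARMS,
    EQ5D_MAX,
    EQ5D_MIN,
    FOLLOWUP_MONTHS,
    PERIODS,
    LifeTable,
    MedicationEpisode,
    PatientRecord,
    ProcedureEvent,
    SeverityStage,
    ValidationError,
)
from .io import default_life_table

__all__ = ["GeneratorParams", "generate_cohort", "assign_treatment",
           "simulate_outcomes", "impose_missingness", "generate_trial",
           "clipped_normal_location"]


def _default_utility_targets():
    return {
        ARM_LENS: {0: (0.881, 0.189), 6: (0.903, 0.185), 12: (0.905, 0.159),
                   24: (0.883, 0.196), 36: (0.857, 0.228)},
        ARM_STANDARD: {0: (0.872, 0.190), 6: (0.847, 0.233),
                       12: (0.847, 0.232), 24: (0.847, 0.241),
                       36: (0.845, 0.229)},
    }


def _default_gui_targets():
    return {
        ARM_LENS: {0: (0.877, 0.149), 6: (0.919, 0.094), 12: (0.912, 0.096),
                   24: (0.916, 0.096), 36: (0.919, 0.102)},
        ARM_STANDARD: {0: (0.874, 0.155), 6: (0.880, 0.138),
                       12: (0.879, 0.125), 24: (0.878, 0.125),
                       36: (0.871, 0.142)},
    }


def _default_progression():
    # P(move down one severity stage or more by 36 months), by arm and
    # baseline stage; standard care progresses faster.
    return {
        ARM_LENS: {"PAC_normal": 0.12, "mild": 0.10, "moderate": 0.08,
                   "severe": 0.0},
        ARM_STANDARD: {"PAC_normal": 0.25, "mild": 0.20, "moderate": 0.15,
                       "severe": 0.0},
    }


def _default_event_rates():
    # Expected Poisson counts per patient over 36 months, back-solved from
    # mean category costs / unit tariffs.  (kind, eye) keyed.
    return {
        ARM_LENS: {
            ("lens_capsulotomy", "eligible_index"): 0.1157,
            ("laser_iridotomy", "eligible_index"): 0.0085,
            ("lens_capsulotomy", "non_eligible"): 0.0165,
            ("laser_iridotomy", "non_eligible"): 0.0932,
            ("cataract_surgery", "non_eligible"): 0.3487,
            ("ophthalmology_outpatient", "eligible_index"): 4.66,
        },
        ARM_STANDARD: {
            ("laser_iridotomy", "eligible_index"): 0.1695,
            ("iridoplasty", "eligible_index"): 0.1221,
            ("laser_iridotomy", "non_eligible"): 0.5678,
            ("iridoplasty", "non_eligible"): 0.0174,
            ("cataract_surgery", "non_eligible"): 0.0173,
            ("ophthalmology_outpatient", "eligible_index"): 5.09,
        },
    }


def _default_surgery_kind_mix():
    # Composition of the aggregate "subsequent glaucoma/cataract surgery"
    # event, per arm (shares back-solved from per-category cost means).
    return {
        ARM_LENS: {"trabeculectomy": 0.20, "cataract_surgery": 0.38,
                   "other_glaucoma_procedure": 0.42},
        ARM_STANDARD: {"trabeculectomy": 0.17, "cataract_surgery": 0.72,
                       "other_glaucoma_procedure": 0.11},
    }


def _default_primary_care_rates():
    # Expected visits per patient over 36 months by contact type.
    return {
        ARM_LENS: {"gp_surgery_visit": 1.93, "practice_nurse": 1.61,
                   "district_nurse": 0.80, "community_optician": 1.89},
        ARM_STANDARD: {"gp_surgery_visit": 2.72, "practice_nurse": 8.76,
                       "district_nurse": 4.38, "community_optician": 1.95},
    }


def _default_medication():
    # (probability of any treatment, mean treated fraction of 36 months),
    # by arm and eye class; monthly class cost is in the unit-cost table.
    return {
        ARM_LENS: {"eligible": (0.40, 0.50), "non_eligible": (0.25, 0.289)},
        ARM_STANDARD: {"eligible": (0.90, 0.711),
                       "non_eligible": (0.50, 0.300)},
    }


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic trial."""

    n: int = 285
    allocation_ratio: float = 0.5
    seed: int = 0
    # baseline covariates
    age_mean: float = 67.5
    age_sd: float = 8.42
    age_min: float = 50.0
    p_female: float = 0.575
    p_both_eyes: float = 0.446
    p_pac: float = 0.354
    p_chinese: float = 0.014
    n_centres: int = 22
    pacg_stage_probs: dict = field(default_factory=lambda: {
        "mild": 0.60, "moderate": 0.37, "severe": 0.03})
    baseline_cost_mean: float = 50.0
    baseline_cost_sd: float = 50.0
    # outcome trajectories
    utility_targets: dict = field(default_factory=_default_utility_targets)
    gui_targets: dict = field(default_factory=_default_gui_targets)
    utility_latent_weight: float = 0.6
    # severity progression and surgery
    progression_p36: dict = field(default_factory=_default_progression)
    weibull_shape: dict = field(default_factory=lambda: {
        ARM_LENS: 1.3, ARM_STANDARD: 1.3})
    weibull_scale_months: dict = field(default_factory=lambda: {
        ARM_LENS: 203.3, ARM_STANDARD: 79.6})
    surgery_kind_mix: dict = field(default_factory=_default_surgery_kind_mix)
    # initial interventions
    daycase_prob: float = 0.9
    second_eye_prob: float = 0.53
    initial_iridotomy_extra_rate: float = 0.534
    # resource use
    event_rates: dict = field(default_factory=_default_event_rates)
    primary_care_rates: dict = field(
        default_factory=_default_primary_care_rates)
    medication: dict = field(default_factory=_default_medication)
    medication_class: str = "iop_lowering"
    # participant & indirect inputs
    selfpurchase_mean: float = 250.0
    travel_cost_mean: float = 12.0
    travel_visits_mean: float = 15.0
    hours_paid_mean: dict = field(default_factory=lambda: {
        ARM_LENS: 30.0, ARM_STANDARD: 22.0})
    hours_unpaid_mean: dict = field(default_factory=lambda: {
        ARM_LENS: 47.5, ARM_STANDARD: 35.0})
    # missingness (logistic on arm + prior utility, cell-wise)
    missing_intercept: float = -1.62
    missing_b_standard_arm: float = 0.2
    missing_b_utility: float = -1.5
    # mortality: None -> packaged life table; float -> constant annual hazard
    annual_mortality_hazard: Optional[float] = None

    def validate(self) -> None:
        if self.n < 0:
            raise ValidationError("cohort size n must be >= 0")
        for arm in ARMS:
            if self.weibull_shape[arm] <= 0 or self.weibull_scale_months[arm] <= 0:
                raise ValidationError("Weibull shape/scale must be > 0")
            for p in self.progression_p36[arm].values():
                if not 0 <= p <= 1:
                    raise ValidationError("progression probability outside [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


# -- clipped-normal calibration -------------------------------------------

def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return (lo * stats.norm.cdf(a) + hi * stats.norm.sf(b)
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            - sd * (stats.norm.pdf(b) - stats.norm.pdf(a)))


def clipped_normal_location(target_mean: float, sd: float,
                            lo: float = EQ5D_MIN,
                            hi: float = EQ5D_MAX) -> float:
    """Location mu such that a N(mu, sd) clipped to [lo, hi] has mean
    ``target_mean``."""
    if not lo < target_mean < hi:
        raise ValidationError("target mean must lie inside the clip range")
    return optimize.brentq(
        lambda m: _clipped_normal_mean(m, sd, lo, hi) - target_mean,
        lo - 10 * sd, hi + 10 * sd, xtol=1e-12)


def _gamma_draw(rng, mean, sd, size=None):
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    shape = (mean / sd) ** 2
    return rng.gamma(shape, mean / shape, size=size)


# -- operations ------------------------------------------------------------

def generate_cohort(params: GeneratorParams,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[PatientRecord]:
    """Draw baseline covariates only (no arm, no follow-up)."""
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    records = []
    stages = list(params.pacg_stage_probs)
    stage_p = np.array([params.pacg_stage_probs[s] for s in stages])
    stage_p = stage_p / stage_p.sum()
    # baseline utility: pooled across arms (pre-randomisation)
    means = params.utility_targets
    s0 = float(np.mean([means[a][0][1] for a in ARMS]))
    mu0 = clipped_normal_location(
        float(np.mean([means[a][0][0] for a in ARMS])), s0)
    g_means = params.gui_targets
    gs0 = float(np.mean([g_means[a][0][1] for a in ARMS]))
    gmu0 = clipped_normal_location(
        float(np.mean([g_means[a][0][0] for a in ARMS])), gs0, 0, 1)
    for i in range(params.n):
        diagnosis = "PAC" if rng.random() < params.p_pac else "PACG"
        if diagnosis == "PAC":
            stage = SeverityStage.PAC_normal
        else:
            stage = SeverityStage[stages[rng.choice(len(stages), p=stage_p)]]
        u0 = float(np.clip(rng.normal(mu0, s0), EQ5D_MIN, EQ5D_MAX))
        g0 = float(np.clip(rng.normal(gmu0, gs0), 0.0, 1.0))
        records.append(PatientRecord(
            id=f"P{i:04d}",
            arm=None,
            age=float(max(params.age_min,
                          rng.normal(params.age_mean, params.age_sd))),
            sex="F" if rng.random() < params.p_female else "M",
            ethnicity_chinese=bool(rng.random() < params.p_chinese),
            diagnosis=diagnosis,
            eyes_eligible="both" if rng.random() < params.p_both_eyes
            else "one",
            centre=f"C{rng.integers(params.n_centres) + 1:02d}",
            baseline_stage=stage,
            baseline_cost=float(_gamma_draw(rng, params.baseline_cost_mean,
                                            params.baseline_cost_sd)),
            baseline_utility=u0,
            utilities={0: u0},
            gui={0: g0},
        ))
    return records


def assign_treatment(cohort: Sequence[PatientRecord],
                     factors: Sequence[str] = ("sex", "ethnicity_chinese",
                                               "centre", "diagnosis",
                                               "eyes_eligible"),
                     seed: int = 0,
                     p_biased: float = 0.8) -> list[str]:
    """Minimisation allocation: biased coin toward the arm that minimises
    total within-factor imbalance (probability ``p_biased``); simple 1:1
    randomisation when ``factors`` is empty.  Returns one arm label per
    patient and writes it onto the records.
    """
    for f in factors:
        if not hasattr(cohort[0] if cohort else PatientRecord(
                id="", arm=None, age=0, sex="F", ethnicity_chinese=False,
                diagnosis="PAC", eyes_eligible="one", baseline_utility=0.8),
                f):
            raise ValidationError(f"unknown minimisation factor {f!r}")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str, object], int] = {}
    out = []
    for rec in cohort:
        if not factors:
            arm = ARM_LENS if rng.random() < 0.5 else ARM_STANDARD
        else:
            imb = {}
            for cand in ARMS:
                total = 0
                for f in factors:
                    lvl = getattr(rec, f)
                    n_lens = counts.get((f, ARM_LENS, lvl), 0)
                    n_std = counts.get((f, ARM_STANDARD, lvl), 0)
                    if cand == ARM_LENS:
                        n_lens += 1
                    else:
                        n_std += 1
                    total += abs(n_lens - n_std)
                imb[cand] = total
            if imb[ARM_LENS] == imb[ARM_STANDARD]:
                arm = ARM_LENS if rng.random() < 0.5 else ARM_STANDARD
            else:
                best = min(imb, key=imb.get)
                other = ARM_STANDARD if best == ARM_LENS else ARM_LENS
                arm = best if rng.random() < p_biased else other
            for f in factors:
                lvl = getattr(rec, f)
                counts[(f, arm, lvl)] = counts.get((f, arm, lvl), 0) + 1
        rec.arm = arm
        out.append(arm)
    return out


def _death_time_months(rec: PatientRecord, params: GeneratorParams,
                       life_table: LifeTable,
                       rng: np.random.Generator) -> Optional[float]:
    for month in range(36):
        age = rec.age + month / 12.0
        if params.annual_mortality_hazard is not None:
            q_ann = 1.0 - math.exp(-params.annual_mortality_hazard)
        else:
            q_ann = life_table.annual_q(age, rec.sex)
        q_month = 1.0 - (1.0 - q_ann) ** (1.0 / 12.0)
        if rng.random() < q_month:
            return month + rng.random()
    return None


def simulate_outcomes(cohort: Sequence[PatientRecord],
                      params: GeneratorParams,
                      rng: Optional[np.random.Generator] = None,
                      life_table: Optional[LifeTable] = None
                      ) -> list[PatientRecord]:
    """Fill in follow-up outcomes for an allocated cohort (in place).

    Utilities are drawn per arm per timepoint around the calibrated
    clipped-normal locations with a shared patient latent (weight ``w``)
    inducing within-patient correlation; subsequent surgery time is Weibull
    per arm censored at 36 months; severity progression is Bernoulli per
    arm and baseline stage; resource-use counts are Poisson.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed + 1)
    if life_table is None and params.annual_mortality_hazard is None:
        life_table = default_life_table()
    w = params.utility_latent_weight
    w2 = math.sqrt(max(0.0, 1.0 - w * w))
    # pre-solve clipped-normal locations
    loc = {(a, m): clipped_normal_location(mu, sd)
           for a in ARMS for m, (mu, sd) in params.utility_targets[a].items()}
    gloc = {(a, m): clipped_normal_location(mu, sd, 0.0, 1.0)
            for a in ARMS for m, (mu, sd) in params.gui_targets[a].items()}

    for rec in cohort:
        if rec.arm is None:
            raise ValidationError(f"{rec.id}: no arm assigned")
        arm = rec.arm
        # latent recovered from the baseline draw
        mu0 = np.mean([loc[(a, 0)] for a in ARMS])
        s0 = np.mean([params.utility_targets[a][0][1] for a in ARMS])
        z = float(np.clip((rec.baseline_utility - mu0) / s0, -3.0, 3.0))

        death = _death_time_months(rec, params, life_table, rng)
        rec.death_time = death

        for m in FOLLOWUP_MONTHS[1:]:
            if death is not None and m > death:
                rec.utilities[m] = None
                rec.gui[m] = None
                continue
            mu, sd = params.utility_targets[arm][m]
            draw = loc[(arm, m)] + sd * (w * z + w2 * rng.standard_normal())
            rec.utilities[m] = float(np.clip(draw, EQ5D_MIN, EQ5D_MAX))
            gmu, gsd = params.gui_targets[arm][m]
            gdraw = gloc[(arm, m)] + gsd * (w * z + w2 * rng.standard_normal())
            rec.gui[m] = float(np.clip(gdraw, 0.0, 1.0))

        events: list[ProcedureEvent] = []
        # initial intervention(s)
        if arm == ARM_LENS:
            kind = ("lens_extraction_daycase"
                    if rng.random() < params.daycase_prob
                    else "lens_extraction_inpatient")
            events.append(ProcedureEvent(kind, "eligible_index",
                                         float(rng.uniform(0.0, 2.0))))
            if (rec.eyes_eligible == "both"
                    and rng.random() < params.second_eye_prob):
                kind2 = ("lens_extraction_daycase"
                         if rng.random() < params.daycase_prob
                         else "lens_extraction_inpatient")
                events.append(ProcedureEvent(kind2, "eligible_fellow",
                                             float(rng.uniform(0.0, 2.0))))
        else:
            n_init = 1 + rng.poisson(params.initial_iridotomy_extra_rate)
            for j in range(int(n_init)):
                eye = ("eligible_fellow" if j % 2 == 1
                       and rec.eyes_eligible == "both" else "eligible_index")
                events.append(ProcedureEvent("laser_iridotomy", eye,
                                             float(rng.uniform(0.0, 2.0))))

        # single aggregate subsequent-surgery transition (Weibull)
        scale = params.weibull_scale_months[arm]
        shape = params.weibull_shape[arm]
        if scale > 0 and np.isfinite(scale):
            t_surg = float(scale * rng.weibull(shape))
            if t_surg <= 36.0 and (death is None or t_surg < death):
                mix = params.surgery_kind_mix[arm]
                kinds = list(mix)
                kind = kinds[rng.choice(len(kinds),
                                        p=np.array([mix[k] for k in kinds])
                                        / sum(mix.values()))]
                events.append(ProcedureEvent(kind, "eligible_index", t_surg))

        # background Poisson events
        for (kind, eye), rate in params.event_rates[arm].items():
            for _ in range(int(rng.poisson(rate))):
                t = float(rng.uniform(2.5, 36.0))
                if death is None or t < death:
                    events.append(ProcedureEvent(kind, eye, t))
        rec.events = sorted(events, key=lambda e: e.time)

        # primary care per period, proportional to period length
        rec.primary_care = {}
        for ctype, rate in params.primary_care_rates[arm].items():
            for pidx, (lo, hi) in enumerate(PERIODS, start=1):
                if death is not None and death <= lo:
                    rec.primary_care[(ctype, pidx)] = 0.0
                    continue
                lam = rate * (hi - lo) / 36.0
                rec.primary_care[(ctype, pidx)] = float(rng.poisson(lam))

        # medication episodes
        rec.medication_episodes = []
        for eyeclass, (p_any, frac_mean) in params.medication[arm].items():
            if rng.random() < p_any:
                a_b = 2.0
                b_b = a_b * (1.0 - frac_mean) / frac_mean
                dur = 36.0 * float(rng.beta(a_b, b_b))
                if death is not None:
                    dur = min(dur, death)
                eye = ("eligible_index" if eyeclass == "eligible"
                       else "non_eligible")
                rec.medication_episodes.append(MedicationEpisode(
                    params.medication_class, dur, eye))

        # participant & indirect inputs
        rec.selfpurchase_cost = float(_gamma_draw(
            rng, params.selfpurchase_mean, params.selfpurchase_mean))
        rec.travel_cost_per_visit = float(_gamma_draw(
            rng, params.travel_cost_mean, params.travel_cost_mean / 2))
        rec.travel_visits = float(rng.poisson(params.travel_visits_mean))
        rec.hours_paid_lost = float(_gamma_draw(
            rng, params.hours_paid_mean[arm], params.hours_paid_mean[arm]))
        rec.hours_unpaid_lost = float(_gamma_draw(
            rng, params.hours_unpaid_mean[arm],
            params.hours_unpaid_mean[arm]))

        # 36-month severity stage
        if death is not None and death <= 36.0:
            rec.stage_36m = None
        else:
            p36 = params.progression_p36[arm][rec.baseline_stage.name]
            if rng.random() < p36:
                rec.stage_36m = SeverityStage(
                    min(rec.baseline_stage + 1, SeverityStage.severe))
            else:
                rec.stage_36m = rec.baseline_stage
        rec.validate()
    return list(cohort)


# cells deletable by the missingness model: follow-up utility/GUI at each
# visit, and the resource-use questionnaire for each period (the period-4
# questionnaire also carries the participant-cost items).
def impose_missingness(records: Sequence[PatientRecord],
                       params: GeneratorParams,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Delete follow-up cells via the logistic MAR model.

    Each post-baseline utility cell and each period's resource-use cell is
    independently set missing with probability
    ``expit(a + b_arm * [standard care] + b_u * prior utility)`` where the
    prior utility is the cell's pre-deletion predecessor.  Baseline is never
    deleted.  Returns ``(observed, ground_truth)`` — the complete copy is
    retained for oracle comparisons.
    """
    truth = copy.deepcopy(list(records))
    observed = copy.deepcopy(list(records))
    rng = rng or np.random.default_rng(params.seed + 2)
    a = params.missing_intercept
    b_arm = params.missing_b_standard_arm
    b_u = params.missing_b_utility

    def p_missing(rec, prior_u):
        if prior_u is None:
            prior_u = rec.baseline_utility
        lin = a + b_arm * (rec.arm == ARM_STANDARD) + b_u * prior_u
        return 1.0 / (1.0 + math.exp(-lin))

    months = FOLLOWUP_MONTHS[1:]
    truth_by_id = {t.id: t for t in truth}
    for rec in observed:
        # utility / GUI cells
        for prev_m, m in zip(FOLLOWUP_MONTHS, months):
            if rec.utilities.get(m) is None:
                continue  # already absent (death)
            if rng.random() < p_missing(rec, rec.utilities.get(prev_m)):
                rec.utilities[m] = None
                rec.gui[m] = None
        # resource-use questionnaire cells (one per period)
        for pidx, (lo, hi) in enumerate(PERIODS, start=1):
            if rec.death_time is not None and rec.death_time <= lo:
                continue
            # predictor: pre-deletion utility at the period's end visit
            true_u = truth_by_id[rec.id].utilities.get(int(hi))
            if rng.random() < p_missing(rec, true_u):
                for key in list(rec.primary_care):
                    if key[1] == pidx:
                        rec.primary_care[key] = None
                if pidx == len(PERIODS):
                    rec.selfpurchase_cost = None
                    rec.hours_paid_lost = None
                    rec.hours_unpaid_lost = None
    return observed, truth


def generate_trial(params: GeneratorParams,
                   life_table: Optional[LifeTable] = None
                   ) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Full pipeline: baseline cohort -> minimisation allocation ->
    outcomes -> missingness.  Returns (observed records, ground truth)."""
    rng = np.random.default_rng(params.seed)
    cohort = generate_cohort(params, rng)
    if cohort:
        assign_treatment(cohort, seed=params.seed + 10)
    simulate_outcomes(cohort, params, rng, life_table=life_table)
    return impose_missingness(cohort, params, rng)
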