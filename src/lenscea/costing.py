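"""Per-patient cost construction and QALY area-under-curve.

Costs take the UK NHS perspective by default: every procedure event is
priced at its (kind, setting) tariff, medication at monthly class cost x
duration, primary-care contacts per visit, plus ophthalmology outpatient
attendances.  Participant-borne costs (self-purchased items, travel) and
indirect costs (time lost from paid and unpaid activity, valued at hourly
rates) are constructed separately and only enter the analysis under the
societal-perspective scenario.

QALYs integrate the EQ-5D utility trajectory over the 36-month follow-up by
linear interpolation between measurement points (trapezoid rule).  A zero
utility weight applies from the time of death, with utility declining
linearly from the last observation before death to zero at death.

Questionnaire-derived quantities (primary-care counts, participant items)
may be missing; any category touching a missing cell is ``None`` and so is
the patient's total — such patients fall out of the complete-case set.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

from .records import (
    ARM_LENS,
    ARM_STANDARD,
    FOLLOWUP_MONTHS,
    PERIODS,
    PatientRecord,
    UnitCostTable,
)

__all__ = ["CostBreakdown", "compute_costs", "compute_qalys",
           "IncompleteFollowUp"]

#: Window (months) within which an eligible-eye procedure counts as the
#: initial intervention (protocol: within 60 days of randomisation).
INITIAL_WINDOW_MONTHS = 2.0


class IncompleteFollowUp(ValueError):
    """Follow-up utilities required for a QALY are missing (and no imputed
    value was supplied); the patient is excluded from complete-case sets."""


@dataclass
class CostBreakdown:
    """Per-patient costs (GBP) split by the trial's reporting categories.

    ``None`` marks a category that cannot be computed because a contributing
    questionnaire cell is missing.  ``total_nhs`` sums the NHS-perspective
    components only; participant and indirect costs sit outside it.
    """

    intervention_eligible: float = 0.0
    capsulotomy_eligible: float = 0.0
    iridotomy_eligible: float = 0.0
    iridoplasty_eligible: float = 0.0
    trabeculectomy_eligible: float = 0.0
    cataract_eligible: float = 0.0
    other_eligible: float = 0.0
    medication_eligible: float = 0.0
    capsulotomy_non_eligible: float = 0.0
    iridotomy_non_eligible: float = 0.0
    iridoplasty_non_eligible: float = 0.0
    trabeculectomy_non_eligible: float = 0.0
    lens_cataract_non_eligible: float = 0.0
    other_non_eligible: float = 0.0
    medication_non_eligible: float = 0.0
    gp: Optional[float] = 0.0
    nurse: Optional[float] = 0.0
    optician: Optional[float] = 0.0
    outpatient: float = 0.0
    participant: Optional[float] = 0.0
    indirect: Optional[float] = 0.0

    _NHS_EVENT_FIELDS = (
        "intervention_eligible", "capsulotomy_eligible", "iridotomy_eligible",
        "iridoplasty_eligible", "trabeculectomy_eligible", "cataract_eligible",
        "other_eligible", "medication_eligible", "capsulotomy_non_eligible",
        "iridotomy_non_eligible", "iridoplasty_non_eligible",
        "trabeculectomy_non_eligible", "lens_cataract_non_eligible",
        "other_non_eligible", "medication_non_eligible", "outpatient",
    )
    _NON_ELIGIBLE_FIELDS = (
        "capsulotomy_non_eligible", "iridotomy_non_eligible",
        "iridoplasty_non_eligible", "trabeculectomy_non_eligible",
        "lens_cataract_non_eligible", "other_non_eligible",
        "medication_non_eligible",
    )

    @property
    def total_nhs(self) -> Optional[float]:
        parts = [getattr(self, f) for f in self._NHS_EVENT_FIELDS]
        parts += [self.gp, self.nurse, self.optician]
        if any(p is None for p in parts):
            return None
        return float(sum(parts))

    def total(self, include_participant: bool = False) -> Optional[float]:
        t = self.total_nhs
        if not include_participant:
            return t
        if t is None or self.participant is None or self.indirect is None:
            return None
        return t + self.participant + self.indirect

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        def add(a, b):
            return None if a is None or b is None else a + b
        return CostBreakdown(**{
            f.name: add(getattr(self, f.name), getattr(other, f.name))
            for f in fields(self)
        })


def _classify(event, arm: str) -> str:
    """Map an event to its cost-breakdown category."""
    k, eye = event.kind, event.eye
    eligible = eye != "non_eligible"
    if k == "ophthalmology_outpatient":
        return "outpatient"
    if k in ("lens_extraction_daycase", "lens_extraction_inpatient"):
        if not eligible:
            return "lens_cataract_non_eligible"
        if arm == ARM_LENS:
            return "intervention_eligible"
        return "cataract_eligible"  # standard care: lens removed later
    if k == "cataract_surgery":
        return "cataract_eligible" if eligible else "lens_cataract_non_eligible"
    if k == "laser_iridotomy":
        if eligible and arm == ARM_STANDARD and event.time <= INITIAL_WINDOW_MONTHS:
            return "intervention_eligible"
        return "iridotomy_eligible" if eligible else "iridotomy_non_eligible"
    suffix = "eligible" if eligible else "non_eligible"
    base = {
        "lens_capsulotomy": "capsulotomy",
        "iridoplasty": "iridoplasty",
        "trabeculectomy": "trabeculectomy",
        "other_glaucoma_procedure": "other",
    }[k]
    return f"{base}_{suffix}"


def compute_costs(record: PatientRecord, costs: UnitCostTable,
                  exclude_non_eligible: bool = False) -> CostBreakdown:
    """Price one patient's resource use against the unit-cost table.

    ``exclude_non_eligible`` zeroes procedure and medication costs accrued in
    non-eligible eyes (deterministic sensitivity scenario).  Category sums
    are exact; splitting a record's events across two records and adding the
    breakdowns reproduces the original.
    """
    bd = CostBreakdown()
    arm = record.arm or ARM_STANDARD
    for ev in record.events:
        cat = _classify(ev, arm)
        setattr(bd, cat, getattr(bd, cat) + costs.procedure_cost(ev.kind))
    for med in record.medication_episodes:
        monthly = costs.medications_monthly.get(med.drug_class)
        if monthly is None:
            from .records import CompletenessError
            raise CompletenessError(
                f"no monthly cost for drug class {med.drug_class!r}")
        cat = ("medication_eligible" if med.eye != "non_eligible"
               else "medication_non_eligible")
        setattr(bd, cat, getattr(bd, cat) + monthly * med.duration_months)

    if exclude_non_eligible:
        for f in CostBreakdown._NON_ELIGIBLE_FIELDS:
            setattr(bd, f, 0.0)

    # primary care: GP (surgery/home/phone), nurses, optician
    groups = {"gp": ("gp_surgery_visit", "gp_home_visit", "gp_phone"),
              "nurse": ("practice_nurse", "district_nurse"),
              "optician": ("community_optician",)}
    for cat, ctypes in groups.items():
        total: Optional[float] = 0.0
        for (ctype, _period), count in record.primary_care.items():
            if ctype not in ctypes:
                continue
            if count is None:
                total = None
                break
            total += count * costs.contact_cost(ctype)
        setattr(bd, cat, total)

    # participant-borne: self-purchased items + travel (mode cost x visits)
    if record.selfpurchase_cost is None:
        bd.participant = None
    else:
        bd.participant = (record.selfpurchase_cost
                          + record.travel_cost_per_visit * record.travel_visits)
    # indirect: lost time valued at wage / inferred rates
    if record.hours_paid_lost is None or record.hours_unpaid_lost is None:
        bd.indirect = None
    else:
        bd.indirect = (record.hours_paid_lost * costs.wage_paid_hourly
                       + record.hours_unpaid_lost * costs.value_unpaid_hourly)
    return bd


def compute_qalys(utilities: dict[int, Optional[float]],
                  death_time: Optional[float] = None,
                  horizon_months: float = 36.0) -> float:
    """QALYs (years) from the utility trajectory by trapezoid AUC.

    Linear interpolation between scheduled measurements; if the patient dies,
    utility declines linearly from the last pre-death observation to zero at
    ``death_time`` and stays zero thereafter.  Raises
    :class:`IncompleteFollowUp` if any required (pre-death, pre-horizon)
    utility is missing.
    """
    sched = [m for m in FOLLOWUP_MONTHS if m <= horizon_months]
    if death_time is not None:
        required = [m for m in sched if m < death_time]
    else:
        required = sched
    pts: list[tuple[float, float]] = []
    for m in required:
        u = utilities.get(m)
        if u is None:
            raise IncompleteFollowUp(f"utility missing at month {m}")
        pts.append((float(m), u))
    if not pts:
        raise IncompleteFollowUp("no baseline utility")
    if death_time is not None and death_time <= horizon_months:
        pts.append((float(death_time), 0.0))
        pts.append((float(horizon_months), 0.0))
    elif death_time is not None:
        # death beyond horizon: interpolate toward 0 at death, cut at horizon
        t_last, u_last = pts[-1]
        if t_last < horizon_months:
            u_h = u_last * (death_time - horizon_months) / (death_time - t_last)
            pts.append((float(horizon_months), u_h))
    area = 0.0
    for (t0, u0), (t1, u1) in zip(pts, pts[1:]):
        area += (u0 + u1) / 2.0 * (t1 - t0)
    return area / 12.0


def period_of(time_months: float) -> int:
    """1-based questionnaire period (0-6, 6-12, 12-24, 24-36) containing a
    time; times at a boundary fall in the later period, 36 in the last."""
    for i, (lo, hi) in enumerate(PERIODS, start=1):
        if lo <= time_months < hi:
            return i
    return len(PERIODS)
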