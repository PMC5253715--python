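"""Domain types and validation for the trial data model.

The trial compares early lens extraction against standard care (laser
iridotomy followed by medical therapy and, if needed, glaucoma surgery) in
adults newly diagnosed with primary angle closure (PAC) or primary angle
closure glaucoma (PACG).  One :class:`PatientRecord` holds everything the
economic analysis consumes for a participant: arm, baseline covariates,
EQ-5D utility trajectory over 36 months, glaucoma severity stages, dated
procedure events, primary-care contacts, medication episodes, participant
and time costs, and death time.

Times in the trial data model are **months from randomisation**; the Markov
extrapolation module converts to years.  Utilities are EQ-5D index values
under the UK time trade-off tariff, bounded to [-0.594, 1].  Missing data
are represented as ``None`` (never zero — zero is always a real value).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ARM_LENS",
    "ARM_STANDARD",
    "ARMS",
    "EVENT_KINDS",
    "EYES",
    "CONTACT_TYPES",
    "FOLLOWUP_MONTHS",
    "EQ5D_MIN",
    "EQ5D_MAX",
    "SeverityStage",
    "ProcedureEvent",
    "MedicationEpisode",
    "PatientRecord",
    "UnitCostTable",
    "LifeTable",
    "AnalysisConfig",
    "ValidationError",
    "SchemaError",
    "CompletenessError",
]

ARM_LENS = "lens_extraction"
ARM_STANDARD = "standard_care"
ARMS = (ARM_LENS, ARM_STANDARD)

#: Closed set of costed procedure/contact event kinds.
EVENT_KINDS = (
    "lens_extraction_daycase",
    "lens_extraction_inpatient",
    "laser_iridotomy",
    "lens_capsulotomy",
    "iridoplasty",
    "trabeculectomy",
    "cataract_surgery",
    "other_glaucoma_procedure",
    "ophthalmology_outpatient",
)

EYES = ("eligible_index", "eligible_fellow", "non_eligible")

#: Primary-care contact types priced per visit.
CONTACT_TYPES = (
    "gp_surgery_visit",
    "gp_home_visit",
    "gp_phone",
    "practice_nurse",
    "district_nurse",
    "community_optician",
)

#: EQ-5D / questionnaire follow-up schedule, months from randomisation.
FOLLOWUP_MONTHS = (0, 6, 12, 24, 36)

#: Questionnaire periods between follow-ups, as (start, end) months.
PERIODS = ((0, 6), (6, 12), (12, 24), (24, 36))

EQ5D_MIN = -0.594
EQ5D_MAX = 1.0


class ValidationError(ValueError):
    """A record violates a typed invariant."""


class SchemaError(ValueError):
    """A file does not conform to the documented column dictionary."""


class CompletenessError(KeyError):
    """A lookup table is missing required keys."""


class SeverityStage(enum.IntEnum):
    """Glaucoma severity stage from GSS2 visual-field score cut-offs.

    PAC/normal (score 0) < mild (1-4) < moderate (5-10) < severe (11-16).
    """

    PAC_normal = 0
    mild = 1
    moderate = 2
    severe = 3

    @classmethod
    def from_label(cls, label: str) -> "SeverityStage":
        try:
            return cls[label]
        except KeyError:
            raise ValidationError(f"unknown severity stage {label!r}") from None


@dataclass
class ProcedureEvent:
    """A dated, costed procedure or secondary-care contact."""

    kind: str
    eye: str
    time: float  # months from randomisation

    def validate(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.eye not in EYES:
            raise ValidationError(f"unknown eye {self.eye!r}")
        if not 0 <= self.time <= 36:
            raise ValidationError(
                f"event time {self.time} outside [0, 36] months"
            )


@dataclass
class MedicationEpisode:
    """A spell on an IOP-lowering drug class, priced per month."""

    drug_class: str
    duration_months: float
    eye: str = "eligible_index"

    def validate(self) -> None:
        if self.duration_months < 0:
            raise ValidationError("medication duration must be >= 0")
        if self.eye not in EYES:
            raise ValidationError(f"unknown eye {self.eye!r}")


@dataclass
class PatientRecord:
    """One trial participant.

    ``utilities`` and ``gui`` map follow-up month to index value or ``None``
    (missing).  ``primary_care`` maps ``(contact_type, period)`` — period is
    1-based over the questionnaire intervals 0-6, 6-12, 12-24, 24-36 months —
    to a visit count.  Participant-borne and indirect cost inputs are kept as
    raw quantities (self-purchased spend, travel, lost hours) and valued by
    the costing module.
    """

    id: str
    arm: Optional[str]
    age: float
    sex: str  # {"F", "M"}
    ethnicity_chinese: bool
    diagnosis: str  # {"PAC", "PACG"}
    eyes_eligible: str  # {"one", "both"}
    baseline_utility: float
    baseline_cost: float = 0.0
    utilities: dict[int, Optional[float]] = field(default_factory=dict)
    gui: dict[int, Optional[float]] = field(default_factory=dict)
    baseline_stage: Optional[SeverityStage] = None
    stage_36m: Optional[SeverityStage] = None
    events: list[ProcedureEvent] = field(default_factory=list)
    primary_care: dict[tuple[str, int], Optional[float]] = field(
        default_factory=dict
    )
    medication_episodes: list[MedicationEpisode] = field(default_factory=list)
    selfpurchase_cost: Optional[float] = None
    travel_cost_per_visit: float = 0.0
    travel_visits: float = 0.0
    hours_paid_lost: Optional[float] = None
    hours_unpaid_lost: Optional[float] = None
    centre: str = "C01"
    death_time: Optional[float] = None  # months from randomisation

    def validate(self) -> None:
        if self.arm is not None and self.arm not in ARMS:
            raise ValidationError(f"{self.id}: unknown arm {self.arm!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.id}: unknown sex {self.sex!r}")
        if self.diagnosis not in ("PAC", "PACG"):
            raise ValidationError(
                f"{self.id}: unknown diagnosis {self.diagnosis!r}"
            )
        if self.eyes_eligible not in ("one", "both"):
            raise ValidationError(
                f"{self.id}: eyes_eligible must be 'one' or 'both'"
            )
        if self.death_time is not None and self.death_time < 0:
            raise ValidationError(f"{self.id}: negative death time")
        for month, u in self.utilities.items():
            if month not in FOLLOWUP_MONTHS:
                raise ValidationError(
                    f"{self.id}: utility at unscheduled month {month}"
                )
            if u is not None and not EQ5D_MIN <= u <= EQ5D_MAX:
                raise ValidationError(
                    f"{self.id}: utility {u} at month {month} outside "
                    f"[{EQ5D_MIN}, {EQ5D_MAX}]"
                )
            if (
                u is not None
                and self.death_time is not None
                and month > self.death_time
            ):
                raise ValidationError(
                    f"{self.id}: utility recorded after death "
                    f"(month {month} > death at {self.death_time})"
                )
        for month, g in self.gui.items():
            if g is not None and not 0 <= g <= 1:
                raise ValidationError(
                    f"{self.id}: GUI index {g} outside [0, 1]"
                )
        for ev in self.events:
            ev.validate()
        for med in self.medication_episodes:
            med.validate()
        for (ctype, period), count in self.primary_care.items():
            if ctype not in CONTACT_TYPES:
                raise ValidationError(
                    f"{self.id}: unknown contact type {ctype!r}"
                )
            if period not in (1, 2, 3, 4):
                raise ValidationError(
                    f"{self.id}: primary-care period must be 1..4"
                )
            if count is not None and count < 0:
                raise ValidationError(f"{self.id}: negative contact count")

    # -- convenience -------------------------------------------------------
    def utility_at(self, month: int) -> Optional[float]:
        if month == 0:
            return self.utilities.get(0, self.baseline_utility)
        return self.utilities.get(month)


@dataclass
class UnitCostTable:
    """Unit costs (GBP) for the financial year carried in ``currency_year``.

    ``procedures`` is keyed by event kind (the closed set above); ``contacts``
    by primary-care contact type; ``medications_monthly`` by drug class (cost
    per month on treatment).  Hourly rates value lost paid work and lost
    unpaid (housework/leisure) time in the indirect-cost calculation.
    """

    procedures: dict[str, float]
    contacts: dict[str, float]
    medications_monthly: dict[str, float]
    wage_paid_hourly: float = 13.08
    value_unpaid_hourly: float = 7.00
    currency_year: str = "2012-2013"

    def validate(self) -> None:
        missing = [k for k in EVENT_KINDS if k not in self.procedures]
        if missing:
            raise CompletenessError(
                f"unit-cost table missing procedure kinds: {missing}"
            )
        for name, table in (
            ("procedure", self.procedures),
            ("contact", self.contacts),
            ("medication", self.medications_monthly),
        ):
            for key, cost in table.items():
                if cost < 0:
                    raise ValidationError(
                        f"negative {name} cost for {key!r}"
                    )

    def procedure_cost(self, kind: str) -> float:
        try:
            return self.procedures[kind]
        except KeyError:
            raise CompletenessError(
                f"no unit cost for procedure kind {kind!r}"
            ) from None

    def contact_cost(self, contact_type: str) -> float:
        try:
            return self.contacts[contact_type]
        except KeyError:
            raise CompletenessError(
                f"no unit cost for contact type {contact_type!r}"
            ) from None


class LifeTable:
    """Annual all-cause probability of death by (integer age, sex)."""

    def __init__(self, q: dict[tuple[int, str], float]):
        for (age, sex), prob in q.items():
            if not 0 <= prob <= 1:
                raise ValidationError(
                    f"life-table q({age},{sex})={prob} outside [0,1]"
                )
        self._q = dict(q)
        self.max_age = {
            s: max((a for (a, sx) in q if sx == s), default=None)
            for s in ("F", "M")
        }

    def annual_q(self, age: float, sex: str) -> float:
        """Annual death probability; ages beyond the table clamp to the
        oldest row."""
        a = int(age)
        top = self.max_age.get(sex)
        if top is None:
            raise CompletenessError(f"life table has no rows for sex {sex!r}")
        if a > top:
            a = top
        try:
            return self._q[(a, sex)]
        except KeyError:
            raise CompletenessError(
                f"life table has no row for age {a}, sex {sex!r}"
            ) from None

    def items(self):
        return self._q.items()


@dataclass
class AnalysisConfig:
    """Analysis settings shared across the within-trial and model stages.

    ``rc_grid`` are willingness-to-pay thresholds (GBP/QALY) for the CEAC and
    must include 20 000 and 30 000.  Discounting (3.5%/year by default)
    applies only to the model-based extrapolation; within-trial costs and
    QALYs are undiscounted.  Scenario flags mirror the deterministic
    sensitivity analyses: excluding non-eligible-eye costs, parameterising
    the model from the multiple-imputation data set, adding participant and
    indirect costs, a GLM (log-link) cost model, cohort entry age 50,
    alternative horizons, and an exponential time-to-surgery model.
    """

    rc_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 50001, 2500))
    bootstrap_reps: int = 1000
    psa_iterations: int = 1000
    discount_rate: float = 0.035
    cycle_length: float = 0.5  # years
    horizons: tuple[float, ...] = (3.0, 5.0, 10.0)
    seed: int = 0
    mi_imputations: int = 20
    covariates: tuple[str, ...] = (
        "sex",
        "ethnicity_chinese",
        "diagnosis",
        "eyes_eligible",
        "baseline_cost",
        "baseline_utility",
    )
    include_centre: bool = False
    discount_within_trial: bool = False
    # sensitivity-scenario toggles
    exclude_non_eligible: bool = False
    use_mi_inputs: bool = False
    include_participant_costs: bool = False
    glm_cost_model: bool = False
    entry_age_50: bool = False
    exponential_surgery: bool = False

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be > 0")
        if self.bootstrap_reps < 1 or self.psa_iterations < 1:
            raise ValidationError("reps/iterations must be >= 1")
        if not {20000.0, 30000.0} <= {float(r) for r in self.rc_grid}:
            raise ValidationError("rc_grid must include 20000 and 30000")
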