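"""Readers and writers for the trial data-file set.

The on-disk layout mirrors the CRF/questionnaire split of the source data:
a wide per-patient file plus long-format event, resource-use and medication
files, all comma-delimited UTF-8 with documented headers.

Missing data are encoded as **empty cells**, never sentinels; zero is always
a real value.  ``read_patient_table`` / ``write_patient_table`` round-trip
every field including missing markers.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (
    ARMS,
    CONTACT_TYPES,
    FOLLOWUP_MONTHS,
    AnalysisConfig,
    LifeTable,
    PatientRecord,
    MedicationEpisode,
    ProcedureEvent,
    SchemaError,
    SeverityStage,
    UnitCostTable,
)

PATIENT_FILE = "patients.csv"
EVENT_FILE = "events.csv"
RESOURCE_FILE = "resource_use.csv"
MEDICATION_FILE = "medications.csv"

_PATIENT_COLUMNS = (
    ["id", "arm", "age", "sex", "ethnicity_chinese", "diagnosis",
     "eyes_eligible", "centre", "baseline_stage", "stage_36m",
     "baseline_cost", "baseline_utility"]
    + [f"u{m}" for m in FOLLOWUP_MONTHS]
    + [f"gui{m}" for m in FOLLOWUP_MONTHS]
    + ["selfpurchase_cost", "travel_cost_per_visit", "travel_visits",
       "hours_paid_lost", "hours_unpaid_lost", "death_time"]
)


def _none_if_nan(x):
    if x is None:
        return None
    if isinstance(x, float) and np.isnan(x):
        return None
    if isinstance(x, str) and x == "":
        return None
    return x


def _opt_float(x) -> Optional[float]:
    x = _none_if_nan(x)
    return None if x is None else float(x)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a data directory (patients/events/resource-use/medications CSVs)
    into validated :class:`PatientRecord` objects.

    Raises :class:`SchemaError` naming row and column for unknown labels and
    :class:`~lenscea.records.ValidationError` for invariant violations such
    as out-of-range utilities.
    """
    path = Path(path)
    pat = pd.read_csv(path / PATIENT_FILE, dtype={"id": str, "centre": str},
                      float_precision="round_trip")
    missing_cols = [c for c in _PATIENT_COLUMNS if c not in pat.columns]
    if missing_cols:
        raise SchemaError(f"{PATIENT_FILE} missing columns: {missing_cols}")

    events = _read_long(path / EVENT_FILE,
                        ["patient_id", "kind", "eye", "time_months"])
    resource = _read_long(path / RESOURCE_FILE,
                          ["patient_id", "contact_type", "period", "count"])
    meds = _read_long(path / MEDICATION_FILE,
                      ["patient_id", "drug_class", "duration_months", "eye"])

    records = []
    for i, row in pat.iterrows():
        arm = _none_if_nan(row["arm"])
        if arm is not None and arm not in ARMS:
            raise SchemaError(
                f"{PATIENT_FILE} row {i}, column 'arm': unknown label {arm!r}"
            )
        diagnosis = row["diagnosis"]
        if diagnosis not in ("PAC", "PACG"):
            raise SchemaError(
                f"{PATIENT_FILE} row {i}, column 'diagnosis': "
                f"unknown label {diagnosis!r}"
            )
        rec = PatientRecord(
            id=str(row["id"]),
            arm=arm,
            age=float(row["age"]),
            sex=str(row["sex"]),
            ethnicity_chinese=bool(row["ethnicity_chinese"]),
            diagnosis=str(diagnosis),
            eyes_eligible=str(row["eyes_eligible"]),
            centre=str(row["centre"]),
            baseline_stage=_read_stage(row["baseline_stage"]),
            stage_36m=_read_stage(row["stage_36m"]),
            baseline_cost=float(row["baseline_cost"]),
            baseline_utility=float(row["baseline_utility"]),
            utilities={m: _opt_float(row[f"u{m}"]) for m in FOLLOWUP_MONTHS},
            gui={m: _opt_float(row[f"gui{m}"]) for m in FOLLOWUP_MONTHS},
            selfpurchase_cost=_opt_float(row["selfpurchase_cost"]),
            travel_cost_per_visit=float(row["travel_cost_per_visit"]),
            travel_visits=float(row["travel_visits"]),
            hours_paid_lost=_opt_float(row["hours_paid_lost"]),
            hours_unpaid_lost=_opt_float(row["hours_unpaid_lost"]),
            death_time=_opt_float(row["death_time"]),
        )
        records.append(rec)

    by_id = {r.id: r for r in records}
    for i, row in events.iterrows():
        rec = _lookup(by_id, row["patient_id"], EVENT_FILE, i)
        rec.events.append(ProcedureEvent(
            kind=str(row["kind"]), eye=str(row["eye"]),
            time=float(row["time_months"]),
        ))
    for i, row in resource.iterrows():
        rec = _lookup(by_id, row["patient_id"], RESOURCE_FILE, i)
        rec.primary_care[(str(row["contact_type"]), int(row["period"]))] = (
            _opt_float(row["count"])
        )
    for i, row in meds.iterrows():
        rec = _lookup(by_id, row["patient_id"], MEDICATION_FILE, i)
        rec.medication_episodes.append(MedicationEpisode(
            drug_class=str(row["drug_class"]),
            duration_months=float(row["duration_months"]),
            eye=str(row["eye"]),
        ))

    for rec in records:
        rec.validate()
    return records


def _read_long(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} missing columns: {missing}")
    return df


def _lookup(by_id, pid, fname, i) -> PatientRecord:
    try:
        return by_id[str(pid)]
    except KeyError:
        raise SchemaError(
            f"{fname} row {i}: unknown patient id {pid!r}"
        ) from None


def _read_stage(x) -> Optional[SeverityStage]:
    x = _none_if_nan(x)
    return None if x is None else SeverityStage.from_label(str(x))


def write_patient_table(records: Iterable[PatientRecord],
                        path: str | Path) -> None:
    """Write the four-file data set; inverse of :func:`read_patient_table`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prow, erow, rrow, mrow = [], [], [], []
    for r in records:
        d = {
            "id": r.id, "arm": r.arm, "age": r.age, "sex": r.sex,
            "ethnicity_chinese": r.ethnicity_chinese,
            "diagnosis": r.diagnosis, "eyes_eligible": r.eyes_eligible,
            "centre": r.centre,
            "baseline_stage": None if r.baseline_stage is None
            else r.baseline_stage.name,
            "stage_36m": None if r.stage_36m is None else r.stage_36m.name,
            "baseline_cost": r.baseline_cost,
            "baseline_utility": r.baseline_utility,
            "selfpurchase_cost": r.selfpurchase_cost,
            "travel_cost_per_visit": r.travel_cost_per_visit,
            "travel_visits": r.travel_visits,
            "hours_paid_lost": r.hours_paid_lost,
            "hours_unpaid_lost": r.hours_unpaid_lost,
            "death_time": r.death_time,
        }
        for m in FOLLOWUP_MONTHS:
            d[f"u{m}"] = r.utilities.get(m)
            d[f"gui{m}"] = r.gui.get(m)
        prow.append(d)
        for ev in r.events:
            erow.append({"patient_id": r.id, "kind": ev.kind,
                         "eye": ev.eye, "time_months": ev.time})
        for (ctype, period), count in sorted(r.primary_care.items()):
            rrow.append({"patient_id": r.id, "contact_type": ctype,
                         "period": period, "count": count})
        for med in r.medication_episodes:
            mrow.append({"patient_id": r.id, "drug_class": med.drug_class,
                         "duration_months": med.duration_months,
                         "eye": med.eye})

    pd.DataFrame(prow, columns=_PATIENT_COLUMNS).to_csv(
        path / PATIENT_FILE, index=False)
    pd.DataFrame(erow, columns=["patient_id", "kind", "eye", "time_months"]
                 ).to_csv(path / EVENT_FILE, index=False)
    pd.DataFrame(rrow, columns=["patient_id", "contact_type", "period",
                                "count"]).to_csv(path / RESOURCE_FILE,
                                                 index=False)
    pd.DataFrame(mrow, columns=["patient_id", "drug_class",
                                "duration_months", "eye"]
                 ).to_csv(path / MEDICATION_FILE, index=False)


# -- unit costs & life tables ---------------------------------------------

def read_unit_costs(path: str | Path) -> UnitCostTable:
    """Read a (category, key, value) unit-cost CSV; validates completeness
    over the closed procedure-kind set."""
    df = pd.read_csv(path, dtype=str)
    proc, cont, med, wage = {}, {}, {}, {}
    year = "2012-2013"
    for _, row in df.iterrows():
        cat, key, val = row["category"], row["key"], row["value"]
        if cat == "procedure":
            proc[key] = float(val)
        elif cat == "contact":
            cont[key] = float(val)
        elif cat == "medication_monthly":
            med[key] = float(val)
        elif cat == "wage":
            wage[key] = float(val)
        elif cat == "meta" and key == "currency_year":
            year = str(val)
        else:
            raise SchemaError(f"unknown unit-cost category {cat!r}")
    table = UnitCostTable(
        procedures=proc, contacts=cont, medications_monthly=med,
        wage_paid_hourly=wage.get("paid_hourly", 13.08),
        value_unpaid_hourly=wage.get("unpaid_hourly", 7.00),
        currency_year=year,
    )
    table.validate()
    return table


def default_unit_costs() -> UnitCostTable:
    """The packaged 2012-2013 NHS reference-cost / PSSRU tariff table."""
    with importlib.resources.as_file(
        importlib.resources.files("lenscea.data") / "unit_costs.csv"
    ) as p:
        return read_unit_costs(p)


def read_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    return LifeTable({(int(r.age), str(r.sex)): float(r.q)
                      for r in df.itertuples()})


def default_life_table() -> LifeTable:
    """Packaged synthetic (Gompertz) age/sex life table standing in for
    national all-cause mortality tables."""
    with importlib.resources.as_file(
        importlib.resources.files("lenscea.data") / "life_table_synthetic.csv"
    ) as p:
        return read_life_table(p)


# -- configuration ---------------------------------------------------------

def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for key in ("rc_grid", "horizons", "covariates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = AnalysisConfig(**raw)
    cfg.validate()
    return cfg


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(cfg).items()}
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)


# -- results export --------------------------------------------------------

def write_results(results: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Export result tables as CSV, one file per table, deterministic column
    order (byte-identical on re-export of identical results)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        df.to_csv(path / f"{name}.csv", index=False,
                  float_format="%.10g", lineterminator="\n")
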