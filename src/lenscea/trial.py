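"""Within-trial cost-effectiveness analysis.

Covariate-adjusted arm means by recycled predictions, non-parametric
bootstrap of incremental costs and QALYs, net-monetary-benefit and CEAC
construction, confidence ellipses on the cost-effectiveness plane,
chained-equations multiple imputation for missing follow-up data, and
subgroup analyses.

The estimand is the adjusted incremental cost and QALY for lens extraction
versus standard care over the 36-month trial window (undiscounted).  Cost
and QALY equations share the same regressors, so equation-by-equation least
squares reproduces the seemingly-unrelated-regression point estimates; the
joint patient-level bootstrap preserves the cross-equation error
correlation when quantifying uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costing import CostBreakdown, IncompleteFollowUp, compute_costs, compute_qalys
from .records import (
    ARM_LENS,
    ARM_STANDARD,
    AnalysisConfig,
    PatientRecord,
    UnitCostTable,
    ValidationError,
)

__all__ = [
    "CEEstimate", "CEReplicateSet", "build_analysis_table",
    "adjusted_means", "icer", "nmb", "bootstrap_ce", "ce_ellipse",
    "impute_chained", "pooled_cea", "subgroup_cea", "within_trial_cea",
    "DOMINANT", "DOMINATED", "UNDEFINED",
]

DOMINANT = "dominant (cost saving)"
DOMINATED = "dominated"
UNDEFINED = "undefined"

#: Default adjustment covariates: minimisation factors (centre optional)
#: plus baseline cost and baseline EQ-5D.
DEFAULT_COVARIATES = ("sex", "ethnicity_chinese", "diagnosis",
                      "eyes_eligible", "baseline_cost", "baseline_utility")
_CATEGORICAL = {"sex", "diagnosis", "eyes_eligible", "centre"}


@dataclass
class CEEstimate:
    """Adjusted incremental cost-effectiveness summary for one analysis."""

    cost_standard: float
    cost_lens: float
    qaly_standard: float
    qaly_lens: float
    n_complete: int
    prob_ce: dict[float, float] = field(default_factory=dict)
    nmb_ci: dict[float, tuple[float, float]] = field(default_factory=dict)
    label: str = ""

    @property
    def delta_cost(self) -> float:
        return self.cost_lens - self.cost_standard

    @property
    def delta_qaly(self) -> float:
        return self.qaly_lens - self.qaly_standard

    @property
    def icer(self):
        return icer(self.delta_cost, self.delta_qaly)


@dataclass
class CEReplicateSet:
    """Bootstrap (or PSA) replicates of (ΔC, ΔE) with CEAC evaluations."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    resampling_unit: str = "patient, stratified by arm"
    n_redrawn: int = 0

    def __len__(self) -> int:
        return len(self.delta_cost)

    def ceac(self, rc_grid: Sequence[float]) -> pd.DataFrame:
        rows = []
        for rc in rc_grid:
            inmb = self.delta_qaly * rc - self.delta_cost
            rows.append({"rc": rc, "p_lens": float(np.mean(inmb > 0)),
                         "p_standard": float(np.mean(inmb <= 0))})
        return pd.DataFrame(rows)

    def nmb_interval(self, rc: float, level: float = 0.95
                     ) -> tuple[float, float]:
        inmb = self.delta_qaly * rc - self.delta_cost
        lo, hi = np.percentile(inmb, [50 * (1 - level), 100 - 50 * (1 - level)])
        return float(lo), float(hi)


# -- elementary quantities -------------------------------------------------

def nmb(qalys: float, cost: float, rc: float) -> float:
    """Net monetary benefit: QALYs x willingness-to-pay threshold - cost."""
    return qalys * rc - cost


def icer(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio or a dominance label.

    Positive ΔC / positive ΔE gives the ratio; a cheaper, more effective
    strategy is labelled dominant (cost saving); costlier and less effective
    is dominated; ΔE = 0 gives an undefined label, never a division.
    """
    if delta_qaly == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    return delta_cost / delta_qaly


# -- analysis table --------------------------------------------------------

def build_analysis_table(records: Sequence[PatientRecord],
                         unit_costs: UnitCostTable,
                         config: Optional[AnalysisConfig] = None
                         ) -> pd.DataFrame:
    """One row per patient with total cost, QALYs, covariates, and a
    complete-case flag.  Cost respects the configured perspective
    (NHS-only by default; participant + indirect under the societal
    scenario) and the non-eligible-eye exclusion scenario."""
    config = config or AnalysisConfig()
    rows = []
    for rec in records:
        bd = compute_costs(rec, unit_costs,
                           exclude_non_eligible=config.exclude_non_eligible)
        cost = bd.total(include_participant=config.include_participant_costs)
        try:
            qaly = compute_qalys(
                {0: rec.baseline_utility, **rec.utilities}, rec.death_time)
        except IncompleteFollowUp:
            qaly = None
        rows.append({
            "id": rec.id, "arm": rec.arm,
            "lens": 1.0 if rec.arm == ARM_LENS else 0.0,
            "sex": rec.sex, "ethnicity_chinese": float(rec.ethnicity_chinese),
            "diagnosis": rec.diagnosis, "eyes_eligible": rec.eyes_eligible,
            "centre": rec.centre,
            "baseline_cost": rec.baseline_cost,
            "baseline_utility": rec.baseline_utility,
            "cost": np.nan if cost is None else cost,
            "qaly": np.nan if qaly is None else qaly,
        })
    df = pd.DataFrame(rows)
    df["complete"] = df["cost"].notna() & df["qaly"].notna()
    return df


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Design matrix: intercept + arm indicator + dummy-coded covariates."""
    X = pd.DataFrame({"const": 1.0, "lens": df["lens"].to_numpy()},
                     index=df.index)
    for cov in covariates:
        if cov in _CATEGORICAL:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True,
                                     dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = pd.to_numeric(df[cov])
    # constant columns (single observed level) carry no adjustment
    # information; drop them rather than fail on rank
    keep = [c for c in X.columns
            if c in ("const", "lens") or X[c].nunique() > 1]
    return X[keep]


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name offending columns: ones whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValidationError(
            f"singular design matrix; collinear columns: {bad}")


def adjusted_means(df: pd.DataFrame, outcome: str,
                   covariates: Sequence[str] = DEFAULT_COVARIATES,
                   use_glm: bool = False) -> tuple[float, float]:
    """Adjusted per-arm means of ``outcome`` by recycled predictions.

    Fits outcome ~ arm + covariates (OLS, or a log-link Gamma GLM for the
    sensitivity scenario), predicts every patient under each arm assignment
    and averages.  With no covariates this collapses to the raw arm means.
    Returns ``(mean_standard, mean_lens)``.
    """
    data = df.dropna(subset=[outcome])
    X = _design(data, covariates)
    _check_rank(X)
    y = data[outcome].to_numpy(dtype=float)
    if use_glm:
        model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
    else:
        res = sm.OLS(y, X).fit()
    X1 = X.copy()
    X0 = X.copy()
    X1["lens"] = 1.0
    X0["lens"] = 0.0
    return float(np.mean(res.predict(X0))), float(np.mean(res.predict(X1)))


# -- bootstrap -------------------------------------------------------------

def _point_estimate(df: pd.DataFrame, config: AnalysisConfig
                    ) -> tuple[float, float, float, float]:
    covs = list(config.covariates) + (["centre"] if config.include_centre
                                      else [])
    cs, cl = adjusted_means(df, "cost", covs, use_glm=config.glm_cost_model)
    qs, ql = adjusted_means(df, "qaly", covs)
    return cs, cl, qs, ql


def bootstrap_ce(df: pd.DataFrame, config: AnalysisConfig,
                 seed: Optional[int] = None) -> CEReplicateSet:
    """Patient-level bootstrap, stratified by arm, of the adjusted
    incremental cost and QALY.  Replicates with a singular design are
    redrawn (and counted)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    data = df[df["complete"]].reset_index(drop=True)
    idx_by_arm = {a: data.index[data["arm"] == a].to_numpy()
                  for a in (ARM_LENS, ARM_STANDARD)}
    B = config.bootstrap_reps
    dc = np.empty(B)
    de = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        take = np.concatenate([
            rng.choice(idx, size=len(idx), replace=True)
            for idx in idx_by_arm.values()])
        rep = data.loc[take]
        try:
            cs, cl, qs, ql = _point_estimate(rep, config)
        except ValidationError:
            redrawn += 1
            if redrawn > 10 * B:
                raise
            continue
        dc[b] = cl - cs
        de[b] = ql - qs
        b += 1
    return CEReplicateSet(delta_cost=dc, delta_qaly=de, seed=seed,
                          n_redrawn=redrawn)


def ce_ellipse(replicates: CEReplicateSet, level: float = 0.95) -> dict:
    """Bivariate-normal confidence ellipse of the (ΔE, ΔC) replicate cloud.

    Returns centre, semi-axis lengths, and orientation (degrees,
    anticlockwise from the ΔE axis) at the chi-square(2 df) quantile of
    ``level``.  A degenerate covariance collapses to a segment or point and
    is flagged."""
    from scipy import stats as sps
    if len(replicates) < 3:
        raise ValidationError("need at least 3 replicates for an ellipse")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    pts = np.column_stack([replicates.delta_qaly, replicates.delta_cost])
    centre = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    q = sps.chi2.ppf(level, df=2)
    axes = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
    return {
        "level": level,
        "centre": (float(centre[0]), float(centre[1])),
        "semi_axes": (float(axes[1]), float(axes[0])),  # major, minor
        "angle_deg": angle,
        "degenerate": bool(np.min(evals) <= 1e-300 * max(1.0, np.max(evals))),
    }


# -- multiple imputation ---------------------------------------------------

_MI_PREDICTORS = ("lens", "female", "both_eyes", "pacg", "chinese",
                  "baseline_cost", "baseline_utility")


def _mi_frame(records: Sequence[PatientRecord], unit_costs: UnitCostTable,
              config: AnalysisConfig) -> pd.DataFrame:
    """Rectangular table for chained-equations imputation: follow-up
    utilities, per-category questionnaire costs, and fully-observed
    predictors (event-based NHS cost is CRF-derived and complete)."""
    rows = []
    for rec in records:
        bd = compute_costs(rec, unit_costs,
                           exclude_non_eligible=config.exclude_non_eligible)
        event_cost = sum(getattr(bd, f) for f in CostBreakdown._NHS_EVENT_FIELDS)
        rows.append({
            "id": rec.id,
            "lens": 1.0 if rec.arm == ARM_LENS else 0.0,
            "female": float(rec.sex == "F"),
            "both_eyes": float(rec.eyes_eligible == "both"),
            "pacg": float(rec.diagnosis == "PACG"),
            "chinese": float(rec.ethnicity_chinese),
            "baseline_cost": rec.baseline_cost,
            "baseline_utility": rec.baseline_utility,
            "event_cost": event_cost,
            "u6": rec.utilities.get(6), "u12": rec.utilities.get(12),
            "u24": rec.utilities.get(24), "u36": rec.utilities.get(36),
            "gp_cost": bd.gp, "nurse_cost": bd.nurse,
            "optician_cost": bd.optician,
            "participant_cost": bd.participant, "indirect_cost": bd.indirect,
            "death_time": np.nan if rec.death_time is None else rec.death_time,
        })
    return pd.DataFrame(rows).astype(float, errors="ignore")


def impute_chained(records: Sequence[PatientRecord],
                   unit_costs: UnitCostTable,
                   m: int = 20, seed: int = 0,
                   config: Optional[AnalysisConfig] = None,
                   return_frames: bool = False):
    """Chained-equations multiple imputation (predictive mean matching).

    Imputes per-timepoint utilities and per-category questionnaire costs
    conditional on arm, minimisation factors, baseline cost/utility, and
    observed same-patient values, then rebuilds ``m`` completed analysis
    tables (cost, qaly per patient).  Cells structurally absent through
    death are not treated as missing.  Deterministic under ``seed``.
    """
    from statsmodels.imputation.mice import MICEData
    config = config or AnalysisConfig()
    frame = _mi_frame(records, unit_costs, config)
    impute_cols = ["u6", "u12", "u24", "u36", "gp_cost", "nurse_cost",
                   "optician_cost", "participant_cost", "indirect_cost"]
    # death-truncated utility cells are structural, not missing: fill with 0
    # placeholders during imputation and mask afterwards
    death = frame.pop("death_time")
    struct = {}
    for col, month in (("u6", 6), ("u12", 12), ("u24", 24), ("u36", 36)):
        mask = death.notna() & (death < month)
        struct[col] = mask
        frame.loc[mask, col] = 0.0
    for col in ("gp_cost", "nurse_cost", "optician_cost"):
        struct[col] = pd.Series(False, index=frame.index)

    ids = frame.pop("id")
    fully_missing = [c for c in impute_cols if frame[c].notna().sum() == 0]
    if fully_missing:
        raise ValidationError(
            f"imputation impossible: no observed values for {fully_missing}")

    if not frame[impute_cols].isna().any().any():
        completed = [frame.copy() for _ in range(m)]
    else:
        np.random.seed(seed % (2 ** 31))
        md = MICEData(frame)
        completed = []
        for _ in range(m):
            md.update_all(1)
            completed.append(md.data.copy())

    out = []
    by_id = {r.id: r for r in records}
    for comp in completed:
        comp = comp.copy()
        comp["id"] = ids.to_numpy()
        rows = []
        for _, row in comp.iterrows():
            rec = by_id[row["id"]]
            utils = {0: rec.baseline_utility}
            for col, month in (("u6", 6), ("u12", 12), ("u24", 24),
                               ("u36", 36)):
                if not (rec.death_time is not None
                        and month > rec.death_time):
                    utils[month] = float(row[col])
            qaly = compute_qalys(utils, rec.death_time)
            cost = (row["event_cost"] + row["gp_cost"] + row["nurse_cost"]
                    + row["optician_cost"])
            if config.include_participant_costs:
                cost += row["participant_cost"] + row["indirect_cost"]
            rows.append({
                "id": rec.id, "arm": rec.arm, "lens": row["lens"],
                "sex": rec.sex,
                "ethnicity_chinese": row["chinese"],
                "diagnosis": rec.diagnosis,
                "eyes_eligible": rec.eyes_eligible, "centre": rec.centre,
                "baseline_cost": row["baseline_cost"],
                "baseline_utility": row["baseline_utility"],
                "cost": float(cost), "qaly": float(qaly),
            })
        df = pd.DataFrame(rows)
        df["complete"] = True
        out.append(df)
    if return_frames:
        return out, completed
    return out


def pooled_cea(imputed: Sequence[pd.DataFrame], config: AnalysisConfig,
               records: Optional[Sequence[PatientRecord]] = None,
               unit_costs: Optional[UnitCostTable] = None,
               bootstrap_reps: int = 0, m_per_rep: int = 2,
               seed: Optional[int] = None) -> tuple[CEEstimate,
                                                    Optional[CEReplicateSet]]:
    """Pool adjusted means across completed data sets (average of
    within-imputation estimates).  Uncertainty, when requested, comes from
    bootstrap-then-impute: resample patients, impute within each replicate
    at reduced ``m_per_rep``, re-estimate."""
    if len(imputed) < 2:
        raise ValidationError("pooled analysis needs m >= 2 imputations")
    ests = np.array([_point_estimate(df, config) for df in imputed])
    cs, cl, qs, ql = ests.mean(axis=0)
    est = CEEstimate(cost_standard=cs, cost_lens=cl, qaly_standard=qs,
                     qaly_lens=ql, n_complete=len(imputed[0]),
                     label="multiple imputation")
    reps = None
    if bootstrap_reps > 0:
        if records is None or unit_costs is None:
            raise ValidationError(
                "bootstrap-then-impute needs records and unit costs")
        seed = config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        recs = list(records)
        by_arm = {a: [r for r in recs if r.arm == a]
                  for a in (ARM_LENS, ARM_STANDARD)}
        import copy as _copy
        dc, de = [], []
        for b in range(bootstrap_reps):
            sample = []
            for arm_recs in by_arm.values():
                take = rng.integers(0, len(arm_recs), size=len(arm_recs))
                sample.extend(arm_recs[i] for i in take)
            # re-identify duplicates so imputation treats them as rows
            sample = [_copy.deepcopy(r) for r in sample]
            for j, r in enumerate(sample):
                r.id = f"B{j:05d}"
            comp = impute_chained(sample, unit_costs, m=m_per_rep,
                                  seed=int(rng.integers(2 ** 31)),
                                  config=config)
            e = np.array([_point_estimate(df, config) for df in comp]
                         ).mean(axis=0)
            dc.append(e[1] - e[0])
            de.append(e[3] - e[2])
        reps = CEReplicateSet(np.array(dc), np.array(de), seed=seed,
                              resampling_unit="patient (bootstrap-then-impute)")
        for rc in config.rc_grid:
            inmb = reps.delta_qaly * rc - reps.delta_cost
            est.prob_ce[rc] = float(np.mean(inmb > 0))
            est.nmb_ci[rc] = reps.nmb_interval(rc)
    return est, reps


# -- top level -------------------------------------------------------------

def within_trial_cea(records: Sequence[PatientRecord],
                     unit_costs: UnitCostTable,
                     config: AnalysisConfig,
                     seed: Optional[int] = None
                     ) -> tuple[CEEstimate, CEReplicateSet]:
    """Complete-case within-trial analysis: adjusted means, stratified
    bootstrap, CEAC and NMB intervals over the configured Rc grid."""
    df = build_analysis_table(records, unit_costs, config)
    cc = df[df["complete"]]
    cs, cl, qs, ql = _point_estimate(cc, config)
    est = CEEstimate(cost_standard=cs, cost_lens=cl, qaly_standard=qs,
                     qaly_lens=ql, n_complete=int(df["complete"].sum()),
                     label="complete case")
    reps = bootstrap_ce(df, config, seed=seed)
    for rc in config.rc_grid:
        inmb = reps.delta_qaly * rc - reps.delta_cost
        est.prob_ce[rc] = float(np.mean(inmb > 0))
        est.nmb_ci[rc] = reps.nmb_interval(rc)
    return est, reps


def subgroup_cea(records: Sequence[PatientRecord],
                 unit_costs: UnitCostTable,
                 config: AnalysisConfig,
                 split: str) -> dict[str, tuple[CEEstimate, CEReplicateSet]]:
    """Run the full complete-case pipeline within each level of ``split``
    (``diagnosis`` or ``eyes_eligible``); empty levels are skipped with a
    warning.  The split variable is dropped from the adjustment set."""
    if split not in ("diagnosis", "eyes_eligible"):
        raise ValidationError(f"unsupported subgroup split {split!r}")
    levels = sorted({getattr(r, split) for r in records})
    out = {}
    sub_cfg_covs = tuple(c for c in config.covariates if c != split)
    for level in levels:
        subset = [r for r in records if getattr(r, split) == level]
        n_arms = len({r.arm for r in subset})
        if not subset or n_arms < 2:
            warnings.warn(f"subgroup {split}={level!r} empty or one-armed; "
                          "skipped")
            continue
        import dataclasses
        cfg = dataclasses.replace(config, covariates=sub_cfg_covs)
        out[level] = within_trial_cea(subset, unit_costs, cfg)
    return out
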