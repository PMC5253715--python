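"""Probabilistic sensitivity analysis and result-table assembly.

Second-order Monte Carlo over the model's input parameters: gamma
distributions for cost cells, beta for utility cells (method of moments
from each cell's mean and standard error), and multinormal distributions —
sampled through the Cholesky factor of the estimated covariance — for the
logistic-progression and Weibull time-to-surgery coefficient vectors.
Parameter draws are shared between the two strategies within an iteration
(common random numbers), matching the paired incremental design.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inputs import ModelInputs, build_specs
from .markov import run_cohort
from .records import (
    ARM_LENS,
    ARM_STANDARD,
    ARMS,
    AnalysisConfig,
    LifeTable,
    UnitCostTable,
    PatientRecord,
    ValidationError,
)
from .trial import UNDEFINED, icer, nmb

__all__ = ["ParameterDistribution", "sample_parameter", "run_psa",
           "PSAResult", "build_results_table", "run_scenarios"]


@dataclass
class ParameterDistribution:
    """One uncertain model parameter.

    ``kind`` is one of ``gamma_mean_se`` (costs), ``beta_mean_se``
    (utilities), ``multinormal_coefficients`` (regression parameter
    vectors), or ``fixed``.
    """

    kind: str
    mean: Optional[float] = None
    se: Optional[float] = None
    coef: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None

    def validate(self) -> None:
        if self.kind in ("gamma_mean_se", "beta_mean_se"):
            if self.mean is None or self.se is None or self.se < 0:
                raise ValidationError(f"{self.kind} needs mean and se >= 0")
            if self.kind == "beta_mean_se" and not 0 < self.mean < 1:
                raise ValidationError("beta mean must lie in (0, 1)")
        elif self.kind == "multinormal_coefficients":
            if self.coef is None or self.cov is None:
                raise ValidationError("multinormal needs coef and cov")
        elif self.kind != "fixed":
            raise ValidationError(f"unknown distribution kind {self.kind!r}")


def sample_parameter(dist: ParameterDistribution, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` samples; moment-matched gamma/beta, Cholesky multinormal.

    A zero standard error degenerates to the mean.  A non-positive-
    semi-definite covariance raises with a hint to repair to the nearest
    PSD matrix."""
    dist.validate()
    if dist.kind == "fixed" or (dist.se == 0 and dist.kind != "multinormal_coefficients"):
        return np.full(n, dist.mean if dist.mean is not None else np.nan)
    if dist.kind == "gamma_mean_se":
        if dist.mean <= 0:
            return np.zeros(n)
        shape = (dist.mean / dist.se) ** 2
        scale = dist.se ** 2 / dist.mean
        return rng.gamma(shape, scale, size=n)
    if dist.kind == "beta_mean_se":
        m, v = dist.mean, dist.se ** 2
        if v >= m * (1 - m):
            raise ValidationError(
                "beta se too large for the given mean (variance >= m(1-m))")
        nu = m * (1 - m) / v - 1.0
        return rng.beta(m * nu, (1 - m) * nu, size=n)
    # multinormal via Cholesky
    cov = np.asarray(dist.cov, dtype=float)
    cov = (cov + cov.T) / 2.0
    if not cov.any():  # zero covariance degenerates to the coefficients
        return np.tile(np.asarray(dist.coef, dtype=float), (n, 1))
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        raise ValidationError(
            "covariance not positive semi-definite; consider repairing to "
            "the nearest PSD matrix") from None
    z = rng.standard_normal((n, len(cov)))
    return np.asarray(dist.coef) + z @ chol.T


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PSAResult:
    """Iteration-level strategy (cost, QALY) pairs plus CEAC and means."""

    cost: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    ceac: pd.DataFrame
    seed: int
    n_rejected: int = 0

    @property
    def summary(self) -> dict:
        dc = float(np.mean(self.cost[ARM_LENS] - self.cost[ARM_STANDARD]))
        de = float(np.mean(self.qaly[ARM_LENS] - self.qaly[ARM_STANDARD]))
        return {
            "cost_lens": float(np.mean(self.cost[ARM_LENS])),
            "cost_standard": float(np.mean(self.cost[ARM_STANDARD])),
            "qaly_lens": float(np.mean(self.qaly[ARM_LENS])),
            "qaly_standard": float(np.mean(self.qaly[ARM_STANDARD])),
            "delta_cost": dc, "delta_qaly": de, "icer": icer(dc, de),
        }


def run_psa(inputs: ModelInputs, life_table: LifeTable,
            config: AnalysisConfig, horizon_years: float,
            seed: Optional[int] = None,
            n_iter: Optional[int] = None) -> PSAResult:
    """Second-order Monte Carlo: draw every uncertain parameter once per
    iteration (common draws for both strategies), run both cohorts, and
    summarise.  CEAC(Rc) is the fraction of iterations in which each
    strategy attains the greatest net monetary benefit (NMB ties go to
    standard care).  Iterations yielding invalid probabilities are redrawn
    and counted; more than 1% rejections fails the run."""
    seed = config.seed if seed is None else seed
    n_iter = config.psa_iterations if n_iter is None else n_iter
    rng = np.random.default_rng(seed)
    prog = inputs.progression
    surg = inputs.surgery
    cost_draws = {a: np.column_stack([
        sample_parameter(ParameterDistribution(
            "gamma_mean_se", mean=float(m), se=float(s)), n_iter, rng)
        for m, s in zip(inputs.cycle_cost_mean[a], inputs.cycle_cost_se[a])])
        for a in ARMS}
    util_draws = {a: np.column_stack([
        sample_parameter(ParameterDistribution(
            "beta_mean_se", mean=float(m), se=float(s)), n_iter, rng)
        for m, s in zip(inputs.cycle_utility_mean[a],
                        inputs.cycle_utility_se[a])])
        for a in ARMS}
    logit_draws = sample_parameter(ParameterDistribution(
        "multinormal_coefficients", coef=prog.coef, cov=prog.cov),
        n_iter, rng)
    surg_draws = sample_parameter(ParameterDistribution(
        "multinormal_coefficients", coef=surg.coef, cov=surg.cov),
        n_iter, rng)
    sc_draws = sample_parameter(ParameterDistribution(
        "gamma_mean_se", mean=inputs.surgery_cost_mean,
        se=inputs.surgery_cost_se), n_iter, rng)
    entry_draws = {a: sample_parameter(ParameterDistribution(
        "gamma_mean_se", mean=inputs.entry_cost_mean[a],
        se=inputs.entry_cost_se[a]), n_iter, rng) for a in ARMS}

    cost = {a: np.empty(n_iter) for a in ARMS}
    qaly = {a: np.empty(n_iter) for a in ARMS}
    rejected = 0
    i = 0
    while i < n_iter:
        it = dataclasses.replace(inputs)
        it.cycle_cost_mean = {a: cost_draws[a][i] for a in ARMS}
        it.entry_cost_mean = {a: float(entry_draws[a][i]) for a in ARMS}
        it.cycle_utility_mean = {a: util_draws[a][i] for a in ARMS}
        # progression cell logits -> probabilities
        p36 = {a: dict(prog.p36[a]) for a in ARMS}
        for (arm, stage), logit in zip(prog.cells, logit_draws[i]):
            p36[arm][stage] = float(_expit(logit))
        it.progression = dataclasses.replace(prog, p36=p36)
        # Weibull AFT params -> per-arm rate
        b0, b1, lg = surg_draws[i]
        gam = math.exp(lg)
        lam = {ARM_LENS: (12.0 / math.exp(b0)) ** gam,
               ARM_STANDARD: (12.0 / math.exp(b0 + b1)) ** gam}
        it.surgery = dataclasses.replace(surg, gamma=gam, lam=lam)
        it.surgery_cost_mean = float(sc_draws[i])
        if any(not 0 <= p <= 1 for a in ARMS for p in p36[a].values()):
            rejected += 1
            logit_draws[i] = sample_parameter(ParameterDistribution(
                "multinormal_coefficients", coef=prog.coef, cov=prog.cov),
                1, rng)[0]
            continue
        sl, ss = build_specs(it, life_table, config)
        res = run_cohort(sl, ss, horizon_years)
        cost[ARM_LENS][i] = res["cost_lens"]
        cost[ARM_STANDARD][i] = res["cost_standard"]
        qaly[ARM_LENS][i] = res["qaly_lens"]
        qaly[ARM_STANDARD][i] = res["qaly_standard"]
        i += 1
    if rejected > 0.01 * n_iter:
        raise ValidationError(
            f"{rejected} PSA iterations rejected (> 1% of {n_iter})")

    rows = []
    for rc in config.rc_grid:
        nmb_l = qaly[ARM_LENS] * rc - cost[ARM_LENS]
        nmb_s = qaly[ARM_STANDARD] * rc - cost[ARM_STANDARD]
        p_lens = float(np.mean(nmb_l > nmb_s))  # ties -> standard care
        rows.append({"rc": float(rc), "p_lens": p_lens,
                     "p_standard": 1.0 - p_lens})
    return PSAResult(cost=cost, qaly=qaly, ceac=pd.DataFrame(rows),
                     seed=seed, n_rejected=rejected)


# -- reporting -------------------------------------------------------------

def _fmt_icer(val) -> str:
    if isinstance(val, str):
        return "cost saving" if val.startswith("dominant") else val
    return f"{val:.0f}"


def build_results_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble an incremental cost-effectiveness table.

    Each input row carries a label, per-arm unrounded cost and QALY means
    and optionally probabilities cost-effective at 20 000 and 30 000 GBP.
    Increments are computed on unrounded values; display rounding is costs
    to whole GBP, QALYs and probabilities to 3 dp; a dominant result prints
    "cost saving" instead of a negative ratio."""
    out = []
    for row in rows:
        dc = row["cost_lens"] - row["cost_standard"]
        de = row["qaly_lens"] - row["qaly_standard"]
        out.append({
            "analysis": row.get("label", ""),
            "cost_standard": round(row["cost_standard"]),
            "cost_lens": round(row["cost_lens"]),
            "delta_cost": round(dc),
            "qaly_standard": round(row["qaly_standard"], 3),
            "qaly_lens": round(row["qaly_lens"], 3),
            "delta_qaly": round(de, 3),
            "icer": _fmt_icer(icer(dc, de)),
            "p_ce_20000": (None if row.get("p20") is None
                           else round(row["p20"], 3)),
            "p_ce_30000": (None if row.get("p30") is None
                           else round(row["p30"], 3)),
        })
    return pd.DataFrame(out)


def run_scenarios(records: Sequence[PatientRecord],
                  unit_costs: UnitCostTable,
                  life_table: LifeTable,
                  config: AnalysisConfig,
                  horizon_years: float = 3.0) -> pd.DataFrame:
    """Deterministic scenario harness around the model-based analysis.

    Always runs the base case; each enabled flag on ``config`` adds a row:
    non-eligible-eye cost exclusion, multiple-imputation-based inputs,
    participant + indirect costs, GLM-estimated within-trial means, entry
    age 50, alternative horizons, exponential time to surgery."""
    def model_row(label: str, cfg: AnalysisConfig,
                  recs=None, horizon=horizon_years) -> dict:
        inp = fit_inputs_cached(cfg, recs)
        sl, ss = build_specs(inp, life_table, cfg)
        res = run_cohort(sl, ss, horizon)
        return {"label": label,
                "cost_standard": res["cost_standard"],
                "cost_lens": res["cost_lens"],
                "qaly_standard": res["qaly_standard"],
                "qaly_lens": res["qaly_lens"]}

    from .inputs import fit_model_inputs
    cache: dict = {}

    def fit_inputs_cached(cfg, recs):
        key = (cfg.exclude_non_eligible, cfg.include_participant_costs,
               recs is not None)
        if key not in cache:
            cache[key] = fit_model_inputs(recs if recs is not None
                                          else records, unit_costs, cfg)
        return cache[key]

    base_cfg = dataclasses.replace(
        config, exclude_non_eligible=False, include_participant_costs=False,
        entry_age_50=False, exponential_surgery=False)
    rows = [model_row("base case", base_cfg)]
    if config.exclude_non_eligible:
        rows.append(model_row(
            "1: exclude non-eligible-eye costs",
            dataclasses.replace(base_cfg, exclude_non_eligible=True)))
    if config.use_mi_inputs:
        rows.append(model_row("2: multiple-imputation inputs", base_cfg,
                              recs=_mi_completed_records(records, unit_costs,
                                                         base_cfg,
                                                         config)))
    if config.include_participant_costs:
        rows.append(model_row(
            "3: include participant and indirect costs",
            dataclasses.replace(base_cfg, include_participant_costs=True)))
    if config.glm_cost_model:
        from .trial import within_trial_cea
        cfg = dataclasses.replace(base_cfg, glm_cost_model=True,
                                  bootstrap_reps=1)
        est, _ = within_trial_cea(records, unit_costs, cfg)
        rows.append({"label": "4: GLM-estimated within-trial means",
                     "cost_standard": est.cost_standard,
                     "cost_lens": est.cost_lens,
                     "qaly_standard": est.qaly_standard,
                     "qaly_lens": est.qaly_lens})
    if config.entry_age_50:
        rows.append(model_row(
            "5: cohort entry age 50",
            dataclasses.replace(base_cfg, entry_age_50=True)))
    for h in config.horizons:
        if h != horizon_years:
            rows.append(model_row(f"6: {h:g}-year horizon", base_cfg,
                                  horizon=h))
    if config.exponential_surgery:
        rows.append(model_row(
            "7: exponential time to surgery",
            dataclasses.replace(base_cfg, exponential_surgery=True)))
    return build_results_table(rows)


def _mi_completed_records(records, unit_costs, base_cfg, config):
    """Record copies with missing utility / resource cells replaced by the
    across-imputation mean (used only to refit model inputs under the MI
    scenario)."""
    import copy as _copy
    from statsmodels.imputation.mice import MICEData
    from .trial import _mi_frame

    frame = _mi_frame(records, unit_costs, base_cfg)
    death = frame.pop("death_time")
    for col, month in (("u6", 6), ("u12", 12), ("u24", 24), ("u36", 36)):
        frame.loc[death.notna() & (death < month), col] = 0.0
    ids = frame.pop("id")
    if not frame.isna().any().any():
        return _copy.deepcopy(list(records))
    np.random.seed((config.seed + 7) % (2 ** 31))
    md = MICEData(frame)
    m = min(config.mi_imputations, 5)
    acc = None
    for _ in range(m):
        md.update_all(1)
        acc = md.data.copy() if acc is None else acc + md.data
    mean_frame = acc / m
    mean_frame["id"] = ids.to_numpy()
    by_id = mean_frame.set_index("id")
    out = _copy.deepcopy(list(records))
    for rec in out:
        row = by_id.loc[rec.id]
        for col, month in (("u6", 6), ("u12", 12), ("u24", 24), ("u36", 36)):
            dead = rec.death_time is not None and month > rec.death_time
            if not dead and rec.utilities.get(month) is None:
                rec.utilities[month] = float(
                    np.clip(row[col], -0.594, 1.0))
        # resource cells: replace missing period counts with the arm-level
        # imputed per-period cost is not decomposable to counts; scale the
        # first observed period's counts instead (approximation)
        for (ctype, period), count in list(rec.primary_care.items()):
            if count is None:
                obs = [c for (ct, p), c in rec.primary_care.items()
                       if ct == ctype and c is not None]
                rec.primary_care[(ctype, period)] = (
                    float(np.mean(obs)) if obs else 0.0)
        if rec.selfpurchase_cost is None:
            rec.selfpurchase_cost = float(row["participant_cost"])
            rec.travel_cost_per_visit = 0.0
            rec.travel_visits = 0.0
        if rec.hours_paid_lost is None:
            rec.hours_paid_lost = 0.0
            rec.hours_unpaid_lost = float(row["indirect_cost"] / 7.0)
    return out
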