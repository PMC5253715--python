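"""Within-trial estimation: recycled predictions, bootstrap, CEAC, NMB,
ellipses, imputation, subgroups."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import lenscea as lc
from lenscea.records import ARM_LENS, ARM_STANDARD
from lenscea.trial import (
    DOMINANT,
    DOMINATED,
    UNDEFINED,
    CEReplicateSet,
    _point_estimate,
)


def _synthetic_table(n, delta_q=0.1, delta_c=500.0, seed=0,
                     confounded=False):
    """Analysis table with a known additive treatment effect."""
    rng = np.random.default_rng(seed)
    lens = (np.arange(n) % 2).astype(float)
    base_u = rng.normal(0.85, 0.15, n)
    if confounded:
        base_u += 0.05 * lens  # imbalance the covariate across arms
    qaly = 2.4 + 1.2 * (base_u - 0.85) + delta_q * lens + rng.normal(0, 0.3, n)
    cost = 1500 + 400 * rng.standard_normal(n) + delta_c * lens
    df = pd.DataFrame({
        "id": [f"S{i}" for i in range(n)],
        "arm": np.where(lens == 1, ARM_LENS, ARM_STANDARD),
        "lens": lens, "sex": rng.choice(["F", "M"], n),
        "ethnicity_chinese": 0.0,
        "diagnosis": rng.choice(["PAC", "PACG"], n),
        "eyes_eligible": rng.choice(["one", "both"], n),
        "centre": "C01", "baseline_cost": rng.gamma(2, 25, n),
        "baseline_utility": base_u, "cost": cost, "qaly": qaly,
    })
    df["complete"] = True
    return df


class TestAdjustedMeans:
    def test_no_covariates_collapse_to_raw_means(self):
        df = _synthetic_table(400, seed=1)
        ms, ml = lc.adjusted_means(df, "qaly", covariates=())
        raw = df.groupby("lens")["qaly"].mean()
        assert ms == pytest.approx(raw[0.0])
        assert ml == pytest.approx(raw[1.0])

    def test_recovers_known_treatment_effect(self):
        df = _synthetic_table(5000, delta_q=0.1, seed=2, confounded=True)
        ms, ml = lc.adjusted_means(df, "qaly")
        resid_sd = 0.3
        se = resid_sd * math.sqrt(4 / 5000)
        assert abs((ml - ms) - 0.1) < 2 * se

    def test_balanced_covariates_leave_increment_unmoved(self):
        df = _synthetic_table(10000, seed=3)
        ms, ml = lc.adjusted_means(df, "cost")
        raw = df.groupby("lens")["cost"].mean()
        se = 400 * math.sqrt(4 / 10000)
        assert abs((ml - ms) - (raw[1.0] - raw[0.0])) < 2 * se

    def test_singular_design_names_offending_column(self):
        df = _synthetic_table(50, seed=4)
        df["dup"] = df["baseline_utility"]
        with pytest.raises(lc.records.ValidationError, match="dup"):
            lc.adjusted_means(df, "qaly",
                              covariates=("baseline_utility", "dup"))


class TestIcerAndNmb:
    @pytest.mark.parametrize("dc,de,expected", [
        (-123.0, 0.107, DOMINANT),
        (981.0, 0.069, pytest.approx(14217.39, rel=1e-4)),
        (500.0, -0.05, DOMINATED),
        (0.0, 0.0, UNDEFINED),
        (-100.0, 0.0, UNDEFINED),
    ])
    def test_icer_quadrants(self, dc, de, expected):
        assert lc.icer(dc, de) == expected

    def test_nmb_definition(self):
        assert lc.nmb(2.602, 2467.0, 20000.0) == pytest.approx(49573.0)
        assert lc.nmb(1.0, 750.0, 0.0) == -750.0

    def test_incremental_nmb_zero_at_the_icer(self):
        dc, de = 981.0, 0.069
        rc = dc / de
        assert lc.nmb(de, dc, rc) == pytest.approx(0.0, abs=1e-9)


class TestBootstrap:
    def test_zero_variance_data_gives_degenerate_ceac(self, fast_config):
        df = _synthetic_table(4, seed=5)
        for col in ("cost", "qaly", "baseline_utility", "baseline_cost"):
            df[col] = np.where(df["lens"] == 1,
                               {"cost": 2000.0, "qaly": 2.6,
                                "baseline_utility": 0.9,
                                "baseline_cost": 10.0}[col],
                               {"cost": 1500.0, "qaly": 2.5,
                                "baseline_utility": 0.9,
                                "baseline_cost": 10.0}[col])
        df = pd.concat([df] * 5, ignore_index=True)
        cfg = dataclasses.replace(fast_config, bootstrap_reps=25,
                                  covariates=())
        reps = lc.bootstrap_ce(df, cfg)
        assert np.allclose(reps.delta_cost, 500.0)
        assert np.allclose(reps.delta_qaly, 0.1)
        ceac = reps.ceac(cfg.rc_grid)
        assert set(ceac["p_lens"]) <= {0.0, 1.0}

    def test_ceac_at_zero_rc_is_fraction_cost_saving(self, fast_config):
        df = _synthetic_table(300, delta_c=50.0, seed=6)
        reps = lc.bootstrap_ce(df, fast_config)
        p0 = reps.ceac([0.0])["p_lens"].iloc[0]
        assert p0 == pytest.approx(np.mean(reps.delta_cost < 0))

    def test_ceac_monotone_when_all_replicates_gain_qalys(self):
        rng = np.random.default_rng(7)
        reps = CEReplicateSet(rng.normal(500, 300, 1000),
                              rng.uniform(0.01, 0.2, 1000), seed=7)
        ceac = reps.ceac(np.arange(0, 50001, 2500.0))
        assert (np.diff(ceac["p_lens"]) >= 0).all()

    def test_crosses_half_near_true_icer(self):
        """Large-sample CEAC crosses 0.5 near ΔC/ΔE and approaches 1 well
        above it."""
        df = _synthetic_table(5000, delta_q=0.1, delta_c=500.0, seed=8)
        cfg = dataclasses.replace(lc.AnalysisConfig(), bootstrap_reps=200,
                                  seed=8)
        reps = lc.bootstrap_ce(df, cfg)
        rc_grid = np.arange(0, 30001, 500.0)
        ceac = reps.ceac(rc_grid)["p_lens"].to_numpy()
        crossing = rc_grid[np.argmax(ceac >= 0.5)]
        assert abs(crossing - 5000.0) < 2000.0
        assert ceac[-1] > 0.95

    def test_seed_reproducible(self, fast_config):
        df = _synthetic_table(200, seed=9)
        a = lc.bootstrap_ce(df, fast_config)
        b = lc.bootstrap_ce(df, fast_config)
        assert np.array_equal(a.delta_cost, b.delta_cost)


class TestEllipse:
    def test_coverage_of_bivariate_normal(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((100000, 2))
        reps = CEReplicateSet(pts[:, 1], pts[:, 0], seed=10)
        ell = lc.ce_ellipse(reps, 0.95)
        a, b = ell["semi_axes"]
        # isotropic cloud: axis ratio ~ 1
        assert a / b == pytest.approx(1.0, abs=0.05)
        # Monte Carlo coverage of the fitted ellipse ~ 95%
        th = math.radians(ell["angle_deg"])
        dx = pts[:, 0] - ell["centre"][0]
        dy = pts[:, 1] - ell["centre"][1]
        major = np.cos(th) * dx + np.sin(th) * dy
        minor = -np.sin(th) * dx + np.cos(th) * dy
        inside = np.mean((major / a) ** 2 + (minor / b) ** 2 <= 1.0)
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_identical_replicates_flagged_degenerate(self):
        reps = CEReplicateSet(np.full(10, 5.0), np.full(10, 0.1), seed=0)
        ell = lc.ce_ellipse(reps, 0.5)
        assert ell["degenerate"]

    def test_too_few_replicates_rejected(self):
        reps = CEReplicateSet(np.array([1.0, 2.0]), np.array([0.1, 0.2]),
                              seed=0)
        with pytest.raises(lc.records.ValidationError):
            lc.ce_ellipse(reps)


class TestImputation:
    def test_no_missing_cells_returns_identical_copies(self, unit_costs):
        params = dataclasses.replace(lc.GeneratorParams(n=50, seed=11),
                                     missing_intercept=-50.0)
        observed, _ = lc.generate_trial(params)
        sets = lc.impute_chained(observed, unit_costs, m=3, seed=1)
        assert len(sets) == 3
        for df in sets[1:]:
            pd.testing.assert_frame_equal(df, sets[0])

    def test_pmm_draws_lie_within_observed_support(self, trial_cohort,
                                                   unit_costs):
        obs, _ = trial_cohort
        _tables, frames = lc.impute_chained(obs, unit_costs, m=2, seed=2,
                                            return_frames=True)
        for col in ("u6", "u12", "u24", "u36"):
            observed = [r.utilities.get(int(col[1:])) for r in obs]
            observed = [u for u in observed if u is not None]
            lo, hi = min(observed), max(observed)
            for frame in frames:
                vals = frame[col].to_numpy()
                assert vals.min() >= min(lo, 0.0) - 1e-12
                assert vals.max() <= hi + 1e-12

    def test_mcar_deletion_recovers_full_data_mean(self, unit_costs):
        """Pooled MI mean QALY after 30% MCAR deletion sits within two
        standard errors of the complete-data mean."""
        params = dataclasses.replace(lc.GeneratorParams(n=400, seed=12),
                                     missing_intercept=-50.0)
        observed, _ = lc.generate_trial(params)
        full = lc.build_analysis_table(observed, unit_costs)
        rng = np.random.default_rng(3)
        for rec in observed:
            for m in (6, 12, 24, 36):
                if rec.utilities.get(m) is not None and rng.random() < 0.3:
                    rec.utilities[m] = None
        sets = lc.impute_chained(observed, unit_costs, m=5, seed=4)
        pooled = np.mean([df["qaly"].mean() for df in sets])
        se = full["qaly"].std() / math.sqrt(len(full))
        assert abs(pooled - full["qaly"].mean()) < 2 * se

    def test_fully_missing_variable_is_an_error(self, unit_costs):
        observed, _ = lc.generate_trial(lc.GeneratorParams(n=30, seed=13))
        for rec in observed:
            if rec.death_time is None or rec.death_time > 6:
                rec.utilities[6] = None
        with pytest.raises(lc.records.ValidationError, match="u6"):
            lc.impute_chained(observed, unit_costs, m=2, seed=5)


class TestSubgroups:
    def test_constant_split_level_equals_full_analysis(self, unit_costs,
                                                       fast_config):
        observed, _ = lc.generate_trial(lc.GeneratorParams(n=80, seed=14))
        for rec in observed:
            rec.diagnosis = "PACG"
        cfg = dataclasses.replace(
            fast_config, bootstrap_reps=10,
            covariates=tuple(c for c in fast_config.covariates
                             if c != "diagnosis"))
        full, _ = lc.within_trial_cea(observed, unit_costs, cfg)
        groups = lc.subgroup_cea(observed, unit_costs, cfg, "diagnosis")
        assert list(groups) == ["PACG"]
        est = groups["PACG"][0]
        assert est.delta_cost == pytest.approx(full.delta_cost)
        assert est.delta_qaly == pytest.approx(full.delta_qaly)

    def test_unadjusted_level_increment_is_arm_mean_difference(
            self, unit_costs, trial_cohort):
        obs, _ = trial_cohort
        cfg = dataclasses.replace(lc.AnalysisConfig(), covariates=(),
                                  bootstrap_reps=5, seed=1)
        groups = lc.subgroup_cea(obs, unit_costs, cfg, "eyes_eligible")
        df = lc.build_analysis_table(obs, unit_costs, cfg)
        cc = df[df["complete"]]
        for level, (est, _) in groups.items():
            sub = cc[cc["eyes_eligible"] == level]
            raw = sub.groupby("lens")["cost"].mean()
            assert est.delta_cost == pytest.approx(raw[1.0] - raw[0.0])
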