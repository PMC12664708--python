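"""Normality screening, adjusted regressions, and mixed models."""

import numpy as np
import pandas as pd
import pytest

import vrmaze_gait as vg
from vrmaze_gait.stats import (
    TRANSFORM_LOG,
    TRANSFORM_NONE,
    TRANSFORM_REFUSED,
    adjusted_regression,
    build_association_table,
    condition_visit_mixed_model,
    screen_and_transform,
)


def ols_oracle(y, X):
    """Independent oracle: normal-equations solution via lstsq."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class TestScreenAndTransform:
    def test_lognormal_flagged_and_transformed(self):
        rng = np.random.default_rng(0)
        raw = np.exp(rng.normal(1.0, 0.8, 500))
        out, flag = screen_and_transform(raw)
        assert flag == TRANSFORM_LOG
        np.testing.assert_allclose(np.exp(out), raw)  # exact inverse

    def test_normal_data_usually_untouched(self):
        flags = [
            screen_and_transform(np.random.default_rng(s).normal(10, 2, 500))[1]
            for s in range(100)
        ]
        frac = np.mean([f == TRANSFORM_NONE for f in flags])
        # pass fraction ~ 1 - alpha; allow 3 binomial SEs around 0.95
        assert abs(frac - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / 100)

    def test_nonpositive_nonnormal_refused(self):
        rng = np.random.default_rng(1)
        raw = np.exp(rng.normal(0, 1, 300)) - 1.0  # non-normal, some negatives
        out, flag = screen_and_transform(raw)
        assert flag == TRANSFORM_REFUSED
        np.testing.assert_array_equal(out, raw)

    def test_tiny_sample_fatal(self):
        with pytest.raises(ValueError):
            screen_and_transform(np.array([1.0, 2.0]))


class TestAdjustedRegression:
    def test_matches_normal_equations_oracle(self):
        coh = vg.generate_cohort(200, seed=3)
        r = adjusted_regression("stride_velocity", "tmt_a", coh, transform=False)
        X = np.column_stack(
            [
                np.ones(len(coh)),
                coh["tmt_a"],
                coh["age"],
                (coh["sex"] == "M").astype(float),
                coh["education"],
                coh["height"],
                coh["weight"],
            ]
        )
        beta = ols_oracle(coh["stride_velocity"].to_numpy(), X)
        assert r.coef == pytest.approx(beta[1], abs=1e-8)

    def test_planted_slope_recovered_in_ci(self):
        beta = -0.02
        coh = vg.generate_cohort(
            500, seed=4, planted_effects={("stride_velocity", "logical_memory_delayed"): beta}
        )
        r = adjusted_regression("stride_velocity", "logical_memory_delayed", coh)
        lo, hi = r.conf_int
        assert lo <= beta <= hi
        assert r.pvalue < 0.05

    def test_effect_through_covariate_is_adjusted_away(self):
        # outcome depends only on age; age correlates with the score by
        # construction, yet the adjusted score coefficient should be ~0
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            coh = vg.generate_cohort(300, seed=s, include_outcomes=False)
            coh["tmt_a"] = coh["tmt_a"] + 1.5 * (coh["age"] - 67.8)
            coh["stride_velocity"] = 2.0 - 0.01 * coh["age"] + rng.normal(0, 0.05, 300)
            r = adjusted_regression("stride_velocity", "tmt_a", coh, transform=False)
            if abs(r.coef) < 2 * r.se:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_too_few_complete_cases_fatal(self):
        coh = vg.generate_cohort(10, seed=0)
        with pytest.raises(ValueError, match="complete cases"):
            adjusted_regression("stride_velocity", "tmt_a", coh)

    def test_rank_deficiency_reported(self):
        coh = vg.generate_cohort(50, seed=0)
        coh["height"] = coh["weight"]  # perfectly collinear
        with pytest.raises(ValueError, match="rank"):
            adjusted_regression("stride_velocity", "tmt_a", coh)


class TestMixedModel:
    def test_balanced_zero_variance_matches_ols(self):
        # deterministic cell means + iid noise, no subject effect
        rng = np.random.default_rng(5)
        rows = []
        cell = {("no_wall", "immediate"): 1.0, ("no_wall", "delayed"): 1.1,
                ("wall", "immediate"): 0.8, ("wall", "delayed"): 0.9}
        for i in range(30):
            for (c, v), mu in cell.items():
                rows.append(
                    {"subject_id": f"S{i}", "condition": c, "visit": v,
                     "y": mu + rng.normal(0, 0.05)}
                )
        long = pd.DataFrame(rows)
        r = condition_visit_mixed_model("y", long)
        # OLS oracle on the same design
        X = np.column_stack(
            [
                np.ones(len(long)),
                (long["condition"] == "wall").astype(float),
                (long["visit"] == "delayed").astype(float),
                ((long["condition"] == "wall") & (long["visit"] == "delayed")).astype(float),
            ]
        )
        beta = ols_oracle(long["y"].to_numpy(), X)
        assert r.fixed_effects["condition"] == pytest.approx(beta[1], abs=1e-6)
        assert r.fixed_effects["visit"] == pytest.approx(beta[2], abs=1e-6)
        assert r.fixed_effects["condition:visit"] == pytest.approx(beta[3], abs=1e-6)

    def test_bonferroni_is_exactly_four_times_raw(self):
        study = vg.simulate_study(25, seed=6, mode="summary",
                                  interaction_effects={"mos_ml": -0.02})
        r = condition_visit_mixed_model("mos_ml", study.long, always_pairwise=True)
        assert r.pairwise
        for c in r.pairwise:
            assert c.pvalue_bonferroni == min(1.0, 4 * c.pvalue_raw)
            assert c.pvalue_bonferroni >= c.pvalue_raw

    def test_planted_interaction_pattern_detected(self):
        study = vg.simulate_study(40, seed=7, mode="summary",
                                  interaction_effects={"mos_ml": -0.02})
        r = condition_visit_mixed_model("mos_ml", study.long)
        assert r.interaction_pvalue < 0.05
        by_label = {c.label: c for c in r.pairwise}
        nw = by_label["delayed_vs_immediate_within_no_wall"]
        w = by_label["delayed_vs_immediate_within_wall"]
        assert nw.estimate < 0 and nw.pvalue_bonferroni < 0.05
        assert w.pvalue_bonferroni > 0.05

    def test_too_few_subjects_fatal(self):
        study = vg.simulate_study(4, seed=8, mode="summary")
        with pytest.raises(ValueError, match="subjects"):
            condition_visit_mixed_model("stride_length", study.long)


class TestAssociationTable:
    def test_shape_two_outcomes_by_eleven_tests(self):
        coh = vg.generate_cohort(120, seed=9)
        coefs, pvals = build_association_table(coh, ["stride_velocity", "com_ml"])
        assert coefs.shape == (2, 11)
        assert pvals.shape == (2, 11)
        assert ((pvals >= 0) & (pvals <= 1)).all().all()

    def test_condition_specific_effect_lands_in_its_stratum(self):
        eff = {("stride_velocity", "logical_memory_delayed", "wall"): -0.02}
        study = vg.simulate_study(60, seed=10, mode="summary", planted_effects=eff)
        tables = vg.association_tables_by_stratum(
            study.long, study.cohort, ["stride_velocity"],
            tests=["logical_memory_delayed"],
        )
        p_wall = tables[("wall", "immediate")][1].iloc[0, 0]
        p_nw = tables[("no_wall", "immediate")][1].iloc[0, 0]
        assert p_wall < 0.05
        assert p_wall < p_nw
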