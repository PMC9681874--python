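import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ciaspipe import (
    baseline_comparisons,
    compute_changes,
    estimate_effects,
    fit_ancova,
    regress_change,
    score_dataframe,
)
from ciaspipe.effects import categorical_test, continuous_test
from ciaspipe.errors import (
    DegenerateDesignError,
    InsufficientSampleError,
    SchemaError,
    ZeroVarianceError,
)

from .conftest import make_long_frame, make_long_row


# ---------------------------------------------------------------------------
# oracles (independent of the package's fitting path)


def build_design_oracle(df):
    """Reference coding exactly as documented: most frequent level is the
    reference, arm coded active=1."""
    cols = {"const": np.ones(len(df)), "arm": (df["arm"] == "active").to_numpy(float)}
    cols["age"] = df["age"].to_numpy(float)
    levels = {}
    for cov in ("sex", "site"):
        counts = df[cov].value_counts()
        lv = sorted(counts.index, key=lambda v: (-counts[v], v))
        levels[cov] = lv
        for level in lv[1:]:
            cols[f"{cov}[{level}]"] = (df[cov] == level).to_numpy(float)
    cols["baseline_composite"] = df["baseline_composite"].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names, levels


def normal_equations_oracle(df):
    X, names, levels = build_design_oracle(df)
    y = df["d_composite"].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    mse = float(resid @ resid) / dof
    cov = mse * np.linalg.inv(X.T @ X)
    return beta, cov, mse, dof, names, levels


def lsmean_grid_oracle(df, arm):
    """Explicit enumeration of all sex x site cells, equal weights,
    continuous covariates at overall means."""
    beta, cov, mse, dof, names, levels = normal_equations_oracle(df)
    idx = {n: i for i, n in enumerate(names)}
    cells = []
    for sex in levels["sex"]:
        for site in levels["site"]:
            c = np.zeros(len(names))
            c[idx["const"]] = 1.0
            c[idx["arm"]] = 1.0 if arm == "active" else 0.0
            c[idx["age"]] = df["age"].mean()
            c[idx["baseline_composite"]] = df["baseline_composite"].mean()
            if f"sex[{sex}]" in idx:
                c[idx[f"sex[{sex}]"]] = 1.0
            if f"site[{site}]" in idx:
                c[idx[f"site[{site}]"]] = 1.0
            cells.append(c)
    c = np.mean(cells, axis=0)
    return float(c @ beta), float(np.sqrt(c @ cov @ c))


def random_trial_frame(rng, n=40, n_sites=3):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "arm": rng.permutation(
                np.array(["active"] * (n // 2) + ["placebo"] * (n - n // 2))
            ),
            "site": rng.choice([f"S{j}" for j in range(n_sites)], n),
            "age": rng.integers(18, 61, n).astype(float),
            "sex": rng.choice(["male", "female"], n),
            "baseline_composite": rng.normal(-1, 1, n),
            "d_composite": rng.normal(0, 1, n),
        }
    )


# ---------------------------------------------------------------------------
# change scores


class TestComputeChanges:
    def make_scored(self, simple_table, base_z, wk5_z, base_panss=96, wk5_panss=80):
        rows = [
            make_long_row("P1", "baseline", z=dict.fromkeys(
                ("identification", "detection", "groton_maze", "shopping_list", "one_back"),
                base_z), panss=base_panss),
            make_long_row("P1", "week5", z=dict.fromkeys(
                ("identification", "detection", "groton_maze", "shopping_list", "one_back"),
                wk5_z), panss=wk5_panss),
        ]
        return score_dataframe(make_long_frame(rows), simple_table)

    def test_identical_visits_give_zero_changes(self, simple_table):
        wide, routed = compute_changes(self.make_scored(simple_table, 0.0, 0.0, 96, 96))
        assert wide.loc[0, "d_composite"] == 0.0
        assert wide.loc[0, "d_panss"] == 0.0
        assert routed == ()

    def test_composite_improvement_positive(self, simple_table):
        wide, _ = compute_changes(self.make_scored(simple_table, 1.2, 1.5))
        assert wide.loc[0, "d_composite"] == pytest.approx(0.3)

    def test_panss_improvement_negative(self, simple_table):
        wide, _ = compute_changes(self.make_scored(simple_table, 0, 0, 96, 80))
        assert wide.loc[0, "d_panss"] == -16.0

    def test_missing_endpoint_routed_not_dropped(self, simple_table):
        scored = self.make_scored(simple_table, 0.0, 0.0)
        scored = scored[scored["visit"] == "baseline"]
        wide, routed = compute_changes(scored)
        assert len(wide) == 0
        assert routed == ("P1",)


# ---------------------------------------------------------------------------
# ANCOVA


class TestFitAncova:
    def test_arm_only_model_equals_difference_of_means(self):
        rng = np.random.default_rng(1)
        df = random_trial_frame(rng, n=30)
        fit = fit_ancova(df, covariates=())
        raw_diff = (
            df.loc[df["arm"] == "active", "d_composite"].mean()
            - df.loc[df["arm"] == "placebo", "d_composite"].mean()
        )
        assert fit.params["arm"] == pytest.approx(raw_diff, abs=1e-12)

    def test_identical_arms_give_zero_effect(self):
        y = [0.1, 0.4, -0.2, 0.8]
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "arm": ["active"] * 4 + ["placebo"] * 4,
                "d_composite": y + y,
            }
        )
        fit = fit_ancova(df, covariates=())
        est = estimate_effects(fit)
        assert fit.params["arm"] == pytest.approx(0.0, abs=1e-12)
        assert est.contrast.t == pytest.approx(0.0, abs=1e-9)
        assert est.contrast.cohen_d == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        df = random_trial_frame(rng, n=40)
        fit = fit_ancova(df)
        beta, cov, mse, dof, names, _ = normal_equations_oracle(df)
        for name, b in zip(names, beta):
            assert fit.params[name] == pytest.approx(b, abs=1e-8)
        assert fit.mse == pytest.approx(mse, abs=1e-8)
        assert fit.df_resid == dof

    def test_single_arm_rejected(self):
        df = random_trial_frame(np.random.default_rng(2), n=20)
        df["arm"] = "active"
        with pytest.raises(InsufficientSampleError):
            fit_ancova(df)

    def test_rank_deficiency_names_columns(self):
        df = random_trial_frame(np.random.default_rng(3), n=30)
        df["baseline_composite"] = df["age"] * 2.0  # exact collinearity
        with pytest.raises(DegenerateDesignError, match="baseline_composite|age"):
            fit_ancova(df)

    def test_reduces_to_pooled_t_test_without_covariates(self):
        rng = np.random.default_rng(11)
        df = random_trial_frame(rng, n=26)
        fit = fit_ancova(df, covariates=())
        est = estimate_effects(fit)
        a = df.loc[df["arm"] == "active", "d_composite"]
        b = df.loc[df["arm"] == "placebo", "d_composite"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert est.contrast.t == pytest.approx(t, abs=1e-10)
        assert est.contrast.p == pytest.approx(p, abs=1e-10)


class TestEstimateEffects:
    def test_contrast_reduces_to_arm_coefficient(self):
        rng = np.random.default_rng(4)
        df = random_trial_frame(rng, n=40)
        fit = fit_ancova(df)
        est = estimate_effects(fit)
        assert est.contrast.estimate == pytest.approx(fit.params["arm"], abs=1e-12)
        lsd = est.arms["active"].estimate - est.arms["placebo"].estimate
        assert est.contrast.estimate == pytest.approx(lsd, abs=1e-12)

    def test_centred_single_site_balanced_case(self):
        # one site, sexes exactly balanced within design, centred covariates:
        # the active LS mean differs from placebo by exactly the arm coefficient
        rng = np.random.default_rng(5)
        n = 24
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "arm": ["active", "placebo"] * (n // 2),
                "site": "S1",
                "sex": ["male", "male", "female", "female"] * (n // 4),
                "age": rng.normal(0, 1, n),
                "baseline_composite": rng.normal(0, 1, n),
                "d_composite": rng.normal(0, 1, n),
            }
        )
        df["age"] -= df["age"].mean()
        df["baseline_composite"] -= df["baseline_composite"].mean()
        fit = fit_ancova(df)
        est = estimate_effects(fit)
        assert est.contrast.estimate == pytest.approx(fit.params["arm"], abs=1e-12)
        # and the placebo LS mean is intercept + average sex effect
        expected = fit.params["const"] + fit.params["sex[male]"] / 2 if "sex[male]" in fit.params else None
        if expected is not None:
            assert est.arms["placebo"].estimate == pytest.approx(expected, abs=1e-10)

    def test_cohen_d_is_estimate_over_root_mse(self):
        df = random_trial_frame(np.random.default_rng(6), n=40)
        fit = fit_ancova(df)
        unit_mse = dataclasses.replace(fit, mse=1.0)
        est = estimate_effects(unit_mse)
        assert est.contrast.cohen_d == pytest.approx(est.contrast.estimate, abs=1e-12)
        assert np.sign(est.contrast.cohen_d) == np.sign(est.contrast.estimate)

    def test_lsmeans_match_grid_oracle(self):
        rng = np.random.default_rng(8)
        df = random_trial_frame(rng, n=45, n_sites=4)
        fit = fit_ancova(df)
        est = estimate_effects(fit)
        for arm in ("active", "placebo"):
            mean, se = lsmean_grid_oracle(df, arm)
            assert est.arms[arm].estimate == pytest.approx(mean, abs=1e-8)
            assert est.arms[arm].se == pytest.approx(se, abs=1e-8)

    def test_ci_uses_t_quantile(self):
        df = random_trial_frame(np.random.default_rng(9), n=40)
        fit = fit_ancova(df)
        est = estimate_effects(fit)
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        c = est.contrast
        assert c.ci_lo == pytest.approx(c.estimate - tcrit * c.se, abs=1e-12)
        assert c.ci_hi == pytest.approx(c.estimate + tcrit * c.se, abs=1e-12)

    def test_observed_weighting_available(self):
        df = random_trial_frame(np.random.default_rng(10), n=40)
        fit = fit_ancova(df)
        eq = estimate_effects(fit, weighting="equal")
        ob = estimate_effects(fit, weighting="observed")
        # contrast unaffected by the weighting, per-arm means generally differ
        assert ob.contrast.estimate == pytest.approx(eq.contrast.estimate, abs=1e-12)


# ---------------------------------------------------------------------------
# baseline comparisons


class TestBaselineComparisons:
    def test_identical_groups_f_zero_p_one(self):
        stat, p = continuous_test([np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])])
        assert stat == 0.0 and p == 1.0

    def test_homogeneous_2x2(self):
        stat, p = categorical_test([[30, 30], [30, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_yates_corrected_2x2(self):
        # hand computation with continuity correction
        stat, p = categorical_test([[48, 12], [45, 20]])
        assert stat == pytest.approx(1.377, abs=2e-3)
        assert p == pytest.approx(0.2406, abs=1e-3)

    def test_larger_tables_uncorrected(self):
        table = np.array([[10, 20, 5], [12, 18, 8]])
        stat, _ = categorical_test(table)
        expected, _, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(expected)

    def test_zero_cells_retained(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 5,
                "colour": ["red"] * 5 + ["red", "red", "blue", "blue", "blue"],
                "age": range(10),
            }
        )
        comps = baseline_comparisons(df, "group", [("colour", "categorical")])
        assert comps[0].p > 0  # zero cell kept, test still defined

    def test_summaries_and_types(self):
        df = pd.DataFrame(
            {
                "arm": ["active"] * 4 + ["placebo"] * 4,
                "age": [40, 42, 44, 46, 41, 43, 45, 47],
                "sex": ["male", "male", "female", "male"] * 2,
            }
        )
        comps = baseline_comparisons(
            df, "arm", [("age", "continuous"), ("sex", "categorical")], positive_level="male"
        )
        assert comps[0].kind == "continuous"
        assert comps[0].summaries["active"] == "43.00 (2.58)"
        assert comps[1].summaries["active"] == "3 (75.0%)"

    def test_unknown_kind_rejected(self):
        df = pd.DataFrame({"arm": ["a", "b"], "x": [1, 2]})
        with pytest.raises(SchemaError):
            baseline_comparisons(df, "arm", [("x", "ordinal")])


# ---------------------------------------------------------------------------
# regression


class TestRegressChange:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = regress_change(x, 2.0 * x - 3.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_null_slope_under_independence(self):
        rng = np.random.default_rng(12)
        slopes = []
        for _ in range(100):
            res = regress_change(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
            slopes.append(res.slope)
        assert abs(np.mean(slopes)) < 3 * np.std(slopes, ddof=1) / 10

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 2, 20)
        y = 0.4 * x + rng.normal(0, 1, 20)
        res = regress_change(x, y)
        sxy = np.cov(x, y, ddof=1)
        slope = sxy[0, 1] / sxy[0, 0]
        r = sxy[0, 1] / np.sqrt(sxy[0, 0] * sxy[1, 1])
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.std_beta == pytest.approx(r, abs=1e-10)
        assert res.r2 == pytest.approx(r**2, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1 - (1 - r**2) * 19 / 18, abs=1e-10)
        assert res.adj_r2 <= res.r2

    def test_std_beta_magnitude_is_root_r2(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 50)
        y = -0.3 * x + rng.normal(0, 1, 50)
        res = regress_change(x, y)
        assert abs(res.std_beta) == pytest.approx(np.sqrt(res.r2), abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ZeroVarianceError):
            regress_change([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientSampleError):
            regress_change([1.0, 2.0], [0.0, 1.0])
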