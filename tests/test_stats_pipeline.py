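"""Cohort statistics: t-tests, two-way ANOVA + Tukey, regressions, pipeline."""

import numpy as np
import pandas as pd
import pytest

from cardiohelix import stats_pipeline as sp
from cardiohelix import synthetic_data as syn


# ------------------------------------------------------- independent oracles


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def balanced_two_way_anova_oracle(y, f1, f2):
    """Closed-form two-way ANOVA for a balanced design via cell means."""
    df = pd.DataFrame({"y": y, "a": f1, "b": f2})
    grand = df["y"].mean()
    n_per_cell = df.groupby(["a", "b"]).size().iloc[0]
    a_means = df.groupby("a")["y"].mean()
    b_means = df.groupby("b")["y"].mean()
    cell_means = df.groupby(["a", "b"])["y"].mean()
    la, lb = len(a_means), len(b_means)
    ss_a = n_per_cell * lb * ((a_means - grand) ** 2).sum()
    ss_b = n_per_cell * la * ((b_means - grand) ** 2).sum()
    ss_cells = n_per_cell * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g["y"] - g["y"].mean()) ** 2).sum() for _, g in df.groupby(["a", "b"])
    )
    df_err = len(df) - la * lb
    return {
        "a": (ss_a / (la - 1)) / (ss_err / df_err),
        "b": (ss_b / (lb - 1)) / (ss_err / df_err),
        "ab": (ss_ab / ((la - 1) * (lb - 1))) / (ss_err / df_err),
    }


def ols_oracle(x, y):
    """Closed-form simple-regression slope, intercept, r^2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    syy = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - (resid**2).sum() / syy


# ---------------------------------------------------------------- unit tests


class TestUnpairedTTest:
    def test_identical_groups(self):
        res = sp.unpaired_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation(self):
        res = sp.unpaired_ttest([1.0, 2, 3, 4], [11.0, 12, 13, 14])
        assert res.p_value < 1e-4

    def test_matches_formula_oracle(self):
        a = [4.1, 5.2, 3.9, 4.8, 5.0]
        b = [5.9, 6.3, 5.4, 6.8]
        res = sp.unpaired_ttest(a, b)
        assert res.statistic == pytest.approx(pooled_t_oracle(a, b), abs=1e-10)
        assert res.df == len(a) + len(b) - 2

    def test_degenerate_zero_variance(self):
        equal = sp.unpaired_ttest([2.0, 2.0], [2.0, 2.0])
        assert equal.p_value == 1.0 and equal.statistic == 0.0
        apart = sp.unpaired_ttest([2.0, 2.0], [3.0, 3.0])
        assert apart.p_value == 0.0 and apart.degenerate

    def test_percent_change_uses_first_group_as_reference(self):
        res = sp.unpaired_ttest([1.0, 1.0, 1.0], [1.2, 1.2, 1.2])
        assert res.percent_change == pytest.approx(20.0)

    def test_welch_differs_under_heteroscedasticity(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [2.0, 4.0, 0.5, 3.5, 1.0]
        student = sp.unpaired_ttest(a, b, welch=False)
        welch = sp.unpaired_ttest(a, b, welch=True)
        assert student.p_value != welch.p_value


class TestTwoWayAnova:
    @staticmethod
    def _balanced_table(seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for act in ("sedentary", "exercise"):
            for gen in ("flfl", "C4KO"):
                mu = 100.0
                if act == "exercise" and gen == "flfl":
                    mu *= 1 + effect
                if gen == "C4KO":
                    mu *= 0.7
                for _ in range(5):
                    rows.append(
                        {"activity": act, "genotype": gen, "y": mu + rng.normal(0, 5)}
                    )
        return pd.DataFrame(rows)

    def test_constant_response_gives_null_result(self):
        t = self._balanced_table()
        t["y"] = 42.0
        res = sp.two_way_anova_tukey(t, "y")
        for term in res["anova"].values():
            assert term["F"] == 0.0 and term["p"] == 1.0
        assert all(not r["reject"] for r in res["tukey"])

    def test_matches_balanced_closed_form_oracle(self):
        t = self._balanced_table(seed=3, effect=0.2)
        res = sp.two_way_anova_tukey(t, "y")
        oracle = balanced_two_way_anova_oracle(
            t["y"].to_numpy(), t["activity"].to_numpy(), t["genotype"].to_numpy()
        )
        assert res["anova"]["activity"]["F"] == pytest.approx(oracle["a"], abs=1e-8)
        assert res["anova"]["genotype"]["F"] == pytest.approx(oracle["b"], abs=1e-8)
        assert res["anova"]["activity x genotype"]["F"] == pytest.approx(
            oracle["ab"], abs=1e-8
        )

    def test_detects_generated_genotype_effect_and_interaction(self):
        """Exercise effect present only in flfl: genotype main effect and
        activity x genotype interaction both detected."""
        spec = syn.CohortSpec(
            n_per_group=8,
            groups=(
                ("sedentary", "flfl"),
                ("exercise", "flfl"),
                ("sedentary", "C4KO"),
                ("exercise", "C4KO"),
            ),
            between_animal_cv=0.05,
            seed=5,
        )
        t = syn.cohort_truths(spec)
        res = sp.two_way_anova_tukey(
            t.rename(columns={"helicity_total": "y"}), "y"
        )
        assert res["anova"]["genotype"]["p"] < 0.01
        assert res["anova"]["activity x genotype"]["p"] < 0.05

    def test_empty_cell_rejected_with_name(self):
        t = self._balanced_table()
        t = t[~((t.activity == "exercise") & (t.genotype == "C4KO"))]
        with pytest.raises(ValueError, match="C4KO"):
            sp.two_way_anova_tukey(t, "y")


class TestRegression:
    def test_exact_line(self):
        table = pd.DataFrame(
            {"cited4_total": [1.0, 2, 3, 4], "helicity_total": [2.0, 4, 6, 8]}
        )
        res = sp.regress_cited4_helicity(table, "total")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        table = pd.DataFrame(
            {"cited4_total": [2.0, 2, 2, 2], "helicity_total": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="variance"):
            sp.regress_cited4_helicity(table, "total")

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 4, 20)
        y = 30 * x + rng.normal(0, 5, 20)
        table = pd.DataFrame({"cited4_septal": x, "helicity_septal": y})
        res = sp.regress_cited4_helicity(table, "septal")
        slope, intercept, r2 = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-8)
        assert res.intercept == pytest.approx(intercept, abs=1e-8)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_slope_ci_coverage_on_linear_data(self):
        """95% CI covers the true slope in >= 90% of 100 replicates."""
        import scipy.stats

        rng = np.random.default_rng(17)
        beta, hits, reps = 25.0, 0, 100
        for _ in range(reps):
            x = rng.uniform(1.0, 4.0, 14)
            y = beta * x + rng.normal(0, 8.0, 14)
            table = pd.DataFrame({"cited4_total": x, "helicity_total": y})
            res = sp.regress_cited4_helicity(table, "total")
            # standard error from the residuals (closed form)
            resid = y - res.slope * x - res.intercept
            se = np.sqrt(
                (resid**2).sum() / (len(x) - 2) / ((x - x.mean()) ** 2).sum()
            )
            tcrit = scipy.stats.t.ppf(0.975, len(x) - 2)
            if abs(res.slope - beta) <= tcrit * se:
                hits += 1
        assert hits >= 90


class TestPercentChange:
    def test_convention_matches_reported_uplift(self):
        assert sp.percent_change(1.0, 1.199) == pytest.approx(19.9)

    def test_equal_means(self):
        assert sp.percent_change(5.0, 5.0) == 0.0

    def test_decrease(self):
        assert sp.percent_change(2.0, 1.0) == -50.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            sp.percent_change(0.0, 1.0)


class TestCalibration:
    def test_type_i_error_near_nominal(self):
        """Null cohorts (no effect): the t-test rejects ~5% of the time."""
        null = dict(
            helicity_effect=0.0,
            cited4_effect=0.0,
            wall_thickness_effect=0.0,
            lv_mass_effect=0.0,
            between_animal_cv=0.15,
        )
        rejections = 0
        reps = 400
        for i in range(reps):
            t = syn.cohort_truths(syn.CohortSpec(n_per_group=7, seed=i, **null))
            a = t[t.activity == "sedentary"]["helicity_total"]
            b = t[t.activity == "exercise"]["helicity_total"]
            if sp.unpaired_ttest(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_monotone_in_effect_size(self):
        rates = []
        for eff in (0.0, 0.2, 0.4):
            rej = 0
            for i in range(150):
                t = syn.cohort_truths(
                    syn.CohortSpec(
                        n_per_group=7,
                        helicity_effect=eff,
                        between_animal_cv=0.15,
                        seed=1000 + i,
                    )
                )
                a = t[t.activity == "sedentary"]["helicity_total"]
                b = t[t.activity == "exercise"]["helicity_total"]
                if sp.unpaired_ttest(a, b).p_value < 0.05:
                    rej += 1
            rates.append(rej / 150)
        assert rates[0] < rates[1] < rates[2]


class TestRunPipeline:
    def test_small_cohort_pipeline_deterministic(self, tmp_path):
        cfg = {
            "cohort": {"n_per_group": 3},
            "fish": {"n_nuclei_per_roi": 8},
        }
        b1 = sp.run_pipeline(cfg, seed=9, out_dir=tmp_path / "a")
        b2 = sp.run_pipeline(cfg, seed=9, out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(b1.cohort_table, b2.cohort_table)
        assert (tmp_path / "a" / "cohort_table.csv").exists()
        assert (tmp_path / "a" / "stats.json").exists()
        assert (tmp_path / "a" / "report.md").exists()
        assert (tmp_path / "a" / "regression_total.svg").exists()
        # recovered group separation has the generated direction
        gc = b1.stats["group_comparisons"]
        assert gc["helicity_total"]["percent_change"] > 0

    def test_underpowered_cohort_warns(self):
        with pytest.warns(UserWarning, match="underpowered"):
            sp.run_pipeline(
                {"cohort": {"n_per_group": 2}, "fish": {"n_nuclei_per_roi": 6}},
                seed=4,
            )

    def test_knockout_pattern_recovered(self):
        cfg = {
            "cohort": {
                "n_per_group": 3,
                "groups": [
                    ["sedentary", "flfl"],
                    ["exercise", "flfl"],
                    ["sedentary", "C4KO"],
                    ["exercise", "C4KO"],
                ],
            },
            "fish": {"n_nuclei_per_roi": 8},
        }
        bundle = sp.run_pipeline(cfg, seed=21)
        t = bundle.cohort_table
        ko = t[t.genotype == "C4KO"]
        ctrl = t[t.genotype == "flfl"]
        assert ko["cited4_total"].max() <= 0.05
        assert ctrl["cited4_total"].min() > 0.5
        assert (
            ko["helicity_total_abs"].mean() < ctrl["helicity_total_abs"].mean()
        )
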