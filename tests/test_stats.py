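import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicyto import (
    anova_with_bonferroni,
    compare_groups,
    generate_section,
    preset_params,
    regress_activity_vs_damage,
    run_pipeline,
    violin_summary,
)
from epicyto.stats import stars_for


def t_oracle(a, b):
    """Textbook equal-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
           / (na + nb - 2))
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def _table(a, b, labels=("a", "b")):
    return pd.DataFrame({
        "g": [labels[0]] * len(a) + [labels[1]] * len(b),
        "activity_od": np.concatenate([a, b]),
    })


class TestCompareGroups:
    def test_identical_groups(self):
        a = np.full(5, 3.0)
        res = compare_groups(_table(a, a), "g")
        assert res.t == 0.0 and res.p == 1.0
        assert res.stars == "ns"

    def test_matches_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        res = compare_groups(_table(a, b), "g")
        assert res.t == pytest.approx(t_oracle(a, b), rel=1e-10)
        assert res.p < 1e-10
        assert res.stars == "****"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equality_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 2, rng.integers(3, 40))
        b = rng.normal(0.5, 2, rng.integers(3, 40))
        res = compare_groups(_table(a, b), "g")
        assert res.t == pytest.approx(t_oracle(a, b), rel=1e-9)

    def test_zero_variance_unequal_means_error(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups(_table(np.full(3, 1.0), np.full(3, 2.0)), "g")

    def test_aggregate_by_section(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "g": np.repeat(["a", "b"], 100),
            "section": np.tile(np.repeat([0, 1, 2, 3], 25), 2),
            "activity_od": rng.normal(0, 1, 200),
        })
        res = compare_groups(tab, "g", aggregate_by="section")
        assert res.n == (4, 4)

    def test_star_thresholds(self):
        assert stars_for(0.2) == "ns"
        assert stars_for(0.04) == "*"
        assert stars_for(0.004) == "**"
        assert stars_for(4e-4) == "***"
        assert stars_for(4e-5) == "****"


class TestAnova:
    @staticmethod
    def _metformin_tables(width=1200):
        tabs = []
        for cond, preset, seed in [("control", "homeostatic", 31),
                                   ("metformin", "metformin", 32)]:
            image, _ = generate_section(preset_params(preset, seed=seed,
                                                      width_px=width))
            tabs.append(run_pipeline(image).table.assign(condition=cond))
        df = pd.concat(tabs, ignore_index=True)
        return df[df["stratum"] != "corneal"]

    def test_treatment_effect_detected_per_stratum(self):
        df = self._metformin_tables()
        res = anova_with_bonferroni(df)
        assert res.anova_table.loc["condition", "PR(>F)"] < 1e-6
        assert res.contrasts["significant"].all()
        assert res.n_contrasts == 3

    def test_bonferroni_is_definitional(self):
        df = self._metformin_tables(width=600)
        res = anova_with_bonferroni(df)
        np.testing.assert_allclose(
            res.contrasts["p_adj"],
            np.minimum(1.0, res.n_contrasts * res.contrasts["p_raw"]))

    def test_null_type_one_error_controlled(self):
        """With all groups from one distribution, Bonferroni contrasts stay
        silent in at least 95 % of replicates."""
        n_sig = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "condition": np.repeat(["a", "b"], 30),
                "stratum": np.tile(np.repeat(["s1", "s2", "s3"], 10), 2),
                "activity_od": rng.normal(50, 5, 60),
            })
            res = anova_with_bonferroni(df)
            if res.contrasts["significant"].any():
                n_sig += 1
        # family-wise rate ~5 %; allow 2.5 binomial sd of sampling slack
        assert n_sig <= 0.05 * reps + 2.5 * np.sqrt(reps * 0.05 * 0.95)

    def test_empty_cell_named_in_error(self):
        df = pd.DataFrame({
            "condition": ["a", "a", "b", "b"],
            "stratum": ["s1", "s2", "s1", "s1"],
            "activity_od": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="stratum='s2'"):
            anova_with_bonferroni(df)


class TestRegression:
    def test_perfect_line(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 10,
                            "gh2ax_nuc_mean": np.arange(10.0),
                            "activity_od": np.arange(10.0)})
        res = regress_activity_vs_damage(tab)
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 5,
                            "gh2ax_nuc_mean": np.ones(5),
                            "activity_od": np.arange(5.0)})
        with pytest.raises(ValueError, match="constant"):
            regress_activity_vs_damage(tab)

    def test_null_coupling_ci_covers_zero(self):
        """Without coupling the slope CI contains 0 in >= 90 % of runs."""
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 120
            tab = pd.DataFrame({
                "stratum": ["basal"] * n,
                "gh2ax_nuc_mean": rng.normal(300, 150, n),
                "activity_od": rng.normal(60, 8, n),
            })
            res = regress_activity_vs_damage(tab)
            lo = res.slope - 1.96 * res.stderr
            hi = res.slope + 1.96 * res.stderr
            hits += lo <= 0 <= hi
        assert hits >= 0.90 * reps

    def test_band_symmetric_about_fit(self):
        rng = np.random.default_rng(5)
        tab = pd.DataFrame({"stratum": ["basal"] * 60,
                            "gh2ax_nuc_mean": rng.normal(100, 30, 60),
                            "activity_od": rng.normal(50, 10, 60)})
        res = regress_activity_vs_damage(tab)
        mid = res.intercept + res.slope * res.x_grid
        np.testing.assert_allclose(mid - res.ci_lower, res.ci_upper - mid,
                                   rtol=1e-8)


class TestViolinSummary:
    def test_single_value_group_degenerate(self):
        tab = pd.DataFrame({"stratum": ["basal"], "activity_od": [42.0]})
        summary, traces = violin_summary(tab)
        assert summary.loc[0, "mean"] == 42.0
        assert summary.loc[0, "median"] == 42.0
        grid, dens = traces["basal"]
        assert grid.tolist() == [42.0]

    def test_row_order_invariance(self, default_result):
        tab = default_result.table
        shuffled = tab.sample(frac=1.0, random_state=3)
        s1, _ = violin_summary(tab)
        s2, _ = violin_summary(shuffled)
        pd.testing.assert_frame_equal(s1, s2)

    def test_mean_is_headline_column(self, default_result):
        summary, _ = violin_summary(default_result.table)
        assert list(summary.columns)[:2] == ["stratum", "mean"]
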