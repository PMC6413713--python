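"""Power analysis, summary t-tests, normality, ANOVA and Tukey comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroperf.stats import (
    AnovaResult,
    PowerSpec,
    min_n_per_group,
    oneway_anova,
    oneway_anova_power,
    shapiro_wilk,
    ttest_unpaired_from_summary,
    tukey_hsd,
    two_way_anova,
)

STUDY_DESIGN = PowerSpec(k_groups=4, effect_f=0.72, alpha=0.05, target_power=0.8)


class TestPower:
    def test_large_n_limit(self):
        assert oneway_anova_power(STUDY_DESIGN, 10_000) == pytest.approx(1.0, abs=1e-6)

    def test_study_design_reaches_target_at_seven(self):
        assert oneway_anova_power(STUDY_DESIGN, 7) >= 0.8

    def test_monte_carlo_agreement(self):
        """Exact noncentral-F power vs. simulation of the raw F test."""
        k, f, n, reps = 3, 0.5, 15, 100_000
        rng = np.random.default_rng(0)
        # group means with population SD (divisor k) equal to f * sigma
        c = f * np.sqrt(k / 2.0)
        mus = np.array([-c, 0.0, c])
        data = rng.normal(mus[None, :, None], 1.0, size=(reps, k, n))
        gmean = data.mean(axis=2)
        grand = gmean.mean(axis=1, keepdims=True)
        ssb = n * ((gmean - grand) ** 2).sum(axis=1)
        ssw = ((data - gmean[:, :, None]) ** 2).sum(axis=(1, 2))
        fstat = (ssb / (k - 1)) / (ssw / (k * (n - 1)))
        crit = sps.f.ppf(0.95, k - 1, k * (n - 1))
        sim_power = (fstat > crit).mean()
        exact = oneway_anova_power(PowerSpec(k, f, 0.05, 0.8), n)
        assert abs(sim_power - exact) < 0.01

    def test_strictly_increasing_in_n_f_alpha(self):
        ns = [3, 5, 8, 13, 21]
        powers = [oneway_anova_power(STUDY_DESIGN, n) for n in ns]
        assert np.all(np.diff(powers) > 0)
        fs = [0.2, 0.4, 0.6, 0.9]
        powers = [
            oneway_anova_power(PowerSpec(4, f, 0.05, 0.8), 7) for f in fs
        ]
        assert np.all(np.diff(powers) > 0)
        alphas = [0.01, 0.05, 0.1, 0.2]
        powers = [
            oneway_anova_power(PowerSpec(4, 0.72, a, 0.8), 7) for a in alphas
        ]
        assert np.all(np.diff(powers) > 0)


class TestMinN:
    def test_definitional_minimality(self):
        n, power = min_n_per_group(STUDY_DESIGN)
        assert power >= 0.8
        assert oneway_anova_power(STUDY_DESIGN, n - 1) < 0.8

    def test_large_effect_needs_few_subjects(self):
        spec = PowerSpec(4, 2.0, 0.05, 0.8)
        n, _ = min_n_per_group(spec)
        assert oneway_anova_power(spec, n) >= 0.8
        assert n <= 4

    def test_doubling_effect_never_increases_n(self):
        for f in (0.3, 0.5, 0.72, 1.0):
            n1, _ = min_n_per_group(PowerSpec(4, f, 0.05, 0.8))
            n2, _ = min_n_per_group(PowerSpec(4, 2 * f, 0.05, 0.8))
            assert n2 <= n1


class TestSummaryTTest:
    def test_plasma_biomarker_worked_example(self):
        t, df, p = ttest_unpaired_from_summary(33.2, 10.5, 6, 20.3, 7.43, 6)
        assert t == pytest.approx(2.456, abs=1e-3)
        assert df == 10
        assert p == pytest.approx(0.0338, abs=1e-4)

    def test_identical_groups(self):
        t, _, p = ttest_unpaired_from_summary(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_agreement_with_raw_data_test(self):
        """Construct samples with exactly the given summaries and compare."""
        rng = np.random.default_rng(4)

        def sample(m, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return m + sd * z

        x, y = sample(33.2, 10.5, 6), sample(20.3, 7.43, 6)
        t_raw, p_raw = sps.ttest_ind(x, y, equal_var=True)
        t_sum, _, p_sum = ttest_unpaired_from_summary(33.2, 10.5, 6, 20.3, 7.43, 6)
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_welch_variant_df(self):
        _, df, _ = ttest_unpaired_from_summary(
            10.0, 1.0, 10, 10.0, 5.0, 5, variant="welch"
        )
        assert df < 13  # Welch df shrinks under variance imbalance

    def test_degenerate_equal_groups_warn(self):
        with pytest.warns(UserWarning, match="convention"):
            t, _, p = ttest_unpaired_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert p == 1.0


class TestShapiroWilk:
    def test_uniform_grid_passes(self):
        w, p = shapiro_wilk(np.linspace(0.0, 1.0, 50))
        assert w > 0.9 and p > 0.05

    def test_bimodal_fails(self):
        _, p = shapiro_wilk(np.array([0.0] * 10 + [100.0] * 10))
        assert p < 0.001

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk(np.array([1.0, 2.0]))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.ones(10))


def _lsd_p(table: pd.DataFrame, g1: str, g2: str) -> float:
    """Unadjusted pairwise t-test p on the ANOVA's pooled error term."""
    g = table.groupby("group")["value"]
    means, ns = g.mean(), g.count()
    df_err = int(ns.sum() - len(means))
    sse = float(((table["value"] - table["group"].map(means)) ** 2).sum())
    mse = sse / df_err
    t = abs(means[g1] - means[g2]) / np.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
    return 2.0 * float(sps.t.sf(t, df_err))


def _cell_table(cells: dict[tuple[str, str], list[float]]) -> pd.DataFrame:
    rows = []
    for (g, t), values in cells.items():
        for v in values:
            rows.append({"genotype": g, "treatment": t, "value": v,
                         "group": f"{g}_{t}"})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_pure_additive_design_has_zero_interaction(self):
        cells = {
            ("a", "x"): [10.0, 10.5], ("a", "y"): [12.0, 12.5],
            ("b", "x"): [20.0, 20.5], ("b", "y"): [22.0, 22.5],
        }
        res = two_way_anova(_cell_table(cells))
        assert res.f("genotype:treatment") == pytest.approx(0.0, abs=1e-20)

    def test_balanced_hand_decomposition(self):
        """Integer 2x2 with 2 reps per cell against a manual SS partition."""
        cells = {
            ("a", "x"): [1.0, 3.0], ("a", "y"): [4.0, 6.0],
            ("b", "x"): [5.0, 7.0], ("b", "y"): [2.0, 8.0],
        }
        table = _cell_table(cells)
        res = two_way_anova(table)
        y = table["value"].to_numpy()
        grand = y.mean()
        means = {k: np.mean(v) for k, v in cells.items()}
        ma = {g: np.mean([means[(g, t)] for t in "xy"]) for g in "ab"}
        mt = {t: np.mean([means[(g, t)] for g in "ab"]) for t in "xy"}
        ss_a = 4 * sum((ma[g] - grand) ** 2 for g in "ab")
        ss_b = 4 * sum((mt[t] - grand) ** 2 for t in "xy")
        ss_ab = 2 * sum(
            (means[(g, t)] - ma[g] - mt[t] + grand) ** 2
            for g in "ab" for t in "xy"
        )
        ss_err = sum(
            (v - means[k]) ** 2 for k, vals in cells.items() for v in vals
        )
        mse = ss_err / 4
        assert res.f("genotype") == pytest.approx(ss_a / mse, rel=1e-10)
        assert res.f("treatment") == pytest.approx(ss_b / mse, rel=1e-10)
        assert res.f("genotype:treatment") == pytest.approx(ss_ab / mse, rel=1e-10)

    def test_empty_cell_rejected(self):
        cells = {
            ("a", "x"): [1.0, 2.0], ("a", "y"): [3.0, 4.0],
            ("b", "x"): [5.0, 6.0],
        }
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(_cell_table(cells))

    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 12)
        table = pd.DataFrame(
            {"group": ["g1"] * 9 + ["g2"] * 12, "value": np.r_[x, y]}
        )
        res = oneway_anova(table, "value", "group")
        t, _ = sps.ttest_ind(x, y, equal_var=True)
        assert res.f("group") == pytest.approx(t**2, rel=1e-10)


class TestTukey:
    def _random_table(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, n in enumerate((8, 9, 9, 11)):
            for v in rng.normal(shift * i, 1.0, n):
                rows.append({"group": f"g{i}", "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups_have_p_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        rows = [
            {"group": g, "value": v} for g in ("g1", "g2", "g3") for v in base
        ]
        tk = tukey_hsd(pd.DataFrame(rows))
        assert np.allclose(tk["p_adj"], 1.0)
        assert (tk["mean_diff"] == 0.0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjusted_p_at_least_pairwise_t(self, seed):
        """Studentized-range adjustment dominates the unadjusted pairwise
        comparison on the same pooled error (Fisher LSD)."""
        table = self._random_table(seed, shift=0.4)
        tk = tukey_hsd(table)
        for _, row in tk.iterrows():
            p_t = _lsd_p(table, row["group1"], row["group2"])
            assert row["p_adj"] >= p_t - 1e-12

    @pytest.mark.parametrize("seed", [3, 4])
    def test_agreement_with_statsmodels(self, seed):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        table = self._random_table(seed, shift=0.5)
        tk = tukey_hsd(table)  # pairs in sorted-group order, same as ref
        ref = pairwise_tukeyhsd(table["value"], table["group"])
        np.testing.assert_allclose(tk["mean_diff"], ref.meandiffs, rtol=1e-10)
        np.testing.assert_allclose(tk["p_adj"], ref.pvalues, atol=1e-8)
        np.testing.assert_allclose(tk[["ci_low", "ci_high"]], ref.confint, rtol=1e-8)

    def test_single_group_rejected(self):
        table = pd.DataFrame({"group": ["g"] * 5, "value": np.arange(5.0)})
        with pytest.raises(ValueError, match=">= 2 groups"):
            tukey_hsd(table)
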