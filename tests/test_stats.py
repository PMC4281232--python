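"""Statistical stages: age classes, jackknifed DFA, Spearman, Box-Cox, GLM."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from carapace_pheno.diversity import PHENOTYPE_METRICS
from carapace_pheno.stats import (
    assign_age,
    boxcox,
    compare_age_criteria,
    glm_stepwise,
    lda_loocv,
    spearman_vs_size,
)


def metric_frame(x, labels, rng=None):
    df = pd.DataFrame(x, columns=list(PHENOTYPE_METRICS))
    df["group"] = labels
    return df


class TestAssignAge:
    @pytest.mark.parametrize(
        "sex, width, criterion, expected",
        [
            ("f", 30.0, "maturity", "mature"),
            ("f", 27.0, "maturity", "immature"),
            ("m", 22.0, "maturity", "mature"),
            ("m", 21.0, "maturity", "immature"),
            ("f", 24.0, "width25", "juvenile"),
            ("m", 25.0, "width25", "adult"),
            ("f", 40.0, "width25", "adult"),
        ],
    )
    def test_rules(self, sex, width, criterion, expected):
        df = pd.DataFrame({"sex": [sex], "carapace_width_mm": [width]})
        assert assign_age(df, criterion)["stage"].iloc[0] == expected

    def test_missing_width_dropped_with_warning(self):
        df = pd.DataFrame({"sex": ["f", "m"], "carapace_width_mm": [30.0, np.nan]})
        with pytest.warns(UserWarning, match="missing"):
            out = assign_age(df, "width25")
        assert len(out) == 1

    def test_unknown_criterion_rejected(self):
        df = pd.DataFrame({"sex": ["f"], "carapace_width_mm": [30.0]})
        with pytest.raises(ValueError, match="criterion"):
            assign_age(df, "nonsense")


class TestLdaLoocv:
    def test_wide_separation_classified_perfectly(self, rng):
        a = rng.normal(0, 1, (100, 6))
        b = rng.normal(0, 1, (100, 6))
        b[:, 2] += 10.0  # 10 pooled SD apart
        df = metric_frame(np.vstack([a, b]), ["a"] * 100 + ["b"] * 100)
        res = lda_loocv(df, PHENOTYPE_METRICS, "group")
        assert res.overall_correct >= 0.99
        assert res.confusion.to_numpy().sum() == 200
        # columns sum to the true group sizes
        assert res.confusion.sum(axis=0).tolist() == [100, 100]

    def test_permuted_labels_no_better_than_chance(self, rng):
        x = rng.normal(0, 1, (200, 6))
        labels = rng.permutation(["a"] * 100 + ["b"] * 100)
        res = lda_loocv(metric_frame(x, labels), PHENOTYPE_METRICS, "group")
        upper = 0.5 + 2.58 * np.sqrt(0.25 / 200)
        assert res.overall_correct <= upper  # at or below chance, never above

    def test_deterministic_on_duplicated_dataset(self, rng):
        x = rng.normal(0, 1, (40, 6))
        x[:20, 0] += 2
        df = metric_frame(x, ["a"] * 20 + ["b"] * 20)
        r1 = lda_loocv(df, PHENOTYPE_METRICS, "group")
        r2 = lda_loocv(df.copy(), PHENOTYPE_METRICS, "group")
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_held_out_point_never_used_in_fit(self, rng):
        # moving one 'a' crab onto the 'b' centroid (plus an outlying
        # excursion orthogonal to the separation) flips only its own
        # prediction: its discriminant was fitted without it, and every
        # other fold's boundary is essentially unchanged
        a = rng.normal(0, 1.0, (20, 6))
        b = rng.normal(0, 1.0, (20, 6))
        b[:, 0] += 10.0
        df = metric_frame(np.vstack([a, b]), ["a"] * 20 + ["b"] * 20)
        base = lda_loocv(df, PHENOTYPE_METRICS, "group")
        assert base.overall_correct == 1.0
        spiked = df.copy()
        cols = list(PHENOTYPE_METRICS)
        spiked.loc[0, cols] = 0.0
        spiked.loc[0, cols[0]] = 10.0  # sits on the b centroid
        spiked.loc[0, cols[3]] = 25.0  # far away, orthogonal to separation
        res = lda_loocv(spiked, PHENOTYPE_METRICS, "group")
        assert res.confusion.loc["b", "a"] == 1  # only the moved crab flips
        assert res.confusion.loc["a", "a"] == 19
        assert res.confusion.loc["b", "b"] == 20

    def test_collinear_features_rejected(self, rng):
        x = rng.normal(0, 1, (30, 6))
        x[:, 5] = x[:, 4]  # exact collinearity
        df = metric_frame(x, ["a"] * 15 + ["b"] * 15)
        with pytest.raises(ValueError, match="collinear"):
            lda_loocv(df, PHENOTYPE_METRICS, "group")

    def test_single_group_rejected(self, rng):
        df = metric_frame(rng.normal(0, 1, (10, 6)), ["a"] * 10)
        with pytest.raises(ValueError, match="2 groups"):
            lda_loocv(df, PHENOTYPE_METRICS, "group")


class TestCompareAgeCriteria:
    def test_selects_better_separating_criterion(self, rng):
        # metrics depend on the 25 mm boundary, not on sex-specific maturity
        n = 200
        width = rng.uniform(5, 50, n)
        stage_signal = (width >= 25).astype(float)
        x = rng.normal(0, 1, (n, 6)) + 3.0 * stage_signal[:, None]
        df = pd.DataFrame(x, columns=list(PHENOTYPE_METRICS))
        df["carapace_width_mm"] = width
        df["sex"] = rng.choice(["f", "m"], n)
        best, results = compare_age_criteria(df, PHENOTYPE_METRICS)
        assert best == "width25"
        assert results["width25"].overall_correct > results["maturity"].overall_correct


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        df = pd.DataFrame(
            {"carapace_width_mm": [5, 10, 20, 30, 44], "m": [1, 4, 9, 16, 25]}
        )
        res = spearman_vs_size(df, "m")
        assert res.rho == pytest.approx(1.0)
        assert res.df == 3

    def test_monotone_decreasing_is_minus_one(self):
        df = pd.DataFrame({"carapace_width_mm": [5, 10, 20, 30], "m": [8, 7, 3, 1]})
        assert spearman_vs_size(df, "m").rho == pytest.approx(-1.0)

    def test_tied_table_matches_rank_oracle(self):
        # brute-force: Pearson correlation of midranks
        width = np.array([5.0, 5.0, 10.0, 12.0, 12.0, 20.0])
        metric = np.array([3.0, 1.0, 1.0, 4.0, 2.0, 5.0])
        rw = scipy.stats.rankdata(width)
        rm = scipy.stats.rankdata(metric)
        expected = np.corrcoef(rw, rm)[0, 1]
        df = pd.DataFrame({"carapace_width_mm": width, "m": metric})
        res = spearman_vs_size(df, "m")
        assert res.rho == pytest.approx(expected, rel=1e-12)
        assert res.t == pytest.approx(
            expected * np.sqrt(4 / (1 - expected**2)), rel=1e-12
        )

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        width = rng.uniform(5, 50, 20)
        metric = rng.normal(0, 1, 20)
        df = pd.DataFrame({"carapace_width_mm": width, "m": metric})
        base = spearman_vs_size(df, "m").rho
        df2 = pd.DataFrame(
            {"carapace_width_mm": np.exp(width / 10), "m": metric**3}
        )
        assert spearman_vs_size(df2, "m").rho == pytest.approx(base, rel=1e-9)

    def test_constant_metric_rejected(self):
        df = pd.DataFrame({"carapace_width_mm": [5.0, 10.0, 20.0], "m": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            spearman_vs_size(df, "m")

    def test_exact_permutation_small_n(self):
        df = pd.DataFrame({"carapace_width_mm": [5, 9, 14, 22, 30.0], "m": [1, 2, 3, 5, 4.0]})
        res = spearman_vs_size(df, "m", method="exact")
        assert 0 < res.p <= 1


class TestBoxCox:
    def test_lambda_one_shifts(self):
        v = np.array([1.0, 2.0, 5.0])
        out, lam = boxcox(v, power=1.0)
        np.testing.assert_allclose(out, v - 1.0)

    def test_lambda_zero_is_log(self):
        v = np.array([1.0, np.e, np.e**2])
        out, _ = boxcox(v, power=0.0)
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0])

    def test_negative_power_preserves_information(self):
        v = np.array([1.0, 2.0, 4.0])
        out, _ = boxcox(v, power=-1.124)
        assert np.all(np.diff(out) > 0)  # (v^l - 1)/l is increasing even for l<0

    def test_mle_recovers_log_for_lognormal(self, rng):
        v = np.exp(rng.normal(0, 1, 1000))
        _, lam = boxcox(v)
        assert abs(lam) < 0.1

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox(np.array([1.0, 0.0, 2.0]), power=0.5)


def balanced_two_way(rng, effect_a=0.0, effect_b=0.0, n_cell=10):
    rows = []
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            y = rng.normal(0, 1, n_cell)
            y += effect_a * (a == "a2") + effect_b * (b == "b2")
            for v in y:
                rows.append({"site": a, "stage": b, "zone": "low", "y": v})
    return pd.DataFrame(rows)


class TestGlmStepwise:
    def test_alpha_one_retains_all_interactions(self, rng):
        df = balanced_two_way(rng)
        res = glm_stepwise(
            df, "y", factors=("site", "stage"), interactions=(("site", "stage"),),
            alpha=1.0,
        )
        assert "C(site):C(stage)" in res.retained_terms
        assert res.removal_trace == []

    def test_alpha_zero_removes_all_interactions(self, rng):
        df = balanced_two_way(rng, effect_a=5.0)
        res = glm_stepwise(
            df, "y", factors=("site", "stage"), interactions=(("site", "stage"),),
            alpha=0.0,
        )
        assert "C(site):C(stage)" not in res.retained_terms
        assert len(res.removal_trace) == 1

    def test_balanced_anova_matches_closed_form(self, rng):
        # hand-computed two-way ANOVA on a balanced 2x2 table
        df = balanced_two_way(rng, effect_a=1.0, effect_b=0.5, n_cell=12)
        res = glm_stepwise(
            df, "y", factors=("site", "stage"), interactions=(("site", "stage"),),
            alpha=1.0,
        )
        y = df["y"].to_numpy()
        a = (df["site"] == "a2").to_numpy()
        b = (df["stage"] == "b2").to_numpy()
        n = len(y)
        grand = y.mean()
        ss_a = sum(
            (y[a == lvl].mean() - grand) ** 2 * (a == lvl).sum() for lvl in (0, 1)
        )
        ss_b = sum(
            (y[b == lvl].mean() - grand) ** 2 * (b == lvl).sum() for lvl in (0, 1)
        )
        cell_means = {
            (i, j): y[(a == i) & (b == j)].mean() for i in (0, 1) for j in (0, 1)
        }
        ss_cells = sum(
            ((a == i) & (b == j)).sum() * (cell_means[(i, j)] - grand) ** 2
            for i in (0, 1)
            for j in (0, 1)
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((y[(a == i) & (b == j)] - cell_means[(i, j)]) ** 2).sum()
            for i in (0, 1)
            for j in (0, 1)
        )
        ms_err = ss_err / (n - 4)
        tab = res.anova
        assert tab.loc["C(site)", "F"] == pytest.approx(ss_a / ms_err, rel=1e-9)
        assert tab.loc["C(stage)", "F"] == pytest.approx(ss_b / ms_err, rel=1e-9)
        assert tab.loc["C(site):C(stage)", "F"] == pytest.approx(
            ss_ab / ms_err, rel=1e-9
        )

    def test_boxcox_power_recorded(self, rng):
        df = balanced_two_way(rng)
        df["y"] = np.abs(df["y"]) + 1.0
        res = glm_stepwise(
            df, "y", factors=("site", "stage"), interactions=(),
            boxcox_power=-1.124,
        )
        assert res.boxcox_power == -1.124

    def test_removal_order_is_largest_p_first(self, rng):
        # strong site x stage signal, pure-noise other interactions
        rows = []
        for site in ("s1", "s2"):
            for zone in ("low", "mid", "up"):
                for stage in ("ad", "juv"):
                    y = rng.normal(0, 1, 20)
                    y += 2.0 * ((site == "s2") & (stage == "juv"))
                    for v in y:
                        rows.append(
                            {"site": site, "zone": zone, "stage": stage, "y": v}
                        )
        df = pd.DataFrame(rows)
        res = glm_stepwise(df, "y", alpha=0.05)
        assert "C(site):C(stage)" in res.retained_terms
        removed = [t for t, _ in res.removal_trace]
        assert "C(site):C(stage)" not in removed
        assert len(removed) == 2
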