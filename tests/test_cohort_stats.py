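import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cvitools import (
    PairedCohortTable,
    cohort_battery,
    one_way_anova,
    summarize,
    t_tests,
    wilcoxon_signed_rank,
)
from cvitools.cohort_stats import percent_changes, read_study_spreadsheet


def enumeration_oracle(d):
    """Full 2^n sign enumeration of the signed-rank null, two-sided p."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = ranks.sum()
    w_all = np.array([sum(r for r, s in zip(ranks, signs) if s)
                      for signs in itertools.product([False, True], repeat=len(d))])
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_differences_n5(self):
        pairs = [(b, b - d) for b, d in zip([10.0] * 5, [1, 2, 3, 4, 5])]
        res = wilcoxon_signed_rank(pairs)
        assert res.statistic == 0.0  # W = min(W+, W-) with W- = 0
        assert res.p_value == pytest.approx(2 / 2**5)

    def test_identical_pairs_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert res.p_value == 1.0 and res.n_effective == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # rounding induces ties/zeros
        res = wilcoxon_signed_rank(np.column_stack([d, np.zeros(n)]))
        if res.n_effective == 0:
            return
        assert res.p_value == pytest.approx(enumeration_oracle(d), abs=1e-12)

    def test_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(123)
        d = rng.normal(0.5, 1.0, size=12)
        assert len(np.unique(np.abs(d))) == 12
        ours = wilcoxon_signed_rank(np.column_stack([d, np.zeros(12)]))
        ref = sps.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5])
        res = wilcoxon_signed_rank(np.column_stack([d, np.zeros(5)]))
        assert res.n_effective == 3

    def test_large_n_normal_approximation_close_to_exact_logic(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.4, 1.0, size=40)
        ours = wilcoxon_signed_rank(np.column_stack([d, np.zeros(40)]))
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_of_differences_preserves_p(self):
        d = np.array([0.5, 1.5, -0.7, 2.2, 3.0, -0.1, 0.9])
        res1 = wilcoxon_signed_rank(d)
        res2 = wilcoxon_signed_rank(np.sign(d) * np.abs(d) ** 3)  # order & signs preserved
        assert res1.p_value == res2.p_value


class TestTTests:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = t_tests(a, a, paired=True)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sample_against_hand_formula(self):
        a = np.array([4.1, 5.2, 6.3, 5.8])
        b = np.array([3.0, 3.5, 4.2])
        res = t_tests(a, b)
        # Welch formula by hand
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        res = t_tests(a, b, paired=True)
        ref = sps.ttest_1samp(a - b, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestAnova:
    def test_two_groups_f_is_pooled_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_equal_group_means_r2_zero(self):
        res = one_way_anova([[1.0, -1.0], [2.0, -2.0]])
        assert res.extra["R2"] == pytest.approx(0.0, abs=1e-15)

    def test_three_groups_ss_decomposition(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 5), (1, 7), (2, 6)]]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ss_between = ss_total - ss_within
        assert res.extra["R2"] == pytest.approx(ss_between / ss_total, abs=1e-9)
        k, n = 3, len(allv)
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.statistic == pytest.approx(f)

    def test_all_identical_values(self):
        with pytest.warns(UserWarning):
            res = one_way_anova([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert np.isnan(res.statistic) and res.extra["R2"] == 0.0


def toy_table():
    recs = []
    rng = np.random.default_rng(0)
    for g, mean in [("study", 74.0), ("control", 67.0)]:
        for i in range(6):
            b = mean + rng.normal(0, 2)
            recs.append((f"{g}{i}", g, "baseline", "CVI", b))
            recs.append((f"{g}{i}", g, "followup", "CVI", b - (4 if g == "study" else 0.3)))
    return PairedCohortTable.from_records(recs)


class TestTable:
    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PairedCohortTable.from_records([
                ("e1", "study", "baseline", "CVI", 70.0),
                ("e1", "study", "baseline", "CVI", 71.0),
            ])

    def test_summarize_values(self):
        t = PairedCohortTable.from_records([
            ("e1", "control", "baseline", "CVI", 64.2),
            ("e2", "control", "baseline", "CVI", 69.8),
        ])
        mean, sd, lo, hi = summarize(t, "CVI", "control", "baseline")
        assert (lo, hi) == (64.2, 69.8)
        assert mean == pytest.approx(67.0)
        assert sd == pytest.approx(np.std([64.2, 69.8], ddof=1))

    def test_summarize_single_value_degenerate(self):
        t = PairedCohortTable.from_records([("e1", "study", "baseline", "CVI", 70.0)])
        mean, sd, lo, hi = summarize(t, "CVI", "study", "baseline")
        assert np.isnan(sd) and lo == hi == 70.0

    def test_summarize_no_rows_errors(self):
        with pytest.raises(ValueError):
            summarize(toy_table(), "TCA", "study", "baseline")

    def test_simulated_19_values_vs_spreadsheet_arithmetic(self):
        rng = np.random.default_rng(19)
        vals = rng.normal(74.1, 4.7, 19)
        t = PairedCohortTable.from_records(
            [(f"e{i}", "study", "baseline", "CVI", v) for i, v in enumerate(vals)]
        )
        mean, sd, lo, hi = summarize(t, "CVI", "study", "baseline")
        # independent spreadsheet-style arithmetic
        m = sum(vals) / 19
        s = (sum((v - m) ** 2 for v in vals) / 18) ** 0.5
        assert mean == pytest.approx(m)
        assert sd == pytest.approx(s)

    def test_percent_changes_per_eye(self):
        t = toy_table()
        pc = percent_changes(t, "CVI", "study")
        assert len(pc) == 6 and (pc > 0).all()

    def test_battery_shape_and_r2(self):
        battery = cohort_battery(toy_table())
        assert set(battery.columns) == {"metric", "group", "comparison", "method",
                                        "statistic", "p", "R2"}
        anova = battery[battery.method == "anova_oneway"]
        assert ((anova.R2 >= 0) & (anova.R2 <= 1)).all()
        wil = battery[(battery.method == "wilcoxon_signed_rank") & (battery.group == "study")]
        assert len(wil) == 1 and float(wil.p.iloc[0]) < 0.05


class TestSpreadsheetReader:
    def test_wide_xlsx_maps_to_cohort_table(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({
            "eye_id": ["e1", "e1", "e2", "e2"],
            "group": ["study"] * 4,
            "visit": ["baseline", "followup"] * 2,
            "CVI": [74.0, 69.0, 76.0, 70.0],
            "TCA": [0.8, 0.7, 0.9, 0.8],
        })
        p = tmp_path / "cohort.xlsx"
        df.to_excel(p, index=False)
        table = read_study_spreadsheet(p)
        b, f = table.paired_values("cvi", "study")
        assert list(b) == [74.0, 76.0] and list(f) == [69.0, 70.0]
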