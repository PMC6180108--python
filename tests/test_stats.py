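"""Statistical battery: summary t-tests, chi-square, mixed rm-ANOVA, post-hocs.

Mixed-ANOVA results are cross-checked against independent implementations
(pingouin for the mixed design, statsmodels AnovaRM for the pure
within-subject design) and against the paired-t algebraic identity.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from vigikit.stats import (chi_square_2x2, friedman, mann_whitney_u,
                           mixed_rm_anova, paired_t, pooled_t_from_summary,
                           welch_t_from_summary, wilcoxon_signed_rank)


class TestSummaryTTests:
    def test_welch_identical_summaries(self):
        r = welch_t_from_summary(5, 2, 10, 5, 2, 12)
        assert r.statistic == 0 and r.p == pytest.approx(1.0)

    def test_welch_sign_flips_on_swap(self):
        a = welch_t_from_summary(7, 2, 10, 5, 3, 12)
        b = welch_t_from_summary(5, 3, 12, 7, 2, 10)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_welch_equals_pooled_for_equal_n_and_sd(self):
        a = welch_t_from_summary(7, 2, 10, 5, 2, 10)
        b = pooled_t_from_summary(7, 2, 10, 5, 2, 10)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.df == pytest.approx(b.df)

    def test_pooled_equal_means(self):
        assert pooled_t_from_summary(5, 1, 8, 5, 2, 9).statistic == 0

    def test_welch_df_bounded(self):
        r = welch_t_from_summary(7, 2, 10, 5, 6, 12)
        assert r.df <= 20

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(5, 0, 10, 6, 0, 10)
        with pytest.raises(ValueError):
            pooled_t_from_summary(5, 1, 1, 6, 1, 10)


class TestChiSquare:
    def test_homogeneous_table_is_zero(self):
        assert chi_square_2x2(5, 5, 5, 5).statistic == 0

    def test_transposition_invariance(self):
        a = chi_square_2x2(10, 17, 7, 9)
        b = chi_square_2x2(10, 7, 17, 9)
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)

    def test_matches_closed_form(self):
        a, b, c, d = 12, 5, 7, 9
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square_2x2(a, b, c, d).statistic == pytest.approx(expected)


class TestPairedT:
    def test_zero_variance_rejected_with_message(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="zero-variance|undefined"):
            paired_t(x, x)

    def test_direction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 15)
        y = x - 1 + rng.normal(0, 0.01, 15)
        assert paired_t(x, y).statistic > 10

    def test_matches_textbook_formula(self):
        """Oracle: direct t = mean(d) / (sd(d)/sqrt(n)) on 20 random vectors."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(0, 2, n)
            y = x + rng.normal(0.3, 1, n)
            d = x - y
            t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            assert paired_t(x, y).statistic == pytest.approx(t, abs=1e-10)


class TestMixedAnova:
    def _mixed_data(self, seed=7, n=(8, 8), p=4):
        rng = np.random.default_rng(seed)
        rows = []
        for g, ng in zip("ab", n):
            for s in range(ng):
                base = rng.normal(0, 1)
                for w in range(p):
                    rows.append({"subject": f"{g}{s}", "group": g, "w": w,
                                 "y": base + 0.4 * w
                                 + (0.5 if g == "a" else 0) * w
                                 + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_two_level_within_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        y = x + 0.5 + rng.normal(0, 0.8, 12)
        t = paired_t(x, y).statistic
        d = pd.DataFrame({"subject": list(range(12)) * 2,
                          "w": [0] * 12 + [1] * 12,
                          "y": np.concatenate([x, y])})
        tbl = mixed_rm_anova(d, dv="y", subject="subject", within=["w"])
        assert tbl.F.iloc[0] == pytest.approx(t**2)
        assert tbl.eps.iloc[0] == 1.0     # two levels force epsilon = 1

    def test_matches_pingouin_on_balanced_mixed_design(self):
        pg = pytest.importorskip("pingouin")
        df = self._mixed_data()
        mine = mixed_rm_anova(df, dv="y", subject="subject", within=["w"],
                              between="group")
        ref = pg.mixed_anova(data=df, dv="y", within="w", subject="subject",
                             between="group")
        for eff, src in [("group", "group"), ("w", "w"),
                         ("group * w", "Interaction")]:
            mf = mine.loc[mine.effect == eff, "F"].iloc[0]
            rf = ref.loc[ref.Source == src, "F"].iloc[0]
            assert mf == pytest.approx(rf, rel=1e-8)

    def test_matches_anovarm_on_two_within_factors(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(11)
        rows = []
        for s in range(10):
            base = rng.normal(0, 1)
            for a in range(2):
                for b in range(3):
                    rows.append({"subject": s, "A": a, "B": b,
                                 "y": base + 0.3 * a + 0.2 * b + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        mine = mixed_rm_anova(df, dv="y", subject="subject", within=["A", "B"])
        ref = sm.AnovaRM(df, depvar="y", subject="subject",
                         within=["A", "B"]).fit().anova_table
        for eff, src in [("A", "A"), ("B", "B"), ("A * B", "A:B")]:
            assert (mine.loc[mine.effect == eff, "F"].iloc[0]
                    == pytest.approx(ref.loc[src, "F Value"], rel=1e-8))

    def test_missing_cells_rejected_naming_subjects(self):
        df = self._mixed_data()
        df = df[~((df.subject == "a0") & (df.w == 3))]
        with pytest.raises(ValueError, match="a0"):
            mixed_rm_anova(df, dv="y", subject="subject", within=["w"],
                           between="group")

    def test_null_type_one_error_rate(self):
        """Seeded null simulation: group effect rejection rate near nominal."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 500
        for _ in range(reps):
            rows = []
            for g in "ab":
                for s in range(8):
                    y = rng.normal(0, 1, 4)
                    for w in range(4):
                        rows.append({"subject": f"{g}{s}", "group": g,
                                     "w": w, "y": y[w]})
            tbl = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                                 within=["w"], between="group")
            hits += tbl.loc[tbl.effect == "group", "p_reported"].iloc[0] < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_gg_correction_is_conditional_on_mauchly(self):
        df = self._mixed_data(seed=5)
        tbl = mixed_rm_anova(df, dv="y", subject="subject", within=["w"],
                             between="group")
        row = tbl[tbl.effect == "w"].iloc[0]
        expected = row.p_gg if row.mauchly_p < 0.05 else row.p
        assert row.p_reported == expected


class TestNonparametric:
    def test_mann_whitney_identical_samples(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(3 * 3 / 2)

    def test_mann_whitney_exact_matches_enumeration(self):
        """Oracle: full enumeration of the 20 rank splits for n1 = n2 = 3."""
        x = [1.0, 4.0, 6.0]
        y = [2.0, 3.0, 5.0]
        r = mann_whitney_u(x, y)
        assert "exact" in r.note
        ranks = {v: i + 1 for i, v in enumerate(sorted(x + y))}
        u_obs = sum(ranks[v] for v in x) - 3 * 4 / 2
        count = total = 0
        for combo in itertools.combinations(range(1, 7), 3):
            u = sum(combo) - 3 * 4 / 2
            # two-sided: as or more extreme on either tail around n1 n2 / 2
            if abs(u - 4.5) >= abs(u_obs - 4.5) - 1e-12:
                count += 1
            total += 1
        assert r.p == pytest.approx(count / total)

    def test_wilcoxon_detects_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        r = wilcoxon_signed_rank(x + 1.5, x)
        assert r.p < 0.01

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied|zero"):
            mann_whitney_u([3, 3, 3], [3, 3, 3])
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_friedman_two_treatments_monotone_in_discordance(self):
        """k = 2: the statistic grows with the number of discordant pairs."""
        stats = []
        for n_greater in (3, 4, 5):
            x = np.arange(5, dtype=float)
            y = x.copy()
            y[:n_greater] += 1.0
            y[n_greater:] -= 1.0
            stats.append(friedman(x, y).statistic)
        assert stats[0] < stats[1] < stats[2]

    def test_friedman_exact_mode_reported_for_small_n(self):
        r = friedman([1.0, 5.0, 2.0, 6.0], [2.0, 4.0, 3.0, 7.0],
                     [3.0, 6.0, 1.0, 8.0])
        assert r.note == "exact enumeration"
        assert 0.0 <= r.p <= 1.0

    def test_p_monotone_in_statistic(self):
        """Holding df fixed, a larger statistic never yields a larger p."""
        ps = [sst.chi2.sf(s, 1) for s in (0.5, 1.0, 2.0)]
        rs = [chi_square_2x2(10 + k, 10, 10, 10 + k) for k in (0, 3, 6)]
        assert rs[0].statistic < rs[1].statistic < rs[2].statistic
        assert rs[0].p > rs[1].p > rs[2].p
        del ps
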