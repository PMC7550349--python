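"""Group-level tests: t tests, ANOVAs, post-hocs, Kruskal-Wallis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oflphys.stats import (
    Contrast,
    bonferroni_posthoc,
    kruskal_wallis,
    mixed_anova,
    paired_t,
    rm_anova,
    two_sample_t,
)


class TestPairedT:
    def test_identical_samples_are_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_hand_computed_example(self):
        # differences {1, 2, 3}: mean 2, sd 1, t = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-6)
        assert res.df == 2
        assert res.effect_size == pytest.approx(2.0)

    def test_matches_scipy_and_sign_flip_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0.3, 1.0, 40)
            y = rng.normal(0.0, 1.0, 40)
            res = paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
            # sign-flip permutation oracle on the differences
            d = x - y
            flips = rng.choice([-1.0, 1.0], size=(4000, d.size))
            perm_t = (flips * d).mean(axis=1) / (
                (flips * d).std(axis=1, ddof=1) / math.sqrt(d.size)
            )
            p_perm = np.mean(np.abs(perm_t) >= abs(res.statistic))
            se = math.sqrt(max(p_perm * (1 - p_perm), 1e-5) / 4000)
            assert abs(res.p - p_perm) < 0.02 + 4 * se

    def test_ci_covers_mean_difference(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(1.0, 1.0, 25), rng.normal(0.0, 1.0, 25)
        res = paired_t(x, y)
        lo, hi = res.ci
        assert lo < np.mean(x - y) < hi


def _manual_rm_2x2(values: dict) -> dict:
    """Hand-worked Type III sums-of-squares for a 2x2 within design.

    values maps (subject, a_level, b_level) -> y.  Returns F per effect.
    """
    subjects = sorted({k[0] for k in values})
    a_levels = sorted({k[1] for k in values})
    b_levels = sorted({k[2] for k in values})
    n, na, nb = len(subjects), len(a_levels), len(b_levels)
    grand = np.mean(list(values.values()))

    def mean_where(s=None, a=None, b=None):
        sel = [
            v for (si, ai, bi), v in values.items()
            if (s is None or si == s) and (a is None or ai == a) and (b is None or bi == b)
        ]
        return np.mean(sel)

    ss_a = n * nb * sum((mean_where(a=a) - grand) ** 2 for a in a_levels)
    ss_b = n * na * sum((mean_where(b=b) - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (mean_where(a=a, b=b) - mean_where(a=a) - mean_where(b=b) + grand) ** 2
        for a in a_levels for b in b_levels
    )
    ss_err_a = nb * sum(
        (mean_where(s=s, a=a) - mean_where(s=s) - mean_where(a=a) + grand) ** 2
        for s in subjects for a in a_levels
    )
    ss_err_b = na * sum(
        (mean_where(s=s, b=b) - mean_where(s=s) - mean_where(b=b) + grand) ** 2
        for s in subjects for b in b_levels
    )
    ss_err_ab = sum(
        (
            values[(s, a, b)]
            - mean_where(s=s, a=a) - mean_where(s=s, b=b) - mean_where(a=a, b=b)
            + mean_where(s=s) + mean_where(a=a) + mean_where(b=b) - grand
        ) ** 2
        for s in subjects for a in a_levels for b in b_levels
    )
    return {
        "a": (ss_a / (na - 1)) / (ss_err_a / ((n - 1) * (na - 1))),
        "b": (ss_b / (nb - 1)) / (ss_err_b / ((n - 1) * (nb - 1))),
        "ab": (ss_ab / ((na - 1) * (nb - 1)))
        / (ss_err_ab / ((n - 1) * (na - 1) * (nb - 1))),
    }


def _mean_where(values, **kw):
    sel = [v for k, v in values.items() if all(k[i] == val for i, val in kw.items())]
    return np.mean(sel)


class TestRmAnova:
    def _table(self, values):
        rows = [
            {"subject_id": s, "a": a, "b": b, "value": v}
            for (s, a, b), v in values.items()
        ]
        return pd.DataFrame(rows)

    def test_constant_values_give_zero_f(self):
        values = {(s, a, b): 3.0 for s in "wxyz" for a in "01" for b in "01"}
        res = rm_anova(self._table(values), "value", ["a", "b"], "subject_id")
        assert all(r.statistic == 0.0 and r.p == 1.0 for r in res)

    def test_two_by_two_matches_hand_worked_decomposition(self):
        rng = np.random.default_rng(11)
        values = {
            (s, a, b): float(rng.normal(ord(a) * 0.5 + ord(b) * 0.2, 1.0))
            for s in "wxyz" for a in "01" for b in "01"
        }
        res = {r.name: r for r in rm_anova(self._table(values), "value", ["a", "b"], "subject_id")}
        manual = _manual_rm_2x2(values)
        assert res["a"].statistic == pytest.approx(manual["a"], rel=1e-9)
        assert res["b"].statistic == pytest.approx(manual["b"], rel=1e-9)
        assert res["a * b"].statistic == pytest.approx(manual["ab"], rel=1e-9)

    def test_partial_eta_squared_consistent_with_ss(self):
        rng = np.random.default_rng(12)
        rows = [
            {"subject_id": f"s{s}", "w": w, "value": float(rng.normal(0.3 * i, 1.0))}
            for s in range(8) for i, w in enumerate("abc")
        ]
        res = rm_anova(pd.DataFrame(rows), "value", "w", "subject_id")[0]
        np2 = res.extra["SS"] / (res.extra["SS"] + res.extra["SS_error"])
        assert res.effect_size == pytest.approx(np2, abs=1e-12)
        # 3-level factor also reports the sphericity-corrected p
        assert "p_GG_corr" in res.extra

    def test_missing_cell_rejected(self):
        values = {(s, a, b): 1.0 for s in "wxyz" for a in "01" for b in "01"}
        values.pop(("w", "0", "0"))
        with pytest.raises(ValueError):
            rm_anova(self._table(values), "value", ["a", "b"], "subject_id")


def _mixed_table(rng, n_a=6, n_b=6, effect=0.0):
    rows = []
    for g, n in (("g1", n_a), ("g2", n_b)):
        for s in range(n):
            base = rng.normal()
            for w, delta in (("w1", 0.0), ("w2", effect if g == "g1" else 0.0)):
                rows.append(
                    {"subject_id": f"{g}_{s}", "group": g, "stimulus": w,
                     "value": base + rng.normal() + delta}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_location_shift_invariance(self):
        rng = np.random.default_rng(21)
        df = _mixed_table(rng, effect=0.8)
        res1 = mixed_anova(df, "value", "stimulus", "group", "subject_id")
        df2 = df.assign(value=df.value + 100.0)
        res2 = mixed_anova(df2, "value", "stimulus", "group", "subject_id")
        for a, b in zip(res1, res2):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_interaction_equals_two_sample_t_on_differences(self):
        """For 2 x 2 designs the interaction F is the squared t comparing
        within-subject differences between groups."""
        rng = np.random.default_rng(22)
        df = _mixed_table(rng, effect=1.0)
        res = {r.name: r for r in mixed_anova(df, "value", "stimulus", "group", "subject_id")}
        wide = df.pivot_table(index=["subject_id", "group"], columns="stimulus",
                              values="value").reset_index()
        diff = wide["w2"] - wide["w1"]
        t = two_sample_t(diff[wide.group == "g1"], diff[wide.group == "g2"])
        assert res["Interaction"].statistic == pytest.approx(t.statistic ** 2, rel=1e-6)
        assert res["Interaction"].p == pytest.approx(t.p, rel=1e-6)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(23)
        df = _mixed_table(rng, n_b=1)
        with pytest.raises(ValueError):
            mixed_anova(df, "value", "stimulus", "group", "subject_id")


class TestPosthoc:
    def _table(self, rng, n=10):
        rows = []
        for g, gn in (("aware", n), ("unaware", n)):
            for s in range(gn):
                for c, delta in (("cs_plus", 0.5 if g == "aware" else 0.0), ("cs_minus", 0.0)):
                    rows.append(
                        {"subject_id": f"{g}{s}", "group": g, "condition": c,
                         "value": float(rng.normal(delta, 1.0))}
                    )
        return pd.DataFrame(rows)

    def test_single_contrast_uncorrected(self):
        rng = np.random.default_rng(31)
        table = self._table(rng)
        con = [Contrast("paired", "cs_plus", "cs_minus")]
        res = bonferroni_posthoc(table, con)[0]
        wide = table.pivot(index="subject_id", columns="condition", values="value")
        ref = paired_t(wide["cs_plus"], wide["cs_minus"])
        assert res.p == pytest.approx(ref.p)
        assert res.correction == "bonferroni"

    def test_correction_multiplies_and_caps(self):
        rng = np.random.default_rng(32)
        table = self._table(rng)
        cons = [
            Contrast("paired", "cs_plus", "cs_minus", group="aware"),
            Contrast("paired", "cs_plus", "cs_minus", group="unaware"),
            Contrast("between", "aware", "unaware", condition="cs_plus"),
        ]
        res = bonferroni_posthoc(table, cons)
        aware = table[table.group == "aware"].pivot(
            index="subject_id", columns="condition", values="value")
        raw = paired_t(aware["cs_plus"], aware["cs_minus"]).p
        assert res[0].p == pytest.approx(min(1.0, 3 * raw))
        assert all(r.p <= 1.0 for r in res)

    def test_between_contrast_matches_two_sample_oracle(self):
        rng = np.random.default_rng(33)
        table = self._table(rng)
        res = bonferroni_posthoc(
            table, [Contrast("between", "aware", "unaware", condition="cs_plus")]
        )[0]
        a = table[(table.group == "aware") & (table.condition == "cs_plus")]["value"]
        u = table[(table.group == "unaware") & (table.condition == "cs_plus")]["value"]
        ref = two_sample_t(a, u)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.effect_size == pytest.approx(ref.effect_size)

    def test_unknown_label_rejected(self):
        rng = np.random.default_rng(34)
        with pytest.raises(ValueError):
            bonferroni_posthoc(self._table(rng), [Contrast("paired", "cs_plus", "nope")])


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[3, 3, 3], [3, 3, 3]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_h(self):
        # ranks 1..6, rank sums 6 and 15: H = 12/42 * (12 + 75) - 21
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-9)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_against_exact_permutation_distribution(self):
        """H computed on every relabeling matches a brute-force oracle and
        the chi-square p is close to the exact permutation p."""
        data = [2.0, 5.0, 1.0, 7.0, 4.0, 6.0]
        obs = kruskal_wallis([data[:3], data[3:]])
        ranks = sps.rankdata(data)
        n = len(data)

        def h_of(idx):
            r1 = ranks[list(idx)]
            r2 = np.delete(ranks, list(idx))
            return 12 / (n * (n + 1)) * (r1.sum() ** 2 / 3 + r2.sum() ** 2 / 3) - 3 * (n + 1)

        hs = [h_of(c) for c in itertools.combinations(range(n), 3)]
        assert obs.statistic == pytest.approx(h_of((0, 1, 2)), abs=1e-9)
        p_exact = np.mean([h >= obs.statistic - 1e-12 for h in hs])
        assert abs(obs.p - p_exact) < 0.12

    def test_row_order_invariance(self):
        rng = np.random.default_rng(41)
        a, b = rng.normal(size=9), rng.normal(1.0, 1.0, 11)
        r1 = kruskal_wallis([a, b])
        r2 = kruskal_wallis([a[::-1], b[::-1]])
        assert r1.statistic == pytest.approx(r2.statistic)
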