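import math

import numpy as np
import pandas as pd
import pytest

from bivtrans.expression_analysis import (
    CohortLabel,
    expression_filter,
    fraction_lower,
    geneset_cumulative_score,
    group_difference_summary,
    label_cohort,
    mann_whitney_u,
    read_expression_table,
    tnbc_label,
    welch_t_test,
)
from bivtrans.state_classifier import (
    ChromatinState,
    TransitionGroup,
    TransitionRecord,
    TransitionTable,
)
from oracles import mwu_two_sided_exact, mwu_u_statistic

S = ChromatinState
G = TransitionGroup


class TestExpressionFilter:
    def _table(self, values):
        return pd.DataFrame({"fpkm": values},
                            index=[f"g{i}" for i in range(len(values))])

    def test_strict_threshold(self):
        table = self._table([10.0, 10.1, 9.9, 50.0])
        kept = expression_filter(table, "fpkm", 10.0)
        assert kept.members == {"g1", "g3"}

    def test_missing_column(self):
        with pytest.raises(KeyError):
            expression_filter(self._table([1.0]), "nope")

    def test_random_matches_loop(self, rng):
        values = rng.lognormal(2, 1, size=200)
        table = self._table(values)
        kept = expression_filter(table, "fpkm", 10.0)
        expected = {f"g{i}" for i, v in enumerate(values) if v > 10.0}
        assert kept.members == expected


class TestFractionLower:
    def test_worked_256_of_369(self, rng):
        # fixture with exactly 256 of 369 genes strictly lower in B
        n_lower_planted, n_total = 256, 369
        a = rng.uniform(10, 100, size=n_total)
        b = a.copy()
        b[:n_lower_planted] = a[:n_lower_planted] * rng.uniform(
            0.1, 0.99, size=n_lower_planted
        )
        b[n_lower_planted:] = a[n_lower_planted:] * rng.uniform(
            1.0, 2.0, size=n_total - n_lower_planted
        )
        b[n_lower_planted:] = np.maximum(b[n_lower_planted:], a[n_lower_planted:])
        genes = [f"g{i}" for i in range(n_total)]
        table = pd.DataFrame({"A": a, "B": b}, index=genes)
        n_lower, total, frac = fraction_lower(table, "A", "B", genes)
        assert (n_lower, total) == (256, 369)
        assert 100 * frac == pytest.approx(69.4, abs=0.05)

    def test_ties_not_lower(self):
        table = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0]}, index=["x", "y"])
        n_lower, total, frac = fraction_lower(table, "A", "B", ["x", "y"])
        assert (n_lower, frac) == (0, 0.0)

    def test_random_matches_brute_force(self, rng):
        a = rng.lognormal(1, 1, size=100)
        b = rng.lognormal(1, 1, size=100)
        genes = [f"g{i}" for i in range(100)]
        table = pd.DataFrame({"A": a, "B": b}, index=genes)
        n_lower, total, frac = fraction_lower(table, "A", "B", genes)
        expected = sum(1 for x, y in zip(a, b) if y < x)
        assert n_lower == expected
        assert frac == pytest.approx(expected / 100)

    def test_absent_genes_skipped(self):
        table = pd.DataFrame({"A": [2.0], "B": [1.0]}, index=["x"])
        n_lower, total, frac = fraction_lower(table, "A", "B", ["x", "ghost"])
        assert (n_lower, total) == (1, 1)

    def test_empty_effective_set_errors(self):
        table = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            fraction_lower(table, "A", "B", ["ghost"])

    def test_gene_order_invariance(self, rng):
        a = rng.lognormal(1, 1, size=50)
        b = rng.lognormal(1, 1, size=50)
        genes = [f"g{i}" for i in range(50)]
        table = pd.DataFrame({"A": a, "B": b}, index=genes)
        forward = fraction_lower(table, "A", "B", genes)
        backward = fraction_lower(table, "A", "B", list(reversed(genes)))
        assert forward == backward


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_singletons(self):
        u, p = mann_whitney_u([5.0], [5.0])
        assert u == 0.5
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for nx in range(1, 7):
            for ny in range(1, 7):
                values = rng.permutation(np.arange(1.0, nx + ny + 1.0))
                x, y = values[:nx], values[nx:]
                u, p = mann_whitney_u(x, y, mode="exact")
                assert u == mwu_u_statistic(x, y)
                expected = float(mwu_two_sided_exact(list(x), list(y)))
                assert p == pytest.approx(expected, abs=1e-12)

    def test_u_complement_identity(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=5)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        u1, p1 = mann_whitney_u(x, y, mode="exact")
        u2, p2 = mann_whitney_u(np.exp(x), np.exp(y), mode="exact")
        assert u1 == u2
        assert p1 == pytest.approx(p2)

    def test_ties_fall_back_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            mann_whitney_u([1.0, 2.0], [2.0, 3.0], mode="exact")
        assert "normal approximation" in caplog.text

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestGroupDifferenceSummary:
    def _table_and_transitions(self, rng, repress_I=True):
        groups = {"I": 40, "II": 30, "III": 30, "IV": 30}
        state_a = {"I": S.K4_ONLY, "II": S.K27_ONLY, "III": S.UNMARKED,
                   "IV": S.BIVALENT}
        records, rows = [], {}
        for label, n in groups.items():
            for i in range(n):
                gene = f"{label}_{i}"
                records.append(
                    TransitionRecord(gene, state_a[label], S.BIVALENT, G(label))
                )
                a = float(rng.lognormal(2, 1))
                if label == "I" and repress_I:
                    b = a * float(rng.uniform(0.05, 0.6))
                else:
                    b = a * float(rng.uniform(0.9, 1.1))
                rows[gene] = (a, b)
        table = pd.DataFrame(
            {g: v for g, v in rows.items()}, index=["A", "B"]
        ).T
        return table, TransitionTable(records)

    def test_planted_repression_pattern(self, rng):
        table, transitions = self._table_and_transitions(rng)
        summaries = {
            s.group: s
            for s in group_difference_summary(table, "A", "B", transitions)
        }
        assert summaries["I"].mean_difference < 0
        for other in ("II", "III", "IV"):
            assert abs(summaries["I"].mean_difference) > abs(
                summaries[other].mean_difference
            )
        assert summaries["I"].pairwise_p[("I", "II")] < 0.05

    def test_identical_columns(self, rng):
        table, transitions = self._table_and_transitions(rng)
        table["B"] = table["A"]
        summaries = group_difference_summary(
            table, "A", "B", transitions, mwu_mode="normal_approx"
        )
        for s in summaries:
            assert s.mean_difference == 0.0
            assert s.fraction_lower == 0.0
            for p in s.pairwise_p.values():
                assert p == pytest.approx(1.0)

    def test_mean_sem_textbook_formulas(self, rng):
        table, transitions = self._table_and_transitions(rng)
        summaries = group_difference_summary(table, "A", "B", transitions)
        for s in summaries:
            genes = [g for g in table.index if g.startswith(s.group + "_")]
            d = (table.loc[genes, "B"] - table.loc[genes, "A"]).to_numpy()
            mean = d.sum() / len(d)
            sem = math.sqrt(
                ((d - mean) ** 2).sum() / (len(d) - 1)
            ) / math.sqrt(len(d))
            assert s.mean_difference == pytest.approx(mean)
            assert s.sem_difference == pytest.approx(sem)

    def test_all_pairs_mode(self, rng):
        table, transitions = self._table_and_transitions(rng)
        summaries = group_difference_summary(
            table, "A", "B", transitions, pairing="all_pairs"
        )
        all_pairs = {p for s in summaries for p in s.pairwise_p}
        assert len(all_pairs) == 6


class TestGenesetCumulativeScore:
    def test_sum_and_mean(self):
        matrix = pd.DataFrame(
            {"s1": [3.0, 4.0], "s2": [1.0, 1.0]}, index=["g1", "g2"]
        )
        sums = geneset_cumulative_score(matrix, ["g1", "g2"], "sum")
        assert sums["s1"] == 7.0
        means = geneset_cumulative_score(matrix, ["g1", "g2"], "mean")
        assert means["s1"] == 3.5

    def test_random_matches_loop(self, rng):
        matrix = pd.DataFrame(
            rng.lognormal(1, 1, size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(10)],
        )
        genes = [f"g{i}" for i in range(0, 30, 3)]
        scores = geneset_cumulative_score(matrix, genes, "sum")
        for j in range(10):
            expected = sum(matrix.loc[g, f"s{j}"] for g in genes)
            assert scores[f"s{j}"] == pytest.approx(expected)

    def test_empty_intersection_errors(self):
        matrix = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            geneset_cumulative_score(matrix, ["ghost"])


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_monotone_in_shift(self):
        x = [1.0, 2.0, 3.0]
        last_p = 1.1
        for shift in (1.0, 3.0, 10.0, 100.0):
            _, _, p = welch_t_test(x, [v + shift for v in x])
            assert p < last_p
            last_p = p

    def test_hand_computed_formula(self):
        x = np.array([2.1, 2.5, 2.9, 3.3])
        y = np.array([1.0, 1.8, 2.0])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 3
        t_expected = (x.mean() - y.mean()) / math.sqrt(se2)
        df_expected = se2**2 / ((vx / 4) ** 2 / 3 + (vy / 3) ** 2 / 2)
        t, df, p = welch_t_test(x, y)
        assert t == pytest.approx(t_expected)
        assert df == pytest.approx(df_expected)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(t_expected), df_expected))

    def test_zero_variance_equal_means(self):
        t, _, p = welch_t_test([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_agrees_with_pooled_t_on_balanced_equal_variance(self, rng):
        # equal-variance balanced design: Welch statistic equals pooled t
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0.5, 1, size=10)
        t, df, _ = welch_t_test(x, y)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        t_pooled = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 10 + 1 / 10))
        assert t == pytest.approx(t_pooled, abs=1e-10)


class TestTnbcLabel:
    def test_all_negative_is_tn(self):
        assert tnbc_label("negative", "negative", "negative") is CohortLabel.TN

    def test_any_positive_is_non_tn(self):
        assert tnbc_label("positive", "negative", "negative") is CohortLabel.NON_TN
        assert tnbc_label("indeterminate", "positive", "negative") is (
            CohortLabel.NON_TN
        )

    def test_indeterminate_without_positive_excluded(self):
        assert tnbc_label("indeterminate", "negative", "negative") is (
            CohortLabel.EXCLUDED
        )

    def test_unknown_token_errors(self):
        with pytest.raises(ValueError, match="unknown receptor status"):
            tnbc_label("equivocal", "negative", "negative")

    def test_label_cohort_frame(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "ER": ["negative", "positive", "indeterminate"],
                "PR": ["negative", "negative", "negative"],
                "HER2": ["negative", "negative", "negative"],
            }
        )
        labels = label_cohort(meta)
        assert labels["s1"] is CohortLabel.TN
        assert labels["s2"] is CohortLabel.NON_TN
        assert labels["s3"] is CohortLabel.EXCLUDED


def test_read_expression_table_roundtrip(tmp_path, rng):
    df = pd.DataFrame(
        rng.lognormal(1, 1, size=(5, 2)),
        index=[f"g{i}" for i in range(5)],
        columns=["A", "B"],
    ).rename_axis("gene_id")
    p = tmp_path / "expr.tsv"
    df.to_csv(p, sep="\t")
    back = read_expression_table(p)
    pd.testing.assert_frame_equal(df, back)
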