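"""Time budgets, confusion matrices, Kendall's W, Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethotrace import (
    BehaviorSequence,
    column_normalize,
    concordance_pvalue,
    confusion_matrix,
    cumulative_curves,
    kendalls_w,
    pairwise_day_correlations,
    spearman_rho,
    time_budget,
)
from ethotrace.config import OUT_OF_VIEW

LABELS = ["Standing", "Lying down", "Foraging", OUT_OF_VIEW]


def sec_seq(labels):
    return BehaviorSequence(np.array(labels, dtype=object), "second", 25.0)


class TestTimeBudget:
    def test_single_behavior_100_percent(self, cfg):
        tb = time_budget(sec_seq(["Standing"] * 25200), cfg)
        assert tb.percents["Standing"] == pytest.approx(100.0)
        assert tb.total_duration_s == 25200

    def test_half_and_half(self, cfg):
        tb = time_budget(sec_seq(["Standing"] * 50 + ["Lying down"] * 50), cfg)
        assert tb.percents["Standing"] == pytest.approx(50.0)
        assert tb.percents["Lying down"] == pytest.approx(50.0)

    def test_matches_counting_oracle(self, cfg):
        rng = np.random.default_rng(0)
        labels = [cfg.label_order[rng.integers(7)] for _ in range(500)]
        tb = time_budget(sec_seq(labels), cfg)
        for name in cfg.label_order:
            assert tb.percents[name] == pytest.approx(
                100.0 * labels.count(name) / 500
            )

    def test_empty_sequence_rejected(self, cfg):
        with pytest.raises(ValueError):
            time_budget(sec_seq([]), cfg)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=200))
    def test_budget_conservation(self, labels):
        """Percentages always sum to 100 and are each nonnegative."""
        tb = time_budget(sec_seq(labels))
        assert tb.percents.sum() == pytest.approx(100.0, abs=1e-9)
        assert (tb.percents >= 0).all()


class TestCumulativeCurves:
    def test_constant_behavior_straight_line(self, cfg):
        curves = cumulative_curves(sec_seq(["Foraging"] * 30), cfg)
        np.testing.assert_allclose(curves["Foraging"], np.arange(1, 31))
        assert curves["Drinking"].sum() == 0.0

    def test_alternating_staircases(self, cfg):
        labels = ["Standing", "Lying down"] * 20
        curves = cumulative_curves(sec_seq(labels), cfg)
        assert curves["Standing"].iloc[-1] == 20
        assert curves["Lying down"].iloc[-1] == 20
        # staircase: increments are 0 or 1, alternating phase
        inc = np.diff(curves["Standing"].to_numpy())
        assert set(inc) == {0.0, 1.0}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=150))
    def test_curves_nondecreasing_and_conserve_total(self, labels):
        curves = cumulative_curves(sec_seq(labels))
        assert (curves.diff().fillna(0.0).to_numpy() >= 0).all()
        assert curves.iloc[-1].sum() == pytest.approx(len(labels))


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self, cfg):
        rng = np.random.default_rng(1)
        labels = [cfg.label_order[rng.integers(7)] for _ in range(300)]
        cm = confusion_matrix(sec_seq(labels), sec_seq(labels), cfg)
        counts = cm.counts.to_numpy()
        assert np.trace(counts) == 300
        assert counts.sum() == 300
        norm = column_normalize(cm)
        occupied = [l for l in cfg.label_order if labels.count(l)]
        sub = norm.loc[occupied, occupied].to_numpy()
        np.testing.assert_allclose(np.diag(sub), 1.0)

    def test_systematic_confusion_single_cell(self, cfg):
        """A model that always answers 'Standing' while the animal drinks
        puts all mass in one off-diagonal cell."""
        pred = sec_seq(["Standing"] * 40)
        obs = sec_seq(["Drinking"] * 40)
        cm = confusion_matrix(pred, obs, cfg)
        assert cm.counts.loc["Standing", "Drinking"] == 40
        assert cm.total == 40
        assert column_normalize(cm).loc["Standing", "Drinking"] == 1.0

    def test_matches_pairwise_counting_oracle(self, cfg):
        rng = np.random.default_rng(2)
        pred = [cfg.label_order[rng.integers(7)] for _ in range(400)]
        obs = [cfg.label_order[rng.integers(7)] for _ in range(400)]
        cm = confusion_matrix(sec_seq(pred), sec_seq(obs), cfg)
        for i in cfg.label_order:
            for j in cfg.label_order:
                want = sum(p == i and o == j for p, o in zip(pred, obs))
                assert cm.counts.loc[i, j] == want

    def test_length_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(sec_seq(["Standing"] * 5),
                             sec_seq(["Standing"] * 6), cfg)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=100),
           st.integers(0, 2**31 - 1))
    def test_normalized_columns_sum_to_one_or_zero(self, obs, seed):
        rng = np.random.default_rng(seed)
        pred = [LABELS[rng.integers(4)] for _ in obs]
        cm = confusion_matrix(sec_seq(pred), sec_seq(obs))
        sums = column_normalize(cm).sum(axis=0)
        for label in sums.index:
            expected = 1.0 if cm.counts[label].sum() else 0.0
            assert sums[label] == pytest.approx(expected)


def naive_rank(values):
    """Average ranks by explicit enumeration (test-side oracle)."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return np.array(out)


def naive_w(table):
    """Brute-force Kendall's W: rank rows, sum ranks, classic formula."""
    table = np.asarray(table, dtype=float)
    m, n = table.shape
    ranks = np.vstack([naive_rank(row) for row in table])
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    T = 0.0
    for row in ranks:
        for v in set(row.tolist()):
            t = (row == v).sum()
            T += t**3 - t
    return 12.0 * S / (m * m * (n**3 - n) - m * T)


class TestKendallsW:
    def test_identical_rankings_give_w_one(self):
        table = np.tile(np.arange(6, dtype=float), (4, 1))
        res = kendalls_w(table)
        assert res.W == pytest.approx(1.0)
        assert res.m == 4 and res.n == 6
        assert res.chi2 == pytest.approx(res.m * (res.n - 1))

    def test_reversed_pair_gives_w_zero(self):
        table = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        res = kendalls_w(table)
        assert res.W == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_tables(self):
        """100 random tables, continuous and tied: W equals the naive
        rank-sum oracle and (untied) the mean-pairwise-Spearman identity."""
        rng = np.random.default_rng(3)
        for i in range(100):
            m = int(rng.integers(2, 8))
            n = int(rng.integers(3, 9))
            if i % 2:
                table = rng.normal(size=(m, n))  # continuous: no ties
            else:
                table = rng.integers(0, 4, size=(m, n)).astype(float)
            res = kendalls_w(table)
            assert res.W == pytest.approx(naive_w(table), abs=1e-12)
            if i % 2 and m >= 2:
                rhos = [
                    spearman_rho(table[a], table[b])
                    for a in range(m) for b in range(a + 1, m)
                ]
                w_from_rho = ((m - 1) * np.mean(rhos) + 1) / m
                assert res.W == pytest.approx(w_from_rho, abs=1e-9)

    def test_tie_correction_flag(self):
        res = kendalls_w(np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]]))
        assert res.tie_corrected
        res2 = kendalls_w(np.array([[1.0, 4.0, 2.0], [1.0, 2.0, 3.0]]))
        assert not res2.tie_corrected

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((1, 5)))
        with pytest.raises(ValueError):
            kendalls_w(np.ones((3, 1)))

    def test_concordance_pvalue_matches_table_route(self):
        rng = np.random.default_rng(4)
        table = rng.normal(size=(5, 6))
        res = kendalls_w(table)
        assert concordance_pvalue(res.W, res.m, res.n) == pytest.approx(res.p)


class TestSpearman:
    def test_identity_is_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rx, ry = naive_rank(x), naive_rank(y)
            want = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(want, abs=1e-12)


class TestPairwiseDayCorrelations:
    def test_identical_days_correlate_fully(self):
        curve = np.cumsum(np.random.default_rng(6).random(60))
        table = pairwise_day_correlations({"d1": curve, "d2": curve.copy()})
        assert table.loc["d1", "d2"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(table.to_numpy()), 1.0)

    def test_reversed_day_correlates_negatively(self):
        x = np.arange(30, dtype=float)
        table = pairwise_day_correlations({"a": x, "b": x[::-1]})
        assert table.loc["a", "b"] == pytest.approx(-1.0)
        assert table.loc["b", "a"] == pytest.approx(-1.0)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            pairwise_day_correlations({"a": np.arange(10.0),
                                       "b": np.arange(9.0)})

    def test_shared_onset_correlates_higher_than_shifted(self, cfg):
        """Nights with the same sleep onset rank-correlate higher than a
        night whose onset is shifted by two hours."""
        def night(onset_min, seed):
            rng = np.random.default_rng(seed)
            labels = np.array(["Standing"] * 420, dtype=object)  # minutes
            start = onset_min + int(rng.integers(0, 5))
            labels[start : start + 150] = "Lying down"
            per_min = (labels == "Lying down").astype(float)
            return np.cumsum(per_min)

        curves = {
            "shared1": night(120, 1),
            "shared2": night(120, 2),
            "shifted": night(240, 3),
        }
        table = pairwise_day_correlations(curves)
        assert table.loc["shared1", "shared2"] > table.loc["shared1", "shifted"]
        assert table.loc["shared1", "shared2"] > table.loc["shared2", "shifted"]
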