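"""Verbal-response statistics: accuracy table, normality gate, paired tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from eegaffect.protocol import ResponseEffectSpec, build_study, simulate_verbal_responses
from eegaffect.stats import (
    accuracy_table,
    across_session_test,
    normality_gate,
    wilcoxon_exact,
    within_session_test,
)


def make_acc(rows):
    """rows: (pid, group, session, condition, n_correct)"""
    df = pd.DataFrame(rows, columns=[
        "participant_id", "group", "session_index", "condition", "n_correct",
    ])
    df["n_total"] = 12
    df["accuracy"] = df["n_correct"] / 12
    return df


class TestAccuracyTable:
    def _responses(self, correct_flags):
        rows = []
        for i, flag in enumerate(correct_flags):
            rows.append(("P1", "EG", 1, "NM1", f"s{i}", "happy",
                         "happy" if flag else "sad", bool(flag)))
        return pd.DataFrame(rows, columns=[
            "participant_id", "group", "session_index", "condition",
            "stimulus_id", "true_emotion", "responded_emotion", "correct",
        ])

    def test_all_correct(self):
        acc = accuracy_table(self._responses([True] * 12))
        assert acc["accuracy"].tolist() == [1.0]
        assert acc["n_correct"].tolist() == [12]

    def test_nine_of_twelve(self):
        acc = accuracy_table(self._responses([True] * 9 + [False] * 3))
        assert acc["accuracy"].tolist() == [0.75]

    def test_empty_input_empty_table(self):
        acc = accuracy_table(self._responses([]).iloc[:0])
        assert acc.empty

    def test_duplicate_rows_rejected(self):
        resp = pd.concat([self._responses([True]), self._responses([True])])
        with pytest.raises(ValueError, match="duplicate"):
            accuracy_table(resp)


class TestNormalityGate:
    def test_normal_samples_usually_pass(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(12)
            hits += normality_gate(x).extras["route"] == "parametric"
        assert hits >= 90

    def test_skewed_samples_usually_flagged(self):
        hits = 0
        for seed in range(100):
            # squared exponential: heavily right-skewed
            x = np.random.default_rng(seed).exponential(size=14) ** 2
            hits += normality_gate(x).extras["route"] == "nonparametric"
        assert hits >= 80

    def test_w_statistic_at_most_one(self):
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(10)
            assert normality_gate(x).statistic <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_gate(np.ones(10))


class TestWilcoxonExact:
    def test_matches_full_enumeration_small_n(self):
        """Oracle: enumerate all 2^n sign assignments for n <= 12."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(3, 13)
            d = rng.integers(-6, 7, size=n).astype(float)
            if np.all(d == 0):
                continue
            _, p = wilcoxon_exact(d)
            nz = d[d != 0]
            ranks = sst.rankdata(np.abs(nz))
            wp = ranks[nz > 0].sum()
            null = np.array([
                float(np.dot(ranks, s)) for s in product((0, 1), repeat=len(nz))
            ])
            cdf = np.mean(null <= wp + 1e-12)
            sf = np.mean(null >= wp - 1e-12)
            assert np.isclose(p, min(1.0, 2 * min(cdf, sf)), atol=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.standard_normal(12)
            _, p = wilcoxon_exact(d)
            assert np.isclose(p, sst.wilcoxon(d, method="exact").pvalue, atol=1e-12)

    def test_unanimous_improvement_minimum_tail(self):
        """All 14 participants improve: two-sided p = 2 / 2^14."""
        _, p = wilcoxon_exact(np.ones(14))
        assert np.isclose(p, 2.0 / 2**14, atol=1e-15)


class TestWithinSessionTest:
    def test_identical_conditions_p_one(self):
        rows = [(f"P{i}", "EG", s, c, 8)
                for i in range(6) for s in (1, 2) for c in ("NM1", "NM3")]
        rep = within_session_test(make_acc(rows))
        assert rep.p_value == 1.0
        assert "zero" in rep.note

    def test_unanimous_gain_minimum_tail(self):
        rows = []
        for i in range(14):
            rows.append((f"P{i}", "EG", 1, "NM1", 6))
            rows.append((f"P{i}", "EG", 1, "NM3", 7 + (i % 3)))
        rep = within_session_test(make_acc(rows))
        assert rep.p_value <= 2.0 / 2**13  # well into the minimum tail
        assert rep.extras["n_effective"] == 14

    def test_null_type_one_error(self):
        """delta = 0 response model: rejection rate near 0.05 (500 seeds)."""
        scheds = build_study(seed=0)
        rejections = 0
        n_sim = 500
        for seed in range(n_sim):
            resp = simulate_verbal_responses(scheds, ResponseEffectSpec(0.5, 0.0),
                                             seed=seed)
            rep = within_session_test(accuracy_table(resp), group="EG")
            rejections += rep.p_value <= 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestAcrossSessionTest:
    def test_identical_first_last_p_one(self):
        rows = []
        for i in range(6):
            rows.append((f"P{i}", "EG", 1, "NM1", 8))
            rows.append((f"P{i}", "EG", 5, "NM1", 8))
        reps = across_session_test(make_acc(rows))
        assert reps["EG"].statistic == 0.0
        assert reps["EG"].p_value == 1.0

    def test_t_equals_mean_over_se(self):
        rng = np.random.default_rng(0)
        rows = []
        d_true = rng.integers(0, 5, size=10)
        base = rng.integers(4, 8, size=10)
        for i in range(10):
            rows.append((f"P{i}", "EG", 1, "NM1", int(base[i])))
            rows.append((f"P{i}", "EG", 5, "NM1", int(base[i] + d_true[i])))
        rep = across_session_test(make_acc(rows))["EG"]
        d = d_true.astype(float)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert np.isclose(rep.statistic, d.mean() / se, atol=1e-9)
        assert np.isclose(rep.extras["se_diff"], se)

    def test_f_equals_t_squared_vs_rm_anova(self):
        """Two repeated measures: the paired t statistic squared equals the
        repeated-measures ANOVA F (pingouin oracle)."""
        import pingouin as pg

        rng = np.random.default_rng(3)
        rows, long = [], []
        for i in range(12):
            a, b = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            rows.append((f"P{i}", "EG", 1, "NM1", a))
            rows.append((f"P{i}", "EG", 5, "NM1", b))
            long += [(f"P{i}", "first", a), (f"P{i}", "last", b)]
        rep = across_session_test(make_acc(rows))["EG"]
        df = pd.DataFrame(long, columns=["pid", "time", "score"])
        aov = pg.rm_anova(data=df, dv="score", within="time", subject="pid")
        assert np.isclose(rep.statistic**2, float(aov["F"].iloc[0]), rtol=1e-9)
        assert np.isclose(rep.p_value, float(aov["p_unc"].iloc[0]), rtol=1e-9)

    def test_too_few_participants_rejected(self):
        rows = [("P0", "EG", 1, "NM1", 5), ("P0", "EG", 5, "NM1", 6),
                ("P1", "EG", 1, "NM1", 5), ("P1", "EG", 5, "NM1", 6)]
        with pytest.raises(ValueError, match=">= 3"):
            across_session_test(make_acc(rows))

    def test_improving_eg_detected_and_cg_not(self):
        """p0 = 0.5, delta = 0.1: EG significant and CG not, in >= 80 of
        100 seeds (binomial power oracle via the response simulator)."""
        scheds = build_study(seed=0)
        hits = 0
        for seed in range(100):
            resp = simulate_verbal_responses(scheds, ResponseEffectSpec(0.5, 0.1),
                                             seed=seed)
            reps = across_session_test(accuracy_table(resp))
            hits += reps["EG"].significant and not reps["CG"].significant
        assert hits >= 80

    def test_null_type_one_error(self):
        """delta = 0: the across-session paired t rejects near 0.05."""
        scheds = build_study(seed=0)
        rejections = 0
        n_sim = 500
        for seed in range(n_sim):
            resp = simulate_verbal_responses(scheds, ResponseEffectSpec(0.5, 0.0),
                                             seed=seed)
            rep = across_session_test(accuracy_table(resp))["EG"]
            rejections += rep.p_value <= 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02
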