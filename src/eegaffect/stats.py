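"""Verbal-response statistics: accuracy tables, normality gate, paired tests.

The analysis pipeline mirrors common practice for small paired samples:
a Shapiro-Wilk normality check routes the comparison to either a
parametric paired test or the Wilcoxon matched-pairs signed-ranks test.
Two planned comparisons are provided:

* within-session: first vs. third no-music block (NM1 vs NM3), Wilcoxon;
* across-session: first-session NM1 vs. the post-study NM1 visit, paired
  t-test per group (a two-level repeated-measures ANOVA is the same test,
  F = t^2).

Tests operate on integer correct counts (0-12 per block) so Wilcoxon ranks
stay exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

logger = logging.getLogger(__name__)

ACCURACY_COLUMNS = [
    "participant_id", "group", "session_index", "condition",
    "n_correct", "n_total", "accuracy",
]


@dataclass
class TestReport:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    alpha: float = 0.05
    note: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "alpha": self.alpha,
            "significant": self.significant,
            "note": self.note,
            **self.extras,
        }


def accuracy_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Aggregate raw responses into per-cell correct counts.

    One row per (participant, session, condition) with ``n_correct``,
    ``n_total`` and the accuracy fraction.
    """
    if responses.empty:
        logger.warning("empty response table; returning empty accuracy table")
        return pd.DataFrame(columns=ACCURACY_COLUMNS)
    key = ["participant_id", "session_index", "condition", "stimulus_id"]
    if responses.duplicated(subset=key).any():
        dup = responses.loc[responses.duplicated(subset=key), key].iloc[0]
        raise ValueError(f"duplicate response row for {tuple(dup)}")
    grouped = (
        responses.groupby(
            ["participant_id", "group", "session_index", "condition"], sort=True
        )["correct"]
        .agg(n_correct="sum", n_total="count")
        .reset_index()
    )
    grouped["n_correct"] = grouped["n_correct"].astype(int)
    grouped["accuracy"] = grouped["n_correct"] / grouped["n_total"]
    return grouped[ACCURACY_COLUMNS]


def normality_gate(x, alpha: float = 0.05) -> TestReport:
    """Shapiro-Wilk normality check on paired differences.

    The report's ``extras['route']`` is ``parametric`` when p >= alpha,
    else ``nonparametric`` — the branching used to pick the paired test.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk W undefined for a constant vector")
    w, p = sst.shapiro(x)
    route = "parametric" if p >= alpha else "nonparametric"
    return TestReport(
        test_name="shapiro_wilk", statistic=float(w), p_value=float(p),
        n=len(x), alpha=alpha, extras={"route": route},
    )


def _paired_cells(
    acc: pd.DataFrame, cell_a: tuple, cell_b: tuple
) -> pd.DataFrame:
    """Per-participant n_correct for two (session, condition) cells,
    summing over sessions when a cell's session is None."""
    def pull(cell):
        session, cond = cell
        sel = acc["condition"] == cond
        if session is not None:
            sel &= acc["session_index"] == session
        sub = acc.loc[sel]
        return sub.groupby(["participant_id", "group"])["n_correct"].sum()

    a = pull(cell_a)
    b = pull(cell_b)
    joined = pd.concat({"a": a, "b": b}, axis=1)
    if joined.isna().any().any():
        missing = joined.index[joined.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete pairs for participants {missing}")
    return joined.reset_index()


def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Exact null pmf of the positive-rank sum by dynamic programming.

    ``ranks2`` are the absolute-difference ranks doubled (tied average
    ranks become integers).  Entry ``pmf[s]`` is P(2*W+ = s) under random
    independent signs."""
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_exact(d, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-ranks test with an exact null, zeros
    dropped.

    For n <= 25 (after dropping zeros) the p-value comes from the exact
    sign-flip distribution of the rank sum, computed by dynamic programming
    over tied average ranks, so integer-valued data with ties are handled
    without a normal approximation.  Larger n falls back to the normal
    approximation.  Returns (W, p) with W = min(W+, W-)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n > 25:
        res = sst.wilcoxon(d, alternative=alternative, zero_method="wilcox",
                           method="approx")
        return float(res.statistic), float(res.pvalue)

    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    ranks2 = np.round(2 * ranks).astype(int)
    pmf = _signed_rank_pmf(ranks2)
    s_obs = int(round(2 * w_plus))
    cdf = float(pmf[: s_obs + 1].sum())
    sf = float(pmf[s_obs:].sum())
    if alternative == "greater":
        p = sf
    elif alternative == "less":
        p = cdf
    else:
        p = min(1.0, 2.0 * min(cdf, sf))
    return min(w_plus, w_minus), p


def within_session_test(
    acc: pd.DataFrame,
    cond_a: str = "NM1",
    cond_b: str = "NM3",
    group: str | None = None,
    alpha: float = 0.05,
) -> TestReport:
    """Wilcoxon matched-pairs test of cond_b - cond_a correct counts.

    Counts are summed over sessions per participant so each participant
    contributes one pair.  Zero differences are dropped (classic rule);
    the effective n after dropping is reported.
    """
    sub = acc if group is None else acc.loc[acc["group"] == group]
    a = sub.loc[sub["condition"] == cond_a].set_index(
        ["participant_id", "session_index"])["n_correct"]
    b = sub.loc[sub["condition"] == cond_b].set_index(
        ["participant_id", "session_index"])["n_correct"]
    # pair within each session (the post visit has only one condition),
    # then one summed pair per participant
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").reset_index()
    per_participant = joined.groupby("participant_id")[["a", "b"]].sum()
    d = (per_participant["b"] - per_participant["a"]).to_numpy()
    nz = d[d != 0]
    if len(nz) == 0:
        return TestReport(
            test_name="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            n=len(d), alpha=alpha, note="all paired differences zero",
            extras={"n_effective": 0, "mean_diff": 0.0},
        )
    w, p = wilcoxon_exact(d)
    return TestReport(
        test_name="wilcoxon_signed_rank", statistic=w, p_value=p, n=len(d),
        alpha=alpha,
        extras={"n_effective": len(nz), "mean_diff": float(np.mean(d))},
    )


def across_session_test(
    acc: pd.DataFrame,
    first: tuple = (1, "NM1"),
    last: tuple = (5, "NM1"),
    alpha: float = 0.05,
) -> dict[str, TestReport]:
    """Paired t-test of last-vs-first correct counts, per group.

    With two repeated measures this is the repeated-measures comparison
    (the ANOVA F equals t^2).  Reports mean difference, SD and SE of the
    differences alongside t and p.
    """
    reports: dict[str, TestReport] = {}
    for grp in sorted(acc["group"].unique()):
        pairs = _paired_cells(acc.loc[acc["group"] == grp], first, last)
        d = (pairs["b"] - pairs["a"]).to_numpy(dtype=float)
        n = len(d)
        if n < 3:
            raise ValueError(f"group {grp}: need >= 3 paired participants, got {n}")
        sd = float(np.std(d, ddof=1))
        se = sd / np.sqrt(n)
        if sd == 0:
            t, p = 0.0, 1.0
        else:
            res = sst.ttest_rel(pairs["b"], pairs["a"])
            t, p = float(res.statistic), float(res.pvalue)
        reports[grp] = TestReport(
            test_name="paired_t", statistic=t, p_value=p, n=n, alpha=alpha,
            extras={
                "mean_diff": float(np.mean(d)), "sd_diff": sd, "se_diff": se,
                "f_equivalent": t * t,
            },
        )
    return reports
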