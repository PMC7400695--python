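"""Normality-gated paired comparisons and study-style report tables.

The study protocol: per variable, test the paired before/after
differences; normally distributed variables get a paired t-test,
non-normal ones the Wilcoxon signed-rank test, both two-sided at
alpha = 0.05.  The normality gate here is Shapiro-Wilk on the
differences (the protocol names none; this is a declared choice).

The Wilcoxon path uses the exact null distribution of the positive
rank sum for n <= 25, computed by integer convolution over doubled
midranks — this handles ties exactly, which the textbook tables do
not.  Zero differences are dropped by default (Pratt handling is an
option).  No multiple-testing correction is applied across table
cells, matching the study protocol; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from hemoflow.hemodynamics import HemodynamicSummary

ALPHA = 0.05


class PairingError(ValueError):
    """Before/after samples that cannot be paired."""


@dataclass(frozen=True)
class PairedSample:
    name: str
    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.before, float)
        a = np.asarray(self.after, float)
        if b.shape != a.shape or b.ndim != 1:
            raise PairingError("before/after must be 1-D arrays of equal length")
        if len(b) < 2:
            raise PairingError("need at least 2 pairs")
        object.__setattr__(self, "before", b)
        object.__setattr__(self, "after", a)

    @property
    def differences(self) -> np.ndarray:
        return self.after - self.before


@dataclass(frozen=True)
class TestResult:
    test: str                   # wilcoxon_signed_rank | paired_t | degenerate
    statistic: float
    p_value: float
    significant: bool
    normality_p: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_exact(diffs: Sequence[float], zero_method: str = "wilcox"
                   ) -> tuple[float, float]:
    """Two-sided exact Wilcoxon signed-rank test.

    Returns (W, p) with W = min(W+, W-).  The null distribution of the
    positive rank sum is built by convolution over all 2^m sign
    assignments using doubled (hence integer) midranks, so tied
    magnitudes are exact.  ``zero_method``: 'wilcox' drops zero
    differences, 'pratt' ranks them but excludes them from the sums.
    """
    d = np.asarray(diffs, float)
    if zero_method == "wilcox":
        d = d[d != 0.0]
        ranks = sps.rankdata(np.abs(d)) if len(d) else np.array([])
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[d != 0.0]
        d = d[d != 0.0]
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    m = len(d)
    if m == 0:
        return 0.0, 1.0
    if m > 25:
        raise ValueError("exact path supports at most 25 nonzero differences")
    r2 = np.rint(2.0 * ranks).astype(int)       # doubled midranks are integers
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r].copy() if r > 0 else counts.copy()
    counts /= 2.0 ** m
    w_plus2 = int(np.rint(2.0 * ranks[d > 0].sum()))
    cdf = np.cumsum(counts)
    p_le = cdf[w_plus2]
    p_ge = 1.0 - (cdf[w_plus2 - 1] if w_plus2 > 0 else 0.0)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    w_plus = 0.5 * w_plus2
    w = min(w_plus, ranks.sum() - w_plus)
    return float(w), float(p)


def choose_and_run_test(sample: PairedSample, alpha: float = ALPHA,
                        zero_method: str = "wilcox") -> TestResult:
    """Shapiro-Wilk-gated paired test at the given significance level.

    All-zero differences yield a degenerate (p = 1, flagged) result.
    Constant nonzero differences cannot be tested for normality and are
    routed to the rank test.
    """
    d = sample.differences
    if np.all(d == 0.0):
        return TestResult("degenerate", 0.0, 1.0, False, 1.0, degenerate=True)
    if np.ptp(d) == 0.0:
        normality_p = 0.0
    elif len(d) < 3:
        normality_p = 1.0   # too few pairs to assess normality; use the t-test
    else:
        normality_p = float(sps.shapiro(d).pvalue)
    if normality_p < alpha:
        w, p = wilcoxon_exact(d, zero_method=zero_method)
        return TestResult("wilcoxon_signed_rank", w, p, p < alpha, normality_p)
    t = sps.ttest_rel(sample.after, sample.before)
    return TestResult("paired_t", float(t.statistic), float(t.pvalue),
                      float(t.pvalue) < alpha, normality_p)


STATISTICS = ("minimal", "time_averaged", "maximal")
TABLE_REGIONS = ("whole", "ica")


def build_comparison_tables(summaries: Iterable[HemodynamicSummary],
                            regions: Sequence[str] = TABLE_REGIONS,
                            alpha: float = ALPHA) -> pd.DataFrame:
    """Study-table-style paired report from per-participant summaries.

    One row per (region, side, quantity, statistic): mean +/- SD of each
    condition across participants, the gated test's p-value and a
    significance star.  Left and right sides are separate samples,
    never pooled.  Raises :class:`PairingError` if any participant-side
    lacks one condition.
    """
    df = pd.DataFrame([{
        "region": s.region, "quantity": s.quantity, "side": s.side,
        "condition": s.condition, "participant_id": s.participant_id,
        "minimal": s.minimal, "time_averaged": s.time_averaged,
        "maximal": s.maximal} for s in summaries])
    if df.empty:
        raise PairingError("no summaries given")
    rows = []
    for region in regions:
        for side in sorted(df["side"].unique()):
            for quantity in ("shear_rate", "wss"):
                sel = df[(df.region == region) & (df.side == side)
                         & (df.quantity == quantity)]
                if sel.empty:
                    continue
                piv = {}
                for cond in ("before", "after"):
                    sub = sel[sel.condition == cond].set_index("participant_id")
                    piv[cond] = sub
                missing = set(piv["before"].index) ^ set(piv["after"].index)
                if missing:
                    raise PairingError(f"unpaired participants {sorted(missing)} "
                                       f"for {region}/{side}/{quantity}")
                pids = sorted(piv["before"].index)
                for stat in STATISTICS:
                    b = piv["before"].loc[pids, stat].to_numpy()
                    a = piv["after"].loc[pids, stat].to_numpy()
                    res = choose_and_run_test(
                        PairedSample(f"{region}/{side}/{quantity}/{stat}", b, a),
                        alpha=alpha)
                    rows.append({
                        "region": region, "side": side, "quantity": quantity,
                        "statistic": stat, "n": len(b),
                        "before_mean": b.mean(),
                        "before_sd": b.std(ddof=1) if len(b) > 1 else 0.0,
                        "after_mean": a.mean(),
                        "after_sd": a.std(ddof=1) if len(a) > 1 else 0.0,
                        "test": res.test, "p_value": res.p_value,
                        "significant": res.significant,
                        "degenerate": res.degenerate,
                    })
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering with the '* indicates p < 0.05' convention."""
    lines = ["| Region | Side | Quantity | Statistic | Before | After | p |",
             "|---|---|---|---|---|---|---|"]
    for _, r in table.iterrows():
        star = " *" if r.significant else ""
        lines.append(
            f"| {r.region} | {r.side} | {r.quantity} | {r.statistic} "
            f"| {r.before_mean:.3g} ± {r.before_sd:.2g} "
            f"| {r.after_mean:.3g} ± {r.after_sd:.2g} "
            f"| {r.p_value:.3f}{star} |")
    lines.append("")
    lines.append("\\* indicates p < 0.05.")
    return "\n".join(lines)
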