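"""Cohort descriptive statistics and hypothesis tests.

Summary blocks follow the layout mean / SD / 95% CI on the mean / min / max /
fold change (max/min); the CI uses the t distribution with n-1 df.  Paired
comparisons of the SOWS time profile test each post-dose time against the
subject's own pre-dose score, unadjusted by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "summarize",
    "pearson_corr",
    "paired_compare",
    "anova_oneway",
    "sows_time_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    ci95_lower: float
    ci95_upper: float
    min: float
    max: float
    fold_change: float  # max/min; NaN when min <= 0
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci95_lower": self.ci95_lower,
            "ci95_upper": self.ci95_upper,
            "min": self.min,
            "max": self.max,
            "fold_change": self.fold_change,
            "n": self.n,
        }


def summarize(values) -> SummaryStats:
    """Mean, SD (n-1), t-based 95% CI on the mean, min, max, fold = max/min."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    # clamp against 1-ulp summation artifacts: the mean lies in [min, max]
    mean = float(np.clip(np.mean(x), np.min(x), np.max(x)))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    else:
        half = 0.0
    mn, mx = float(np.min(x)), float(np.max(x))
    fold = mx / mn if mn > 0 else float("nan")
    return SummaryStats(mean, sd, mean - half, mean + half, mn, mx, fold, n)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_compare(baseline, post, method: str = "t") -> float:
    """Two-sided paired test p-value; method 't' or 'wilcoxon'.

    All-zero differences return p = 1 by convention (no evidence of change).
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if baseline.size != post.size:
        raise ValueError("paired vectors must have equal lengths")
    if baseline.size < 2:
        raise ValueError("need at least 2 pairs")
    d = post - baseline
    if np.all(d == 0):
        return 1.0
    if method == "t":
        p = sps.ttest_rel(post, baseline).pvalue
    elif method == "wilcoxon":
        p = sps.wilcoxon(post, baseline, zero_method="wilcox", mode="auto").pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p)


def anova_oneway(groups) -> float:
    """One-way ANOVA F-test p-value across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 1.0  # identical groups: F = 0
    return float(sps.f_oneway(*groups).pvalue)


def sows_time_profile(
    sows: pd.DataFrame, method: str = "t", adjust: str | None = None
) -> pd.DataFrame:
    """Per-time SOWS summary with paired tests against each subject's pre-dose score.

    Parameters
    ----------
    sows : DataFrame with columns subject, time, sows; every subject must have
        a pre-dose (time == 0) record, others are dropped with a warning.
    method : 't' (paired t-test) or 'wilcoxon'.
    adjust : None (unadjusted, default) or 'holm' for step-down adjustment of
        the post-dose p-values.

    Returns a frame indexed by time with n, mean, ci95_lower/upper and the
    p-value versus pre-dose (NaN on the pre-dose row itself).
    """
    required = {"subject", "time", "sows"}
    if not required.issubset(sows.columns):
        raise ValueError(f"sows frame must have columns {sorted(required)}")
    base = sows[sows["time"] == 0].set_index("subject")["sows"]
    missing = set(sows["subject"]) - set(base.index)
    if missing:
        logger.warning("excluding %d subjects without a pre-dose record", len(missing))
        sows = sows[~sows["subject"].isin(missing)]
    if base.empty:
        raise ValueError("no pre-dose (time = 0) records")
    times = sorted(sows["time"].unique())
    post_times = [t for t in times if t > 0]
    if not post_times:
        raise ValueError("no post-dose records")

    rows = []
    for t in times:
        sub = sows[sows["time"] == t].set_index("subject")["sows"]
        s = summarize(sub.to_numpy())
        if t == 0:
            p = float("nan")
        else:
            common = sub.index.intersection(base.index)
            p = paired_compare(base.loc[common], sub.loc[common], method=method)
        rows.append(
            {"time": t, "n": s.n, "mean": s.mean,
             "ci95_lower": s.ci95_lower, "ci95_upper": s.ci95_upper, "p_vs_predose": p}
        )
    out = pd.DataFrame(rows).set_index("time")
    if adjust == "holm":
        mask = out.index > 0
        p = out.loc[mask, "p_vs_predose"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        m = p.size
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[mask, "p_vs_predose"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
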