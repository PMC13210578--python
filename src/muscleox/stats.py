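"""Paired pre/post inference, effect sizes, correlations, outlier sensitivity.

Pre- vs post-training changes are tested with classical paired t-tests and
summarized with Cohen's d.  The default d uses the summary-statistics form

    d = (m_post - m_pre) / sqrt((sd_pre^2 + sd_post^2) / 2)

(the root-mean of the two condition variances); the change-score variant
``mean_diff / sd_diff`` is available as ``d_variant="diff"``.  Relationships
between per-subject changes are assessed with Pearson correlations, with an
explicit sensitivity rerun that reports both the full-sample and the
outlier-excluded correlation rather than silently dropping data.  No
multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedResult",
    "CorrResult",
    "paired_t",
    "cohens_d_summary",
    "pearson_corr",
    "sensitivity_rerun",
    "cohort_report",
]


@dataclass
class PairedResult:
    """Paired t-test summary for one metric."""

    n: int
    mean_pre: float
    mean_post: float
    mean_diff: float
    t_stat: float
    df: int
    p_two_sided: float
    cohens_d: float
    degenerate: bool = False


@dataclass
class CorrResult:
    """Pearson correlation summary."""

    n: int
    r: float
    p_two_sided: float
    excluded_ids: list = field(default_factory=list)


def cohens_d_summary(m_pre: float, sd_pre: float,
                     m_post: float, sd_post: float) -> float:
    """Cohen's d from condition summary statistics.

    ``(m_post - m_pre) / sqrt((sd_pre^2 + sd_post^2) / 2)`` — the mean
    difference scaled by the root-mean of the two condition variances.
    """
    if sd_pre <= 0 or sd_post <= 0:
        raise ValueError("standard deviations must be > 0")
    return (m_post - m_pre) / math.sqrt((sd_pre ** 2 + sd_post ** 2) / 2.0)


def paired_t(pre, post, d_variant: str = "pooled") -> PairedResult:
    """Classical paired t-test of ``post - pre`` with Cohen's d attached.

    ``d_variant="pooled"`` computes d from the two condition means/SDs via
    :func:`cohens_d_summary`; ``"diff"`` uses ``mean_diff / sd_diff``.
    Zero-variance differences are handled explicitly: identical vectors give
    ``t=0, p=1``; a constant nonzero shift gives ``p=0`` with the
    ``degenerate`` flag set.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D vectors")
    if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
        raise ValueError("missing pairs must be removed before testing")
    n = pre.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    diff = post - pre
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    df = n - 1
    m_pre, m_post = float(pre.mean()), float(post.mean())
    sd_pre, sd_post = float(pre.std(ddof=1)), float(post.std(ddof=1))

    degenerate = sd_diff == 0.0
    if degenerate:
        t_stat = 0.0 if mean_diff == 0.0 else math.copysign(math.inf, mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        t_stat = mean_diff / (sd_diff / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t_stat), df))

    if d_variant == "pooled":
        d = (cohens_d_summary(m_pre, sd_pre, m_post, sd_post)
             if sd_pre > 0 and sd_post > 0 else float("nan"))
    elif d_variant == "diff":
        d = mean_diff / sd_diff if sd_diff > 0 else float("nan")
    else:
        raise ValueError(f"unknown d_variant {d_variant!r}")

    return PairedResult(n=n, mean_pre=m_pre, mean_post=m_post,
                        mean_diff=mean_diff, t_stat=float(t_stat), df=df,
                        p_two_sided=p, cohens_d=float(d), degenerate=degenerate)


def pearson_corr(x, y) -> CorrResult:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrResult(n=n, r=float(res.statistic), p_two_sided=float(res.pvalue))


def sensitivity_rerun(x, y, x_threshold: float, ids=None
                      ) -> tuple[CorrResult, CorrResult]:
    """Correlation with and without subjects whose ``x`` exceeds a threshold.

    Returns ``(full, reduced)``; the reduced result records the excluded ids
    so nothing is dropped silently.  Raises if fewer than 3 subjects remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ids is None:
        ids = list(range(x.size))
    keep = x < x_threshold
    full = pearson_corr(x, y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 subjects remain after exclusion")
    excluded = [i for i, k in zip(ids, keep) if not k]
    if excluded:
        reduced = pearson_corr(x[keep], y[keep])
        reduced.excluded_ids = excluded
    else:
        reduced = CorrResult(n=full.n, r=full.r, p_two_sided=full.p_two_sided)
    return full, reduced


def cohort_report(table: pd.DataFrame, metrics: list[str] | None = None,
                  d_variant: str = "pooled") -> pd.DataFrame:
    """One paired-test row per metric from a tidy pre/post table.

    ``table`` must have columns ``subject_id, metric, pre, post``.  Pairs with
    a missing pre or post value are deleted listwise per metric and the
    retained ``n`` reported; metrics left with fewer than 2 pairs are kept as
    rows with NaN statistics and an explanatory note.  Rows follow the
    declared ``metrics`` order (default: order of first appearance).
    """
    required = {"subject_id", "metric", "pre", "post"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if metrics is None:
        metrics = list(pd.unique(table["metric"]))
    if table.empty or not metrics:
        raise ValueError("no data to report")
    rows = []
    for name in metrics:
        sub = table[table["metric"] == name].dropna(subset=["pre", "post"])
        n_dropped = int((table["metric"] == name).sum() - len(sub))
        row = {"metric": name, "n": len(sub), "n_dropped": n_dropped}
        if len(sub) < 2:
            row |= {k: float("nan") for k in
                    ("mean_pre", "mean_post", "mean_diff", "t_stat", "df",
                     "p_two_sided", "cohens_d")}
            row["note"] = "fewer than 2 complete pairs"
        else:
            res = paired_t(sub["pre"].to_numpy(), sub["post"].to_numpy(),
                           d_variant=d_variant)
            row |= {"mean_pre": res.mean_pre, "mean_post": res.mean_post,
                    "mean_diff": res.mean_diff, "t_stat": res.t_stat,
                    "df": res.df, "p_two_sided": res.p_two_sided,
                    "cohens_d": res.cohens_d,
                    "note": "degenerate" if res.degenerate else ""}
        rows.append(row)
    return pd.DataFrame(rows)
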