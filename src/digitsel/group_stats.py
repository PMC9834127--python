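"""Paired group comparisons with Bonferroni correction.

The study design pairs the two contrasts within each subject, so
between-contrast differences in overlap or selectivity metrics are
assessed with classical paired t-tests on the per-subject differences,
two-sided, with Bonferroni adjustment over the family of comparisons
(three digit pairs per region by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedTResult", "GroupStatsResult", "paired_t", "bonferroni", "compare_metrics"]


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int
    #: True when every difference is identical and nonzero: t is infinite
    #: and p is reported as 0 with this flag raised
    zero_variance: bool = False


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t-test of ``a`` vs ``b`` across subjects.

    Degenerate cases are flagged rather than erroring: all-zero
    differences give t = 0, p = 1; zero-variance nonzero differences give
    an infinite t with p reported as 0 and ``zero_variance`` set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("at least two pairs are required (df = n - 1 >= 1)")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("missing or non-finite entries are not allowed")

    d = a - b
    n = d.size
    df = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, mean_diff=0.0, n=n)
        return PairedTResult(
            t=float(np.sign(mean)) * float("inf"),
            df=df,
            p=0.0,
            mean_diff=mean,
            n=n,
            zero_variance=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTResult(t=float(t), df=df, p=min(p, 1.0), mean_diff=mean, n=n)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m * p), order preserved.

    ``m`` defaults to the number of p-values; a larger family size is
    allowed (comparisons counted in the family but not listed here).
    """
    ps = [float(p) for p in p_values]
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError("family size m must be at least the number of p-values")
    return [min(1.0, m * p) for p in ps]


@dataclass
class GroupStatsResult:
    """Tidy per-comparison results: one row per (metric, region, level)."""

    frame: pd.DataFrame


def compare_metrics(
    subject_values: pd.DataFrame,
    *,
    contrast_a: str = "VASO-CBV",
    contrast_b: str = "BOLD",
    family: int | None = None,
) -> GroupStatsResult:
    """Paired contrast-A-vs-B tests for every (metric, region, level).

    ``subject_values`` is tidy with columns {subject, region, contrast,
    metric, level, value}; ``level`` is the digit or digit-pair the
    metric refers to (empty string for ROI-wide metrics such as OS).
    The Bonferroni family is, per (region, metric), the number of levels
    tested there, unless ``family`` overrides it.
    """
    required = {"subject", "region", "contrast", "metric", "level", "value"}
    missing = required - set(subject_values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    rows = []
    for (region, metric), grp in subject_values.groupby(["region", "metric"], sort=True):
        level_rows = []
        for level, sub in grp.groupby("level", sort=True):
            piv = sub.pivot_table(
                index="subject", columns="contrast", values="value", aggfunc="mean"
            )
            if contrast_a not in piv.columns or contrast_b not in piv.columns:
                continue
            piv = piv.dropna(subset=[contrast_a, contrast_b])
            res = paired_t(piv[contrast_a].to_numpy(), piv[contrast_b].to_numpy())
            level_rows.append((level, res))
        m = family if family is not None else max(len(level_rows), 1)
        adj = bonferroni([r.p for _, r in level_rows], m=m)
        for (level, res), p_adj in zip(level_rows, adj):
            rows.append(
                {
                    "metric": metric,
                    "region": region,
                    "level": level,
                    "pairing": f"{contrast_a} vs {contrast_b}",
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "p_adjusted": p_adj,
                    "family_m": m,
                    "zero_variance": res.zero_variance,
                }
            )
    return GroupStatsResult(frame=pd.DataFrame(rows))
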