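"""Group-level statistics for dyad cohorts.

Covers fear-buffering / equalization metrics, the balanced (alternating)
partner assignment used before correlating partners' freezing levels,
top/bottom-40% splits by synchrony, and synchrony-behavior correlations.
Hypothesis tests are delegated to scipy; the normality-gated choice between
parametric and nonparametric tests (Shapiro–Wilk, then t-test vs
Wilcoxon/Mann–Whitney) is reproduced as a documented decision rule.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "freezing_level",
    "equalization_metrics",
    "balanced_partner_assignment",
    "partner_correlation",
    "split_top_bottom",
    "synchrony_behavior_correlation",
    "compare_groups",
]

logger = logging.getLogger(__name__)


def freezing_level(trace) -> float:
    """Percent of window frames spent freezing (0-100)."""
    from .ethogram import BinaryTrace

    v = trace.values if isinstance(trace, BinaryTrace) else np.asarray(trace)
    return float(100.0 * np.mean(v))


def equalization_metrics(
    pair_traces: dict, single_traces: dict
) -> tuple[pd.DataFrame, dict]:
    """Per-dyad absolute freezing differences in PAIR vs SINGLE configuration.

    Both inputs map ``dyad_id -> (trace_a, trace_b)``; every dyad must appear
    in both configurations.  Returns the per-dyad table and a paired
    Wilcoxon signed-rank comparison (PAIR vs SINGLE differences).
    """
    missing = set(pair_traces) ^ set(single_traces)
    if missing:
        raise KeyError(
            f"dyads missing one configuration: {sorted(missing)}"
        )
    rows = []
    for dyad_id in sorted(pair_traces):
        pa, pb = pair_traces[dyad_id]
        sa, sb = single_traces[dyad_id]
        rows.append(
            (
                dyad_id,
                abs(freezing_level(pa) - freezing_level(pb)),
                abs(freezing_level(sa) - freezing_level(sb)),
            )
        )
    df = pd.DataFrame(rows, columns=["dyad_id", "diff_pair", "diff_single"])
    d = df["diff_pair"] - df["diff_single"]
    if np.allclose(d, 0):
        test = {"test": "wilcoxon", "statistic": math.nan, "p_two": 1.0}
    else:
        res = sps.wilcoxon(df["diff_pair"], df["diff_single"])
        test = {"test": "wilcoxon", "statistic": float(res.statistic), "p_two": float(res.pvalue)}
    return df, test


def balanced_partner_assignment(
    group: pd.DataFrame, sex_composition: str = "same"
) -> pd.DataFrame:
    """Assign dyad members to the "animal 1" / "animal 2" columns.

    Same-sex groups: dyads are sorted by mean freezing (descending) and the
    within-dyad high freezer alternates between the two columns, which
    balances both columns by freezing mean and by high/low-freezer counts
    (difference at most one).  Opposite-sex groups ("MF"): male to column 1,
    female to column 2.

    ``group`` needs columns ``dyad_id, subject_a, subject_b, freeze_a,
    freeze_b`` (+ ``sex_a, sex_b`` for MF).
    """
    required = ["dyad_id", "subject_a", "subject_b", "freeze_a", "freeze_b"]
    missing = [c for c in required if c not in group.columns]
    if missing:
        raise ValueError(f"assignment input missing columns: {missing}")

    rows = []
    if sex_composition == "MF":
        for c in ("sex_a", "sex_b"):
            if c not in group.columns:
                raise ValueError("MF assignment needs sex_a/sex_b columns")
        for rec in group.itertuples(index=False):
            if rec.sex_a == "M":
                male, female = ("a", "b")
            else:
                male, female = ("b", "a")
            rows.append(
                (
                    rec.dyad_id,
                    getattr(rec, f"subject_{male}"),
                    getattr(rec, f"freeze_{male}"),
                    getattr(rec, f"subject_{female}"),
                    getattr(rec, f"freeze_{female}"),
                    None,
                )
            )
    else:
        g = group.copy()
        g["mean_freeze"] = (g["freeze_a"] + g["freeze_b"]) / 2.0
        g = g.sort_values(["mean_freeze", "dyad_id"], ascending=[False, True])
        for rank, rec in enumerate(g.itertuples(index=False)):
            if rec.freeze_a == rec.freeze_b:
                logger.info(
                    "dyad %s: within-dyad freezing tie, high/low resolved by "
                    "subject id order",
                    rec.dyad_id,
                )
                high, low = sorted(["a", "b"], key=lambda m: getattr(rec, f"subject_{m}"))
            elif rec.freeze_a > rec.freeze_b:
                high, low = "a", "b"
            else:
                high, low = "b", "a"
            first, second = (high, low) if rank % 2 == 0 else (low, high)
            rows.append(
                (
                    rec.dyad_id,
                    getattr(rec, f"subject_{first}"),
                    getattr(rec, f"freeze_{first}"),
                    getattr(rec, f"subject_{second}"),
                    getattr(rec, f"freeze_{second}"),
                    first == high,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dyad_id",
            "animal1_id",
            "animal1_freeze",
            "animal2_id",
            "animal2_freeze",
            "animal1_is_high",
        ],
    )


def partner_correlation(
    assignment: pd.DataFrame, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between the two assignment columns' freezing levels."""
    if len(assignment) < 3:
        raise ValueError("partner correlation needs at least 3 dyads")
    x = assignment["animal1_freeze"].to_numpy(float)
    y = assignment["animal2_freeze"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def split_top_bottom(
    group: pd.DataFrame, fraction: float = 0.40, key: str = "corrected"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top and bottom ``fraction`` of dyads ranked by ``key``.

    Each subset holds ``floor(fraction * N)`` dyads; the middle is excluded.
    Ties at a subset boundary are broken by dyad id and logged.
    """
    n = len(group)
    if n < 5:
        raise ValueError("split needs at least 5 dyads")
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValueError(f"fraction {fraction} leaves an empty subset for N={n}")
    ordered = group.sort_values([key, "dyad_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    vals = ordered[key].to_numpy()
    for boundary in (k - 1, n - k):
        inside = vals[boundary]
        neighbor = vals[boundary - 1] if boundary == n - k else vals[boundary + 1]
        if inside == neighbor:
            logger.warning(
                "tie at the %s-subset boundary (%s=%r): broken by dyad id",
                "top" if boundary == k - 1 else "bottom",
                key,
                inside,
            )
    return ordered.iloc[:k].copy(), ordered.iloc[n - k :].copy()


def synchrony_behavior_correlation(
    group: pd.DataFrame,
    behavior: str,
    synchrony_col: str = "corrected",
    method: str = "pearson",
) -> tuple[float, float]:
    """Pearson (or Spearman) correlation between synchrony and a count."""
    sub = group[[synchrony_col, behavior]].dropna()
    if len(sub) < 3:
        raise ValueError("correlation needs at least 3 dyads with both values")
    x = sub[synchrony_col].to_numpy(float)
    y = sub[behavior].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def compare_groups(x, y=None, paired: bool = False, alpha: float = 0.05) -> dict:
    """Normality-gated two-group (or one-sample) comparison.

    Shapiro–Wilk decides between the parametric t-test and the
    Wilcoxon signed-rank / Mann–Whitney alternatives.  Both two- and
    one-tailed p-values are reported (the one-tailed value is for the
    direction of the observed effect).
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        normal = bool(sps.shapiro(x).pvalue > alpha) if len(x) >= 3 else True
        if normal:
            res = sps.ttest_1samp(x, 0.0)
            name = "one-sample t"
        else:
            res = sps.wilcoxon(x)
            name = "wilcoxon signed-rank"
    else:
        y = np.asarray(y, dtype=float)
        if paired:
            d = x - y
            normal = bool(sps.shapiro(d).pvalue > alpha) if len(d) >= 3 else True
            if normal:
                res = sps.ttest_rel(x, y)
                name = "paired t"
            else:
                res = sps.wilcoxon(x, y)
                name = "wilcoxon signed-rank"
        else:
            normal = (
                bool(sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha)
                if min(len(x), len(y)) >= 3
                else True
            )
            if normal:
                res = sps.ttest_ind(x, y)
                name = "two-sample t"
            else:
                res = sps.mannwhitneyu(x, y)
                name = "mann-whitney"
    p_two = float(res.pvalue)
    return {
        "test": name,
        "normal": normal,
        "statistic": float(res.statistic),
        "p_two": p_two,
        "p_one": p_two / 2.0,
    }
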