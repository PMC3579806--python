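"""FSH assay calibration and group statistics.

Concentrations are normalized to mIU per mg total protein, then groups are
summarized (mean, SD) and contrasted against a baseline: stimulation
contrasts as treatment/baseline fold ratios, inhibition/stimulation
transfection contrasts as percent change relative to the baseline group,
both rounded to one decimal in the reported columns with full precision
retained. Two-group designs use a pooled-variance Student's t-test
(Welch by flag); multi-group designs use one-way ANOVA followed by
Tukey's HSD pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_ALPHA = 0.05
ASSAY_COLUMNS = ["well_id", "group", "fsh", "total_protein"]


def normalize_by_protein(samples: pd.DataFrame) -> pd.DataFrame:
    """Express FSH per mg total protein (adds ``fsh_per_mg``)."""
    missing = [c for c in ASSAY_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    protein = samples["total_protein"].to_numpy(dtype=float)
    bad = samples.loc[protein <= 0, "well_id"].tolist()
    if bad:
        raise ValueError(f"non-positive total protein in well(s): {bad}")
    out = samples.copy()
    out["fsh_per_mg"] = samples["fsh"].to_numpy(dtype=float) / protein
    return out


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    # (other_group, fold_ratio, percent_change, p_value)
    comparisons: list[tuple[str, float, float, float]] = field(default_factory=list)


def _group_values(samples: pd.DataFrame, group: str) -> np.ndarray:
    return samples.loc[samples["group"] == group, "fsh_per_mg"].to_numpy(dtype=float)


def two_group_p(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value; NaN when variance is degenerate
    (all values identical in both groups)."""
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return math.nan
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def summarize_groups(
    samples: pd.DataFrame,
    baseline: str,
    welch: bool = False,
) -> list[GroupSummary]:
    """Per-group mean/SD plus contrasts of every non-baseline group against
    the baseline: fold = mean(group)/mean(baseline) and
    percent = 100*(mean(group)-mean(baseline))/mean(baseline)."""
    if "fsh_per_mg" not in samples.columns:
        samples = normalize_by_protein(samples)
    groups = list(dict.fromkeys(samples["group"]))
    if baseline not in groups:
        raise ValueError(f"baseline group {baseline!r} not present in the assay table")
    if len(groups) < 2:
        raise ValueError("group comparison needs at least two groups")
    base_vals = _group_values(samples, baseline)
    summaries = []
    for group in groups:
        vals = _group_values(samples, group)
        ddof = 1 if len(vals) >= 2 else 0
        summary = GroupSummary(
            group=group,
            n=len(vals),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=ddof)),
        )
        if group != baseline:
            fold = float(vals.mean() / base_vals.mean())
            percent = 100.0 * (vals.mean() - base_vals.mean()) / base_vals.mean()
            summary.comparisons.append(
                (baseline, fold, float(percent), two_group_p(vals, base_vals, welch))
            )
        summaries.append(summary)
    return summaries


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flat table of group summaries and their baseline contrasts, with
    one-decimal reporting columns alongside full precision."""
    rows = []
    for s in summaries:
        if not s.comparisons:
            rows.append(
                {
                    "group": s.group, "n": s.n, "mean": s.mean, "sd": s.sd,
                    "baseline": "", "fold_ratio": math.nan, "percent_change": math.nan,
                    "fold_ratio_1dp": math.nan, "percent_change_1dp": math.nan,
                    "p_value": math.nan, "significant": False,
                }
            )
        for other, fold, percent, p in s.comparisons:
            rows.append(
                {
                    "group": s.group, "n": s.n, "mean": s.mean, "sd": s.sd,
                    "baseline": other, "fold_ratio": fold, "percent_change": percent,
                    "fold_ratio_1dp": round(fold, 1),
                    "percent_change_1dp": round(percent, 1),
                    "p_value": p,
                    "significant": bool(p < SIGNIFICANCE_ALPHA)
                    if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    samples: pd.DataFrame,
    design: str = "two-group",
    welch: bool = False,
) -> dict:
    """Hypothesis tests for the assay design.

    two-group: two-sided t-test (pooled variance unless ``welch``).
    multi-group: one-way ANOVA plus Tukey HSD pairwise p-values.
    Significance is flagged at p < 0.05; degenerate variance (all values
    identical in every group) reports NaN p-values with a flag.
    """
    if "fsh_per_mg" not in samples.columns:
        samples = normalize_by_protein(samples)
    groups = list(dict.fromkeys(samples["group"]))
    if len(groups) < 2:
        raise ValueError("group comparison needs at least two groups")
    values = [_group_values(samples, g) for g in groups]
    for g, v in zip(groups, values):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if design == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group design requires exactly two groups")
        p = two_group_p(values[0], values[1], welch)
        return {
            "design": "two-group",
            "groups": groups,
            "p_value": p,
            "significant": bool(p < SIGNIFICANCE_ALPHA) if not math.isnan(p) else False,
            "degenerate": math.isnan(p),
        }
    if design != "multi-group":
        raise ValueError(f"unknown design {design!r}")
    if all(np.ptp(v) == 0 for v in values):
        pairs = [
            {"group_a": a, "group_b": b, "p_value": math.nan, "significant": False}
            for i, a in enumerate(groups) for b in groups[i + 1 :]
        ]
        return {
            "design": "multi-group", "groups": groups, "anova_p": math.nan,
            "pairwise": pairs, "degenerate": True,
        }
    anova = stats.f_oneway(*values)
    tukey = stats.tukey_hsd(*values)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(tukey.pvalue[i, j])
            pairs.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "p_value": p,
                    "significant": bool(p < SIGNIFICANCE_ALPHA),
                }
            )
    return {
        "design": "multi-group",
        "groups": groups,
        "anova_p": float(anova.pvalue),
        "pairwise": pairs,
        "degenerate": False,
    }
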