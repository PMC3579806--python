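"""Relative quantification by the 2^-ddCt method and array/qPCR concordance.

Replicate Ct values are averaged per group and gene (Livak procedure);
dCt = mean Ct(target) - mean Ct(reference) within each group,
ddCt = dCt(treatment) - dCt(control), and the relative quantity is
RQ = 2^-ddCt with an amplification efficiency fixed at 2. A two-sided
two-sample t-test on per-replicate dCt values flags significance at
p < 0.05.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_ALPHA = 0.05
CT_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]


def _group_cts(records: pd.DataFrame, gene: str, group: str) -> np.ndarray:
    sel = records[(records["gene"] == gene) & (records["group"] == group)]
    return sel.sort_values("replicate")["ct"].to_numpy(dtype=float)


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    treatment_group: str = "treatment",
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-gene ddCt quantification against ``reference_gene``.

    Returns columns ``gene, delta_ct_treatment, delta_ct_control,
    delta_delta_ct, rq, direction, p_value``. With a single replicate the
    RQ is still computed but the p-value is NaN.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.all(np.isfinite(records["ct"].to_numpy(dtype=float))):
        raise ValueError("non-finite Ct value in input")
    rows = []
    for group in (treatment_group, control_group):
        if len(_group_cts(records, reference_gene, group)) == 0:
            raise ValueError(
                f"reference gene {reference_gene!r} missing from group {group!r}"
            )
    ref_t = _group_cts(records, reference_gene, treatment_group)
    ref_c = _group_cts(records, reference_gene, control_group)
    for gene in [g for g in records["gene"].unique() if g != reference_gene]:
        tgt_t = _group_cts(records, gene, treatment_group)
        tgt_c = _group_cts(records, gene, control_group)
        if len(tgt_t) == 0 or len(tgt_c) == 0:
            continue
        dct_t = float(tgt_t.mean() - ref_t.mean())
        dct_c = float(tgt_c.mean() - ref_c.mean())
        ddct = dct_t - dct_c
        rq = float(2.0 ** (-ddct))
        # per-replicate dCt values (replicate i target minus replicate i reference)
        p = math.nan
        if len(tgt_t) >= 2 and len(tgt_c) >= 2:
            n_t = min(len(tgt_t), len(ref_t))
            n_c = min(len(tgt_c), len(ref_c))
            d_t = tgt_t[:n_t] - ref_t[:n_t]
            d_c = tgt_c[:n_c] - ref_c[:n_c]
            if np.ptp(d_t) > 0 or np.ptp(d_c) > 0:
                p = float(stats.ttest_ind(d_t, d_c, equal_var=True).pvalue)
        if p < SIGNIFICANCE_ALPHA:
            direction = "up" if ddct < 0 else "down"
        else:
            direction = "unchanged"
        rows.append(
            {
                "gene": gene,
                "delta_ct_treatment": dct_t,
                "delta_ct_control": dct_c,
                "delta_delta_ct": ddct,
                "rq": rq,
                "direction": direction,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "delta_ct_treatment", "delta_ct_control", "delta_delta_ct",
            "rq", "direction", "p_value",
        ],
    )


def concordance(array_calls: pd.DataFrame, qpcr: pd.DataFrame) -> dict:
    """Array vs qPCR agreement over shared miRNAs.

    Pearson r between log2 array fold change and log2 RQ (needs >= 3 shared
    miRNAs, otherwise omitted), plus per-miRNA direction agreement counting
    significant-and-concordant, discordant, and non-significant calls.
    """
    arr = array_calls.set_index("miRNA")
    q = qpcr.set_index("gene")
    shared = sorted(set(arr.index) & set(q.index))
    per_mirna = []
    n_concordant = n_discordant = n_nonsig = 0
    for name in shared:
        a_dir = arr.loc[name, "direction"]
        q_dir = q.loc[name, "direction"]
        if q_dir == "unchanged":
            status = "non-significant"
            n_nonsig += 1
        elif q_dir == a_dir:
            status = "significant-concordant"
            n_concordant += 1
        else:
            status = "discordant"
            n_discordant += 1
        per_mirna.append(
            {
                "miRNA": name,
                "array_direction": a_dir,
                "qpcr_direction": q_dir,
                "array_log2_fold": float(np.log2(arr.loc[name, "fold_change"])),
                "qpcr_log2_rq": float(np.log2(q.loc[name, "rq"])),
                "status": status,
            }
        )
    report: dict = {
        "n_shared": len(shared),
        "n_significant_concordant": n_concordant,
        "n_discordant": n_discordant,
        "n_non_significant": n_nonsig,
        "per_mirna": per_mirna,
    }
    if len(shared) >= 3:
        r, p = stats.pearsonr(
            [row["array_log2_fold"] for row in per_mirna],
            [row["qpcr_log2_rq"] for row in per_mirna],
        )
        report["pearson_r"] = float(r)
        report["pearson_p"] = float(p)
    else:
        report["pearson_r"] = None
        report["pearson_p"] = None
    return report
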