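"""Two-color array probe QC, LOWESS normalization, fold-change calling and
seed-family classification.

The slide design is a single array (treatment pool labeled Hy3, control
pool Hy5), so differential calling is fold-change-only: up at fold >= 1.3,
down at fold <= 0.77, both inclusive. Probes enter normalization when both
channel intensities are positive and the signal-to-noise gate passes
(both SNR > 1, or at least one SNR > 2).

Normalization is MA-based: M = log2(Hy3/Hy5) is regressed on
A = (log2 Hy3 + log2 Hy5)/2 with a robust locally weighted linear fit
(tricube distance weights, bisquare robustness reweighting) and the fitted
intensity-dependent dye bias is subtracted from M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .targets import extract_seed

UP_THRESHOLD = 1.3
DOWN_THRESHOLD = 0.77
DEFAULT_SPAN = 0.4
DEFAULT_ITERATIONS = 3
MIN_PROBES = 10


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    mirna_name: str
    intensity_hy3: float
    intensity_hy5: float
    snr_hy3: float
    snr_hy5: float


@dataclass(frozen=True)
class MiRNAFamily:
    family_id: str
    seed: str
    members: tuple[str, ...]
    label: str | None = None


def filter_probes(probes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC gate: keep probes with both intensities > 0 AND
    (both SNR > 1 OR at least one SNR > 2).

    Returns (retained, exclusion_log); the log states which clause failed.
    """
    if probes.empty:
        return probes.copy(), pd.DataFrame(columns=["probe_id", "miRNA", "reason"])
    for col in ("Hy3", "Hy5"):
        vals = probes[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{col} intensities must be finite and >= 0")
    intensity_ok = (probes["Hy3"] > 0) & (probes["Hy5"] > 0)
    snr_ok = ((probes["SNR_Hy3"] > 1) & (probes["SNR_Hy5"] > 1)) | (
        (probes["SNR_Hy3"] > 2) | (probes["SNR_Hy5"] > 2)
    )
    keep = intensity_ok & snr_ok
    reasons = np.where(
        ~intensity_ok,
        "non-positive channel intensity",
        "SNR gate failed (needs both SNR>1 or one SNR>2)",
    )
    log = probes.loc[~keep, ["probe_id", "miRNA"]].copy()
    log["reason"] = reasons[~keep.to_numpy()]
    return probes.loc[keep].reset_index(drop=True), log.reset_index(drop=True)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, None) ** 3
    return w


def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> np.ndarray:
    """Robust locally weighted linear regression, evaluated at the data points.

    For each point the window is its k = round(span*n) nearest neighbors in x
    (contiguous after sorting); tricube weights on scaled distance multiply
    bisquare robustness weights from the previous pass. ``iterations``
    robustness refits follow the initial fit. When the median absolute
    residual is (numerically) zero, robustness degenerates to keeping only
    points with ~zero residual, which makes a noise-free majority trend
    reproduced exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y length mismatch")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(2, min(n, int(round(span * n))))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    delta = np.ones(n)
    fitted_s = np.zeros(n)
    for _pass in range(iterations + 1):
        for i in range(n):
            lo, hi = i, i  # grow the window to the k nearest x values
            while hi - lo + 1 < k:
                if lo == 0:
                    hi += 1
                elif hi == n - 1:
                    lo -= 1
                elif xs[i] - xs[lo - 1] <= xs[hi + 1] - xs[i]:
                    lo -= 1
                else:
                    hi += 1
            xw = xs[lo : hi + 1]
            yw = ys[lo : hi + 1]
            dist = np.abs(xw - xs[i])
            dmax = dist.max()
            w = _tricube(dist / dmax) if dmax > 0 else np.ones_like(dist)
            w = w * delta[lo : hi + 1]
            sw = w.sum()
            if sw <= 0:
                fitted_s[i] = ys[i]
                continue
            xm = (w * xw).sum() / sw
            ym = (w * yw).sum() / sw
            sxx = (w * (xw - xm) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xm * xm):
                fitted_s[i] = ym
            else:
                beta = (w * (xw - xm) * (yw - ym)).sum() / sxx
                fitted_s[i] = ym + beta * (xs[i] - xm)
        if _pass == iterations:
            break
        resid = ys - fitted_s
        s = np.median(np.abs(resid))
        if s < 1e-10:
            scale = max(1.0, float(np.median(np.abs(ys))))
            delta = (np.abs(resid) <= 1e-8 * scale).astype(float)
            if delta.sum() < 2:
                delta = np.ones(n)
        else:
            delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


def lowess_normalize(
    probes: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
    min_probes: int = MIN_PROBES,
) -> pd.DataFrame:
    """Within-slide MA normalization: returns probe table with columns
    ``probe_id, miRNA, A, M_raw, M, fold_change`` where M = M_raw - lowess(A)."""
    if len(probes) < min_probes:
        raise ValueError(
            f"insufficient probes for normalization ({len(probes)} < {min_probes})"
        )
    hy3 = probes["Hy3"].to_numpy(dtype=float)
    hy5 = probes["Hy5"].to_numpy(dtype=float)
    if np.any(hy3 <= 0) or np.any(hy5 <= 0):
        raise ValueError("normalization requires strictly positive intensities; "
                         "run filter_probes first")
    m_raw = np.log2(hy3 / hy5)
    a = 0.5 * (np.log2(hy3) + np.log2(hy5))
    trend = lowess_fit(a, m_raw, span=span, iterations=iterations)
    m = m_raw - trend
    return pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "miRNA": probes["miRNA"].to_numpy(),
            "A": a,
            "M_raw": m_raw,
            "M": m,
            "fold_change": np.power(2.0, m),
        }
    )


def compute_fold_changes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA treatment/control fold change (2^mean M over its probes),
    reported at full precision and rounded to two decimals."""
    grouped = normalized.groupby("miRNA", sort=False)["M"].mean()
    fold = np.power(2.0, grouped.to_numpy())
    return pd.DataFrame(
        {
            "miRNA": grouped.index.to_numpy(),
            "M": grouped.to_numpy(),
            "fold_change": fold,
            "fold_change_2dp": np.round(fold, 2),
        }
    )


def call_differential(
    fold_changes: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
) -> pd.DataFrame:
    """Fold-change-only differential calls: up at fold >= up_threshold,
    down at fold <= down_threshold (both inclusive), else unchanged."""
    if not down_threshold < 1 < up_threshold:
        raise ValueError(
            f"thresholds must satisfy down < 1 < up, got {down_threshold}, {up_threshold}"
        )
    fold = fold_changes["fold_change"].to_numpy(dtype=float)
    direction = np.where(
        fold >= up_threshold, "up", np.where(fold <= down_threshold, "down", "unchanged")
    )
    out = fold_changes.copy()
    out["direction"] = direction
    return out


def assign_families(
    calls: pd.DataFrame,
    mature_seqs: dict[str, str] | None = None,
    seed_window: tuple[int, int] = (2, 8),
    family_labels: dict[str, str] | None = None,
) -> list[MiRNAFamily]:
    """Group miRNAs by identical seed string; the seed itself is the family id.

    Seeds come from a ``seed`` column on ``calls`` when present, otherwise
    from the mature sequences (positions ``seed_window``).
    """
    mature_seqs = mature_seqs or {}
    family_labels = family_labels or {}
    seeds: dict[str, str] = {}
    for _, row in calls.iterrows():
        name = row["miRNA"]
        if "seed" in calls.columns and isinstance(row.get("seed"), str) and row["seed"]:
            seeds[name] = row["seed"]
        elif name in mature_seqs:
            seeds[name] = extract_seed(mature_seqs[name], seed_window)
        else:
            raise ValueError(f"no mature sequence or seed available for {name}")
    by_seed: dict[str, list[str]] = {}
    for name, seed in seeds.items():
        by_seed.setdefault(seed, []).append(name)
    families = [
        MiRNAFamily(
            family_id=seed,
            seed=seed,
            members=tuple(sorted(members)),
            label=next(
                (family_labels[m] for m in sorted(members) if m in family_labels), None
            ),
        )
        for seed, members in sorted(by_seed.items())
    ]
    return families


def differential_table(
    calls: pd.DataFrame,
    mature_seqs: dict[str, str] | None = None,
    family_labels: dict[str, str] | None = None,
    seed_window: tuple[int, int] = (2, 8),
) -> pd.DataFrame:
    """Differential-call table restricted to changed miRNAs, with seed and
    family columns mirroring the published table layout."""
    changed = calls[calls["direction"] != "unchanged"].copy()
    mature_seqs = mature_seqs or {}
    family_labels = family_labels or {}
    seeds = []
    for name in changed["miRNA"]:
        seeds.append(
            extract_seed(mature_seqs[name], seed_window) if name in mature_seqs else ""
        )
    changed["seed"] = seeds
    changed["family_label"] = [family_labels.get(n, "") for n in changed["miRNA"]]
    changed = changed.sort_values(
        ["direction", "fold_change"], ascending=[False, False], ignore_index=True
    )
    return changed
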