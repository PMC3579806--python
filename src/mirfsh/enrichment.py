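"""Gene-set over-representation of predicted targets with FDR control.

The test is the upper-tail hypergeometric probability P[X >= observed] of
drawing the observed overlap when ``query_size`` genes are sampled without
replacement from a universe containing ``set_size`` pathway genes. Sets
whose overlap falls below a minimum (default 20, matching the screening
rule this pipeline reproduces) are excluded before testing; survivors are
Benjamini-Hochberg adjusted and flagged at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_OBSERVED = 20
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")


def gene_sets_from_gmt(gmt: dict[str, tuple[str, list[str]]]) -> list[GeneSet]:
    return [
        GeneSet(set_id=sid, label=desc, genes=frozenset(genes))
        for sid, (desc, genes) in gmt.items()
    ]


def hypergeometric_test(
    observed: int, set_size: int, query_size: int, universe_size: int
) -> float:
    """Upper-tail P[X >= observed], X ~ Hypergeom(universe, set, query)."""
    if not (
        0 <= observed <= min(set_size, query_size)
        and set_size <= universe_size
        and query_size <= universe_size
    ):
        raise ValueError(
            f"inconsistent counts: observed={observed}, set={set_size}, "
            f"query={query_size}, universe={universe_size}"
        )
    return float(stats.hypergeom.sf(observed - 1, universe_size, set_size, query_size))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def enrich_pathways(
    query_genes: set[str],
    gene_sets: list[GeneSet],
    universe: set[str] | None = None,
    min_observed: int = DEFAULT_MIN_OBSERVED,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each gene set.

    The universe defaults to the union of all gene-set members and the
    query. Query genes outside the universe are dropped (logged in the
    returned frame's ``attrs['dropped_query_genes']``). Output is sorted by
    adjusted p then set id; sets with overlap below ``min_observed`` are
    excluded before testing.
    """
    if universe is None:
        universe = set().union(*(gs.genes for gs in gene_sets)) | set(query_genes)
    if not universe:
        raise ValueError("empty universe")
    dropped = sorted(set(query_genes) - universe)
    query = set(query_genes) & universe
    rows = []
    for gs in gene_sets:
        set_genes = gs.genes & universe
        observed = len(query & set_genes)
        if observed < min_observed:
            continue
        p_raw = hypergeometric_test(observed, len(set_genes), len(query), len(universe))
        rows.append(
            {
                "set_id": gs.set_id,
                "label": gs.label,
                "observed": observed,
                "set_size": len(set_genes),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_raw": p_raw,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_id", "label", "observed", "set_size", "query_size",
            "universe_size", "p_raw",
        ],
    )
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_raw"].to_numpy())
        result["significant"] = result["p_adjusted"] < fdr
        result = result.sort_values(["p_adjusted", "set_id"], ignore_index=True)
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    result.attrs["dropped_query_genes"] = dropped
    return result
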