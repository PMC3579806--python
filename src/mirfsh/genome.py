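"""Precursor-to-genome mapping, miRNA cluster detection and per-chromosome
summaries.

Mapping is exact-string search of each hairpin (both strands) against the
genome — precursors and genome derive from the same assembly in this
workflow, so mismatch-tolerant alignment is out of scope. Coordinates are
1-based inclusive (GFF3 convention). Clusters chain same-chromosome loci
whose intergenic gap (next.start - current.end - 1) is at most a threshold
(default 10 kb); singletons are not clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from . import io as mio
from .targets import reverse_complement_rna

DEFAULT_CLUSTER_GAP = 10_000


@dataclass(frozen=True)
class PrecursorLocus:
    mirna_name: str  # precursor (hairpin) name
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    copy_index: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must be <= end")
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MiRNACluster:
    chromosome: str
    members: tuple[PrecursorLocus, ...]
    max_gap: int

    @property
    def gaps(self) -> list[int]:
        return [
            b.start - a.end - 1 for a, b in zip(self.members, self.members[1:])
        ]


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) occurrence."""
    return [m.start() for m in re.finditer(f"(?={re.escape(needle)})", haystack)]


def map_precursors(
    precursors: dict[str, str],
    genome: dict[str, str],
) -> tuple[list[PrecursorLocus], list[str]]:
    """Exact-match search of every precursor against both genome strands.

    Returns (loci, unmapped names). All copies are reported; copy indices
    number the hits of one precursor in (chromosome, start) order.
    U/T and case differences are transparent.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    genome_dna = {c: _to_dna(s) for c, s in genome.items()}
    loci: list[PrecursorLocus] = []
    unmapped: list[str] = []
    for name in precursors:
        query = _to_dna(precursors[name])
        if not query:
            raise ValueError(f"empty precursor sequence for {name}")
        rc = _to_dna(reverse_complement_rna(query))
        hits: list[tuple[str, int, str]] = []  # (chrom, start0, strand)
        for chrom in sorted(genome_dna):
            seq = genome_dna[chrom]
            hits.extend((chrom, s, "+") for s in _find_all(seq, query))
            if rc != query:
                hits.extend((chrom, s, "-") for s in _find_all(seq, rc))
        if not hits:
            unmapped.append(name)
            continue
        hits.sort(key=lambda h: (h[0], h[1]))
        for idx, (chrom, start0, strand) in enumerate(hits, start=1):
            loci.append(
                PrecursorLocus(
                    mirna_name=name,
                    chromosome=chrom,
                    start=start0 + 1,
                    end=start0 + len(query),
                    strand=strand,
                    copy_index=idx,
                )
            )
    return loci, unmapped


def loci_from_gff3(gff: pd.DataFrame) -> tuple[list[PrecursorLocus], dict[str, list[str]]]:
    """Ingest precursor loci (and their mature products, if annotated)
    directly from a GFF3 table."""
    loci = []
    matures: dict[str, list[str]] = {}
    copy_seen: dict[str, int] = {}
    for _, row in gff.iterrows():
        attrs = mio.gff3_attributes(row["attributes"])
        name = attrs.get("Name") or attrs.get("ID", "unknown")
        copy_seen[name] = copy_seen.get(name, 0) + 1
        loci.append(
            PrecursorLocus(
                mirna_name=name,
                chromosome=str(row["seqid"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                copy_index=int(attrs.get("copy", copy_seen[name])),
            )
        )
        if "matures" in attrs:
            matures.setdefault(name, [])
            for m in attrs["matures"].split(","):
                if m and m not in matures[name]:
                    matures[name].append(m)
    return loci, matures


def detect_clusters(
    loci: list[PrecursorLocus],
    max_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[MiRNACluster]:
    """Single-linkage chaining of same-chromosome loci with intergenic gap
    <= ``max_gap``; input order is irrelevant (canonical sort applied)."""
    if max_gap < 0:
        raise ValueError("cluster gap threshold must be >= 0")
    clusters: list[MiRNACluster] = []
    ordered = sorted(loci, key=lambda l: (l.chromosome, l.start, l.end, l.mirna_name))
    chain: list[PrecursorLocus] = []
    def flush() -> None:
        if len(chain) >= 2:
            clusters.append(
                MiRNACluster(
                    chromosome=chain[0].chromosome,
                    members=tuple(chain),
                    max_gap=max_gap,
                )
            )
    for locus in ordered:
        if (
            chain
            and locus.chromosome == chain[-1].chromosome
            and locus.start - chain[-1].end - 1 <= max_gap
        ):
            chain.append(locus)
        else:
            flush()
            chain = [locus]
    flush()
    return clusters


def expand_to_matures(
    loci: list[PrecursorLocus],
    precursor_matures: dict[str, list[str]],
) -> pd.DataFrame:
    """One row per (mature miRNA, locus): precursor loci attributed to every
    mature product of the hairpin."""
    rows = []
    for locus in loci:
        for mature in precursor_matures.get(locus.mirna_name, [locus.mirna_name]):
            rows.append(
                {
                    "miRNA": mature,
                    "precursor": locus.mirna_name,
                    "chromosome": locus.chromosome,
                    "start": locus.start,
                    "end": locus.end,
                    "strand": locus.strand,
                    "copy_index": locus.copy_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["miRNA", "precursor", "chromosome", "start", "end", "strand", "copy_index"],
    )


def summarize_chromosomes(mature_loci: pd.DataFrame) -> pd.DataFrame:
    """Distinct-miRNA count per chromosome (a miRNA with two copies on one
    chromosome counts once there), plus a plot-ready relative position."""
    if mature_loci.empty:
        return pd.DataFrame(columns=["chromosome", "n_mirnas", "mirnas"])
    rows = []
    for chrom, sub in mature_loci.groupby("chromosome"):
        mirnas = sorted(sub["miRNA"].unique())
        rows.append({"chromosome": chrom, "n_mirnas": len(mirnas), "mirnas": ",".join(mirnas)})
    out = pd.DataFrame(rows).sort_values(
        "chromosome",
        key=lambda s: s.map(_chrom_sort_key),
        ignore_index=True,
    )
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, float, str]:
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0.0, name)


def relative_positions(mature_loci: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Locus midpoints as a fraction of chromosome length (for ideogram-style
    plotting of the mapped miRNAs)."""
    out = mature_loci.copy()
    lengths = out["chromosome"].map(lambda c: len(genome[c]))
    out["relative_position"] = ((out["start"] + out["end"]) / 2.0) / lengths
    return out
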