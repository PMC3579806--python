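"""File-format helpers: FASTA, GFF3 (9-column subset), GMT, probe tables."""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_COLUMNS = ["probe_id", "miRNA", "Hy3", "Hy5", "SNR_Hy3", "SNR_Hy5"]

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gff3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "start": int, "end": int},
    )
    return df


def write_gff3(df: pd.DataFrame, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    df.to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(buf.getvalue())


def gff3_attributes(attr: str) -> dict[str, str]:
    """Parse a GFF3 attribute column into a dict."""
    out: dict[str, str] = {}
    for field in attr.strip().split(";"):
        if field and "=" in field:
            key, value = field.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: {set_id: (description, [genes...])}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([set_id, desc, *genes]) for set_id, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
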