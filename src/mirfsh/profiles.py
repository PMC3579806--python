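"""Study conditions for the porcine pituitary GnRH / FSH model.

The constants here define the conditions the synthetic-data generator
emulates: the 31 differentially expressed miRNAs of the dual-channel
array screen (treatment/control fold change, family label and 7-mer seed),
the hormone-assay group means (mIU FSH per mg total protein), the ten
miRNAs re-measured by qPCR, and a genomic locus plan that reproduces the
screen's chromosome-level summary (27 of 31 miRNAs mapped across 12
chromosomes, 8 on chromosome 12 and 4 on X, a miR-133b/miR-206 cluster
separated by a 3766 bp intergenic gap).
"""

from __future__ import annotations

# (name, treatment/control fold change, family label, seed = mature positions 2-8)
UP_REGULATED: list[tuple[str, float, str, str]] = [
    ("ssc-miR-133b", 1.90, "miR-133", "UUGGUCC"),
    ("ssc-miR-425-3p", 1.90, "miR-425/489", "AUGACAC"),
    ("ssc-miR-1307", 1.85, "miR-1307", "CUCGGCG"),
    ("ssc-miR-181d-5p", 1.81, "miR-181", "ACAUUCA"),
    ("ssc-miR-195", 1.78, "miR-15/16/195/424/497", "AGCAGCA"),
    ("ssc-miR-532-5p", 1.77, "miR-532/532-5p", "AUGCCUU"),
    ("ssc-let-7c", 1.62, "let-7/98", "GAGGUAG"),
    ("ssc-miR-130b", 1.61, "miR-130/301", "AGUGCAA"),
    ("ssc-miR-451", 1.57, "miR-451", "AACCGUU"),
    ("ssc-miR-105-2", 1.54, "miR-105.h", "CAAAUGC"),
    ("ssc-miR-19b", 1.50, "miR-19", "GUGCAAA"),
    ("ssc-miR-183", 1.47, "miR-183", "AUGGCAC"),
    ("ssc-miR-423-3p", 1.46, "miR-423/423-3p", "GCUCGGU"),
    ("ssc-miR-206", 1.46, "miR-1/206", "GGAAUGU"),
    ("ssc-miR-15a", 1.42, "miR-15/16/195/424/497", "AGCAGCA"),
    ("ssc-miR-22-5p", 1.39, "miR-22-5p/3568", "GUUCUUC"),
    ("ssc-miR-133a-3p", 1.39, "miR-133", "UUGGUCC"),
    ("ssc-miR-340", 1.37, "miR-340/340-5p", "UAUAAAG"),
    ("ssc-let-7a", 1.37, "let-7/98", "GAGGUAG"),
    ("ssc-miR-338", 1.36, "miR-338/338-3p", "CCAGCAU"),
    ("ssc-miR-361-5p", 1.35, "miR-361/361-5p", "UAUCAGA"),
]

DOWN_REGULATED: list[tuple[str, float, str, str]] = [
    ("ssc-miR-324", 0.47, "miR-324-5p", "GCAUCCC"),
    ("ssc-miR-708-5p", 0.64, "miR-28/28-5p/708", "AGGAGCU"),
    ("ssc-miR-151-3p", 0.66, "miR-151-3p", "UAGACUG"),
    ("ssc-miR-30e-3p", 0.67, "miR-30a-3p/30e", "UUUCAGU"),
    ("ssc-miR-152", 0.69, "miR-148/152", "CAGUGCA"),
    ("ssc-miR-21", 0.70, "miR-21/590-5p", "AGCUUAU"),
    ("ssc-miR-320", 0.75, "miR-320/320abcd", "AAAGCUG"),
    ("ssc-miR-22-3p", 0.76, "miR-22", "AGCUGCC"),
    ("ssc-miR-17-5p", 0.76, "miR-17-5p/20/93.mr/106/519.d", "AAAGUGC"),
    ("ssc-miR-361-3p", 0.76, "miR-361-3p", "CCCCCAG"),
]

DIFFERENTIAL_PROFILE: list[tuple[str, float, str, str]] = UP_REGULATED + DOWN_REGULATED

PLANTED_FOLD_CHANGES: dict[str, float] = {name: fc for name, fc, _, _ in DIFFERENTIAL_PROFILE}
SEEDS: dict[str, str] = {name: seed for name, _, _, seed in DIFFERENTIAL_PROFILE}
FAMILY_LABELS: dict[str, str] = {name: fam for name, _, fam, _ in DIFFERENTIAL_PROFILE}

# miRNAs re-measured by tail-added qPCR against the U6 reference.
VALIDATED_MIRNAS: list[str] = [
    "ssc-let-7c",
    "ssc-miR-30e-3p",
    "ssc-miR-320",
    "ssc-miR-324",
    "ssc-miR-361-3p",
    "ssc-miR-361-5p",
    "ssc-miR-423-3p",
    "ssc-miR-425-3p",
    "ssc-miR-451",
    "ssc-miR-708-5p",
]

# qPCR showed no significant change for this miRNA despite the array call.
QPCR_NON_SIGNIFICANT: str = "ssc-miR-708-5p"

# The deterministic 3' tail appended after U + seed when synthesizing matures.
# miR-361-3p keeps its known suffix so the mature reads UCCCCCAGGUGUGAUUCUGAUU.
MIR_361_3P_TAIL = "GUGUGAUUCUGAUU"

# FSH concentrations, mIU per mg total protein: (mean, sd), n = 6 wells.
HORMONE_GROUPS: dict[str, tuple[float, float]] = {
    "control_3h": (128.11, 7.67),
    "gnrh_3h": (180.00, 41.08),
    "control_6h": (147.70, 21.44),
    "gnrh_6h": (264.74, 60.92),
    "nc": (162.94, 5.01),        # duplex negative control
    "mimic": (140.00, 11.45),    # miR-361-3p mimic
    "inc": (141.91, 7.81),       # inhibitor negative control
    "inhibitor": (163.31, 7.04),  # miR-361-3p inhibitor
}

# Which assay wells belong to which contrast, and the baseline of each.
HORMONE_EXPERIMENTS: dict[str, tuple[str, str]] = {
    # experiment -> (group, baseline)
    "fsh_3h": ("gnrh_3h", "control_3h"),
    "fsh_6h": ("gnrh_6h", "control_6h"),
    "mimic": ("mimic", "nc"),
    "inhibitor": ("inhibitor", "inc"),
}

# FSHbeta mRNA response at 6 h (beta-actin reference): 1.60-fold up.
FSHB_MRNA_FOLD: float = 1.60

# Precursor hairpins: most matures have their own hairpin; the two
# 5p/3p arm pairs each share one.
SHARED_PRECURSORS: dict[str, tuple[str, str]] = {
    "ssc-mir-361": ("ssc-miR-361-5p", "ssc-miR-361-3p"),
    "ssc-mir-22": ("ssc-miR-22-5p", "ssc-miR-22-3p"),
}

# Synthetic genomic locus plan: precursor -> list of chromosomes (one entry
# per genomic copy); precursors absent from the map are unmapped. Engineered
# aggregate: 27/31 miRNAs mapped, 12 chromosomes, chr12 carries 8 miRNAs,
# chrX carries 4 (19b, 105-2 and both mir-361 arms), let-7a has two copies
# on one chromosome, miR-340 one copy on each of two chromosomes.
LOCUS_PLAN: dict[str, list[str]] = {
    "ssc-mir-425-3p": ["chr12"],
    "ssc-mir-1307": ["chr12"],
    "ssc-mir-181d-5p": ["chr12"],
    "ssc-mir-195": ["chr12"],
    "ssc-mir-183": ["chr12"],
    "ssc-mir-15a": ["chr12"],
    "ssc-mir-21": ["chr12"],
    "ssc-mir-324": ["chr12"],
    "ssc-mir-19b": ["chrX"],
    "ssc-mir-105-2": ["chrX"],
    "ssc-mir-361": ["chrX"],
    "ssc-mir-133b": ["chr7"],
    "ssc-mir-206": ["chr7"],
    "ssc-let-7c": ["chr1"],
    "ssc-mir-451": ["chr1"],
    "ssc-mir-423-3p": ["chr2"],
    "ssc-mir-22": ["chr2"],
    "ssc-mir-133a-3p": ["chr3"],
    "ssc-mir-708-5p": ["chr3"],
    "ssc-mir-340": ["chr4", "chr10"],
    "ssc-mir-30e-3p": ["chr4"],
    "ssc-mir-152": ["chr5"],
    "ssc-let-7a": ["chr6", "chr6"],
    "ssc-mir-320": ["chr8"],
    "ssc-mir-17-5p": ["chr9"],
    # unmapped precursors (present in the precursor FASTA, absent from the
    # mini-genome): miR-151-3p, miR-338, miR-532-5p, miR-130b
}

UNMAPPED_MIRNAS: list[str] = [
    "ssc-miR-151-3p",
    "ssc-miR-338",
    "ssc-miR-532-5p",
    "ssc-miR-130b",
]

# Precursors placed on the reverse genomic strand in the fixture.
MINUS_STRAND_PRECURSORS: set[str] = {"ssc-mir-451", "ssc-mir-361", "ssc-mir-320"}

# miR-133b/miR-206 cluster: exact intergenic gap, bp (next.start - prev.end - 1).
CLUSTER_GAP_BP: int = 3766

# Species carrying a fully Watson-Crick-conserved miR-361-3p site in the
# FSHbeta 3'-UTR.
CONSERVED_SPECIES: list[str] = ["pig", "sheep", "cattle", "mouse", "human"]


def precursor_name(mirna: str) -> str:
    """Hairpin name for a mature miRNA (mir- case; arm pairs share one)."""
    for prec, arms in SHARED_PRECURSORS.items():
        if mirna in arms:
            return prec
    return mirna.replace("miR-", "mir-")


def precursor_to_matures() -> dict[str, list[str]]:
    """Map every hairpin name to its mature product(s)."""
    mapping: dict[str, list[str]] = {}
    for name, _, _, _ in DIFFERENTIAL_PROFILE:
        mapping.setdefault(precursor_name(name), []).append(name)
    return mapping
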