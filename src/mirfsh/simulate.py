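"""Synthetic input generator with planted ground truth.

Every input the pipeline consumes can be generated here: the two-channel
probe-intensity table (with an intensity-dependent dye bias for LOWESS to
remove and planted treatment/control ratios), qPCR Ct tables with planted
delta-delta-Ct effects, protein-calibrated FSH assay wells with the study's
group means, a mini-genome plus precursor FASTA/GFF3 with known coordinates
(including a 3766 bp miR-133b/miR-206 intergenic gap, a two-copy precursor
and an unmappable one), and 3'-UTRs with planted high-affinity target sites,
energy-failing decoys and an enriched gene set.

Determinism contract: one integer seed drives every sub-generator through
named ``numpy`` SeedSequence substreams; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import profiles, targets

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))

# substream ids
_S_ARRAY, _S_QPCR, _S_HORMONE, _S_GENOME, _S_UTR, _S_MATURE = range(6)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _default_ct_effects() -> dict[str, float]:
    effects = {
        name: -float(np.log2(profiles.PLANTED_FOLD_CHANGES[name]))
        for name in profiles.VALIDATED_MIRNAS
    }
    effects[profiles.QPCR_NON_SIGNIFICANT] = 0.0
    effects["FSHB"] = -float(np.log2(profiles.FSHB_MRNA_FOLD))
    effects["U6"] = 0.0
    effects["ACTB"] = 0.0
    return effects


def _default_utr_plants() -> list[tuple[str, str, int]]:
    """(miRNA, transcript, 1-based seed-site position) planted target sites.

    FSHB carries the miR-361-3p site; 23 further genes cycle through the
    differentially expressed miRNAs, one planted transcript each.
    """
    plants = [("ssc-miR-361-3p", "TX_FSHB", 201)]
    names = [n for n, _, _, _ in profiles.DIFFERENTIAL_PROFILE]
    for i in range(23):
        plants.append((names[i % len(names)], f"TX_TGT{i + 1:03d}", 60 + (i * 37) % 340))
    return plants


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults reproduce the study design
    (31 planted fold changes, 6 wells per hormone group, triplicate qPCR)."""

    seed: int = 0
    # microarray
    n_null_probes: int = 800
    planted_fold_changes: dict[str, float] = field(
        default_factory=lambda: dict(profiles.PLANTED_FOLD_CHANGES)
    )
    dye_bias_coefficients: tuple[float, ...] = (-0.3, 0.05)  # low->high in A
    noise_sd: float = 0.0
    snr_fail_fraction: float = 0.05
    # qPCR
    ct_effects: dict[str, float] = field(default_factory=_default_ct_effects)
    ct_reference: str = "U6"
    mrna_reference: str = "ACTB"
    ct_noise_sd: float = 0.05
    ct_replicates: int = 3
    # hormone assay
    hormone_group_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(profiles.HORMONE_GROUPS)
    )
    hormone_n: int = 6
    exact_moments: bool = True
    # UTRs / gene sets
    utr_plants: list[tuple[str, str, int]] = field(default_factory=_default_utr_plants)
    decoy_density: float = 1.0
    n_background_utrs: int = 16
    utr_length: int = 500

    def __post_init__(self) -> None:
        for name, ratio in self.planted_fold_changes.items():
            if not ratio > 0:
                raise ValueError(f"planted ratio for {name} must be > 0, got {ratio}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_null_probes < 0:
            raise ValueError("n_null_probes must be >= 0")
        if not 0 <= self.snr_fail_fraction <= 1:
            raise ValueError("snr_fail_fraction must be in [0, 1]")
        for group, (mean, sd) in self.hormone_group_means.items():
            if mean <= 0:
                raise ValueError(f"hormone group {group} mean must be > 0")
            if sd < 0:
                raise ValueError(f"hormone group {group} SD must be >= 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def mature_sequences(config: SimulationConfig) -> dict[str, str]:
    """Synthetic 22-nt matures: U + printed 7-mer seed + deterministic tail,
    so seed extraction at positions 2-8 reproduces every printed seed."""
    rng = _rng(config.seed, _S_MATURE)
    out: dict[str, str] = {}
    for name, _, _, seed in profiles.DIFFERENTIAL_PROFILE:
        if name == "ssc-miR-361-3p":
            tail = profiles.MIR_361_3P_TAIL
        else:
            tail = "".join(rng.choice(_RNA, size=14))
        out[name] = "U" + seed + tail
    return out


def _bias(config: SimulationConfig, a: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(a, np.asarray(config.dye_bias_coefficients))


def generate_array_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Two-channel probe table with planted Hy3/Hy5 (treatment/control)
    ratios on top of an intensity-dependent dye bias."""
    rng = _rng(config.seed, _S_ARRAY)
    names = list(config.planted_fold_changes) + [
        f"null-miR-{i + 1:04d}" for i in range(config.n_null_probes)
    ]
    m_true = np.array(
        [np.log2(config.planted_fold_changes[n]) for n in config.planted_fold_changes]
        + [0.0] * config.n_null_probes
    )
    n = len(names)
    if n == 0:
        return pd.DataFrame(columns=mio.PROBE_COLUMNS)
    a = rng.uniform(6.0, 14.0, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    m_obs = m_true + _bias(config, a) + noise
    hy3 = np.power(2.0, a + m_obs / 2.0)
    hy5 = np.power(2.0, a - m_obs / 2.0)
    snr3 = rng.uniform(3.0, 40.0, size=n)
    snr5 = rng.uniform(3.0, 40.0, size=n)
    # a fraction of NULL probes fails the QC gate; planted probes always pass
    n_plant = len(config.planted_fold_changes)
    n_fail = int(round(config.snr_fail_fraction * config.n_null_probes))
    fail_idx = (
        rng.choice(config.n_null_probes, size=n_fail, replace=False) + n_plant
        if n_fail > 0
        else np.array([], dtype=int)
    )
    for j, idx in enumerate(fail_idx):
        if j % 2 == 0:  # low signal-to-noise in both channels
            snr3[idx] = rng.uniform(0.2, 0.9)
            snr5[idx] = rng.uniform(0.2, 0.9)
        else:  # dead spot in one channel
            hy3[idx] = 0.0
    return pd.DataFrame(
        {
            "probe_id": [f"P{i + 1:05d}" for i in range(n)],
            "miRNA": names,
            "Hy3": hy3,
            "Hy5": hy5,
            "SNR_Hy3": snr3,
            "SNR_Hy5": snr5,
        }
    )


def generate_qpcr_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Triplicate Ct values per group and gene with planted delta-delta-Ct
    effects; reference genes are constant across groups up to noise."""
    refs = {config.ct_reference, config.mrna_reference}
    missing = refs - set(config.ct_effects)
    if missing:
        raise ValueError(f"reference gene(s) missing from ct_effects: {sorted(missing)}")
    for ref in refs:
        if config.ct_effects[ref] != 0.0:
            raise ValueError(f"reference gene {ref} must have a zero planted effect")
    rng = _rng(config.seed, _S_QPCR)
    base_ct = {config.ct_reference: 20.0, config.mrna_reference: 18.0}
    rows = []
    for gene in config.ct_effects:
        base = base_ct.get(gene)
        if base is None:
            base = float(rng.uniform(22.0, 28.0))
        effect = config.ct_effects[gene]
        for group, shift in (("control", 0.0), ("treatment", effect)):
            for rep in range(1, config.ct_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                rows.append(
                    {
                        "sample_id": f"{group}_pool",
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base + shift + noise,
                    }
                )
    return pd.DataFrame(rows)


def generate_hormone_dataset(config: SimulationConfig) -> pd.DataFrame:
    """FSH assay wells (raw mIU + total protein for calibration).

    With ``exact_moments`` (default) each group's per-mg values are
    standardized to the configured sample mean and SD exactly, so the
    printed-mean fold/percent contracts hold for any seed.
    """
    rng = _rng(config.seed, _S_HORMONE)
    n = config.hormone_n
    timepoints = {"control_3h": 3, "gnrh_3h": 3, "control_6h": 6, "gnrh_6h": 6}
    rows = []
    well = 0
    for group, (mean, sd) in config.hormone_group_means.items():
        if sd == 0 or n < 2:
            per_mg = np.full(n, mean)
        else:
            z = rng.normal(size=n)
            if config.exact_moments:
                z = (z - z.mean()) / z.std(ddof=1)
            per_mg = mean + sd * z
        per_mg = np.clip(per_mg, 1e-6, None)
        protein = rng.uniform(0.8, 1.6, size=n)
        for i in range(n):
            well += 1
            rows.append(
                {
                    "well_id": f"W{well:03d}",
                    "group": group,
                    "timepoint": timepoints.get(group, 24),
                    "fsh": per_mg[i] * protein[i],
                    "total_protein": protein[i],
                }
            )
    return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray = _DNA) -> str:
    return "".join(rng.choice(alphabet, size=length))


def generate_genome_fixture(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Mini-genome FASTA, precursor FASTA (RNA) and truth GFF3.

    Precursors are embedded at known coordinates per the locus plan:
    miR-133b/miR-206 sit on one chromosome separated by an intergenic gap of
    exactly 3766 bp, let-7a has two identical genomic copies, and four
    precursors are absent from the genome entirely.
    """
    rng = _rng(config.seed, _S_GENOME)
    matures = mature_sequences(config)
    prec_to_mat = profiles.precursor_to_matures()
    # hairpin sequences (RNA): flanks + mature(s)
    precursors: dict[str, str] = {}
    for prec, mats in prec_to_mat.items():
        if len(mats) == 2:
            seq = (
                _random_seq(rng, 10, _RNA) + matures[mats[0]]
                + _random_seq(rng, 15, _RNA) + matures[mats[1]]
                + _random_seq(rng, 10, _RNA)
            )
        else:
            seq = (
                _random_seq(rng, 20, _RNA) + matures[mats[0]] + _random_seq(rng, 30, _RNA)
            )
        precursors[prec] = seq

    by_chrom: dict[str, list[str]] = {}
    copy_counter: dict[str, int] = {}
    placements: list[tuple[str, str, int]] = []  # (chrom, prec, copy_index)
    for prec, chroms in profiles.LOCUS_PLAN.items():
        for chrom in chroms:
            copy_counter[prec] = copy_counter.get(prec, 0) + 1
            by_chrom.setdefault(chrom, []).append(prec)
            placements.append((chrom, prec, copy_counter[prec]))

    genome: dict[str, str] = {}
    gff_rows = []
    copy_seen: dict[str, int] = {}
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        parts: list[str] = []
        cursor = 0  # 0-based length so far
        prev_end = None
        for prec in by_chrom[chrom]:
            is_cluster_partner = chrom == "chr7" and prec == "ssc-mir-206"
            if prev_end is None:
                gap = 2000
            elif is_cluster_partner:
                gap = profiles.CLUSTER_GAP_BP
            else:
                gap = 15000
            parts.append(_random_seq(rng, gap))
            start = cursor + gap + 1  # 1-based
            dna = precursors[prec].replace("U", "T")
            if prec in profiles.MINUS_STRAND_PRECURSORS:
                strand = "-"
                embedded = str(
                    targets.reverse_complement_rna(precursors[prec])
                ).replace("U", "T")
            else:
                strand = "+"
                embedded = dna
            parts.append(embedded)
            end = start + len(embedded) - 1
            cursor = end
            prev_end = end
            copy_seen[prec] = copy_seen.get(prec, 0) + 1
            gff_rows.append(
                {
                    "seqid": chrom,
                    "source": "mirfsh_sim",
                    "type": "miRNA_primary_transcript",
                    "start": start,
                    "end": end,
                    "score": ".",
                    "strand": strand,
                    "phase": ".",
                    "attributes": (
                        f"ID={prec}.{copy_seen[prec]};Name={prec};"
                        f"copy={copy_seen[prec]};"
                        f"matures={','.join(prec_to_mat[prec])}"
                    ),
                }
            )
        parts.append(_random_seq(rng, 2000))
        genome[chrom] = "".join(parts)
    gff = pd.DataFrame(gff_rows, columns=mio.GFF3_COLUMNS)
    return genome, precursors, gff


def generate_utr_and_genesets(
    config: SimulationConfig,
    params: targets.EnergyParameters | None = None,
) -> tuple[dict[str, str], dict[str, str], dict[str, tuple[str, list[str]]], dict[str, str]]:
    """UTR FASTA, transcript->gene map, GMT gene sets and FSHbeta orthologs.

    Planted sites embed the full reverse complement of the mature so the
    seed complement sits exactly at the declared position and the anchored
    duplex passes the energy filter with margin (< -25 kcal/mol, verified).
    Decoys carry only the 7-mer seed complement and are resampled until the
    anchored duplex fails the filter with margin (> -18 kcal/mol).
    """
    if params is None:
        params = targets.load_energy_parameters()
    rng = _rng(config.seed, _S_UTR)
    matures = mature_sequences(config)
    utrs: dict[str, str] = {}
    gene_map: dict[str, str] = {}

    for mirna, tx, pos in config.utr_plants:
        if mirna not in matures:
            raise ValueError(f"utr plant references undeclared miRNA {mirna}")
        mature = matures[mirna]
        site = targets.reverse_complement_rna(mature)  # full complement, RNA
        offset = len(mature) - 8  # seed complement offset inside the site
        full_start0 = (pos - 1) - offset
        if full_start0 < 0 or pos - 1 + 7 > config.utr_length:
            raise ValueError(
                f"plant position {pos} outside UTR of length {config.utr_length} "
                f"for {mirna}/{tx}"
            )
        for _attempt in range(20):
            seq = list(_random_seq(rng, config.utr_length, _RNA))
            seq[full_start0 : full_start0 + len(site)] = list(site)
            u = "".join(seq)
            mfe = targets.site_energy(mature, u, pos, params=params)
            if mfe < -25.0:
                break
        else:  # pragma: no cover - full complement always clears the margin
            raise RuntimeError(f"could not engineer planted site for {mirna}/{tx}")
        utrs[tx] = u
        gene_map[tx] = tx.removeprefix("TX_")

    # decoy/background UTRs: seed matches engineered to fail the energy filter
    names = [n for n, _, _, _ in profiles.DIFFERENTIAL_PROFILE]
    for i in range(config.n_background_utrs):
        tx = f"TX_BG{i + 1:03d}"
        n_decoys = max(1, round(config.decoy_density * config.utr_length / 1000))
        for _attempt in range(50):
            seq = list(_random_seq(rng, config.utr_length, _RNA))
            decoy_info = []
            for d in range(n_decoys):
                mirna = names[(i * n_decoys + d) % len(names)]
                seed = targets.extract_seed(matures[mirna])
                pos = int(rng.integers(40, config.utr_length - 40))
                seq[pos - 1 : pos + 6] = list(targets.reverse_complement_rna(seed))
                decoy_info.append((mirna, pos))
            u = "".join(seq)
            ok = all(
                targets.site_energy(matures[m], u, p, params=params) > -18.0
                for m, p in decoy_info
            )
            if ok:
                break
        else:  # pragma: no cover - resampling margin failure is pathological
            raise RuntimeError(f"could not engineer decoy UTR {tx}")
        utrs[tx] = u
        gene_map[tx] = f"BGGENE{i + 1:03d}"

    # FSHbeta 3'-UTR orthologs: every species carries the all-WC
    # miR-361-3p seed-complement site (CUGGGGG)
    seed_361 = profiles.SEEDS["ssc-miR-361-3p"]
    site_361 = targets.reverse_complement_rna(seed_361)
    orthologs: dict[str, str] = {}
    for species in profiles.CONSERVED_SPECIES:
        if species == "pig" and "TX_FSHB" in utrs:
            orthologs[species] = utrs["TX_FSHB"]
            continue
        seq = list(_random_seq(rng, 300, _RNA))
        pos = int(rng.integers(80, 200))
        seq[pos - 1 : pos + 6] = list(site_361)
        orthologs[species] = "".join(seq)

    # gene sets: one strongly enriched in planted targets, one undersized,
    # one broad background set, two mid-size background sets
    target_genes = [gene_map[tx] for tx, g in gene_map.items() if not g.startswith("BGGENE")]
    bg_genes = [f"BGGENE{i + 1:03d}" for i in range(260)]
    pool = sorted(set(bg_genes) | set(target_genes))
    gmt: dict[str, tuple[str, list[str]]] = {
        "GNRH_SIGNALING_LIKE": (
            "planted enriched set",
            target_genes[:22] + bg_genes[:8],
        ),
        "BULK_PATHWAY": (
            "broad background set",
            sorted(rng.choice(pool, size=250, replace=False)),
        ),
        "MID_PATHWAY_A": ("background set", bg_genes[8:48]),
        "MID_PATHWAY_B": ("background set", bg_genes[48:88]),
        "SMALL_SET": ("undersized set", bg_genes[88:98]),
    }
    return utrs, gene_map, gmt, orthologs


def write_fixture_dir(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input into ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    probes = generate_array_dataset(config)
    paths["probes"] = out / "probes.tsv"
    mio.write_probe_table(probes, paths["probes"])

    ct = generate_qpcr_dataset(config)
    paths["ct"] = out / "ct.csv"
    ct.to_csv(paths["ct"], index=False, float_format="%.6f")

    hormone = generate_hormone_dataset(config)
    paths["hormone"] = out / "hormone.csv"
    hormone.to_csv(paths["hormone"], index=False, float_format="%.6f")

    genome, precursors, gff = generate_genome_fixture(config)
    paths["genome"] = out / "genome.fa"
    mio.write_fasta(genome, paths["genome"])
    paths["precursors"] = out / "precursors.fa"
    mio.write_fasta(precursors, paths["precursors"])
    paths["precursor_gff"] = out / "precursors.gff3"
    mio.write_gff3(gff, paths["precursor_gff"])

    matures = mature_sequences(config)
    paths["matures"] = out / "matures.fa"
    mio.write_fasta(matures, paths["matures"])

    annotation = pd.DataFrame(
        {
            "miRNA": list(matures),
            "mature_sequence": [matures[n] for n in matures],
            "family_label": [profiles.FAMILY_LABELS[n] for n in matures],
        }
    )
    paths["annotation"] = out / "annotation.csv"
    annotation.to_csv(paths["annotation"], index=False)

    utrs, gene_map, gmt, orthologs = generate_utr_and_genesets(config)
    paths["utrs"] = out / "utrs.fa"
    mio.write_fasta(utrs, paths["utrs"])
    paths["gene_map"] = out / "transcript_genes.csv"
    pd.DataFrame(
        {"transcript_id": list(gene_map), "gene_name": list(gene_map.values())}
    ).to_csv(paths["gene_map"], index=False)
    paths["gmt"] = out / "genesets.gmt"
    mio.write_gmt(gmt, paths["gmt"])
    paths["orthologs"] = out / "fshb_orthologs.fa"
    mio.write_fasta(
        {f"{sp}|FSHB": seq for sp, seq in orthologs.items()}, paths["orthologs"]
    )
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    if "utr_plants" in d:
        d["utr_plants"] = [tuple(x) for x in d["utr_plants"]]
    if "hormone_group_means" in d:
        d["hormone_group_means"] = {
            k: tuple(v) for k, v in d["hormone_group_means"].items()
        }
    if "dye_bias_coefficients" in d:
        d["dye_bias_coefficients"] = tuple(d["dye_bias_coefficients"])
    return SimulationConfig(**d)
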