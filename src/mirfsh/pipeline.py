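"""End-to-end orchestration: simulate -> array-de -> qpcr -> hormone ->
targets -> map -> enrich, with a run manifest and a consolidated report.

Each stage writes its CSV/JSON outputs plus a manifest entry recording the
parameters it ran with, input/output hashes and row counts. A failure in
one stage raises ``StageError`` naming the stage; downstream stages do not
run. Two runs with the same configuration and seed produce byte-identical
stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import array_de, enrichment, genome, hormone, io as mio, profiles, qpcr, simulate, targets

logger = logging.getLogger("mirfsh")

STAGES = ["simulate", "array_de", "qpcr", "hormone", "targets", "genome_map", "enrichment"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full run. With no explicit input paths the
    synthetic fixture is generated into ``<outdir>/inputs``."""

    outdir: Path = Path("mirfsh_run")
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # thresholds, echoed into the manifest
    up_threshold: float = array_de.UP_THRESHOLD
    down_threshold: float = array_de.DOWN_THRESHOLD
    lowess_span: float = array_de.DEFAULT_SPAN
    lowess_iterations: int = array_de.DEFAULT_ITERATIONS
    energy_threshold: float = targets.DEFAULT_ENERGY_THRESHOLD
    seed_window: tuple[int, int] = targets.DEFAULT_SEED_WINDOW
    max_gu: int = 1
    cluster_gap: int = genome.DEFAULT_CLUSTER_GAP
    min_observed: int = enrichment.DEFAULT_MIN_OBSERVED
    fdr: float = enrichment.DEFAULT_FDR
    ct_reference: str = "U6"
    mrna_reference: str = "ACTB"
    hormone_baselines: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(profiles.HORMONE_EXPERIMENTS)
    )
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    inputs: dict[str, str] = field(default_factory=dict)  # pre-existing input paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        if "seed_window" in raw:
            raw["seed_window"] = tuple(raw["seed_window"])
        if "stages" in raw:
            raw["stages"] = {**{s: True for s in STAGES}, **raw["stages"]}
        if "hormone_baselines" in raw:
            raw["hormone_baselines"] = {
                k: tuple(v) for k, v in raw["hormone_baselines"].items()
            }
        return cls(**raw)

    def validate(self) -> None:
        if not self.down_threshold < 1 < self.up_threshold:
            raise ValueError("fold thresholds must satisfy down < 1 < up")
        if self.energy_threshold >= 0:
            raise ValueError("energy threshold must be negative")
        if self.cluster_gap < 0:
            raise ValueError("cluster gap must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"configured input {name!r} does not exist: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "up_threshold": config.up_threshold,
            "down_threshold": config.down_threshold,
            "lowess_span": config.lowess_span,
            "lowess_iterations": config.lowess_iterations,
            "energy_threshold": config.energy_threshold,
            "seed_window": list(config.seed_window),
            "max_gu": config.max_gu,
            "cluster_gap": config.cluster_gap,
            "min_observed": config.min_observed,
            "fdr": config.fdr,
        },
        "stages": {},
    }
    state: dict = {"inputs": {k: Path(v) for k, v in config.inputs.items()}}

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int], params: dict):
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _sha256(Path(v)) for k, v in outputs.items()},
            "row_counts": counts,
            "parameters": params,
        }
        logger.info("stage %s done: %s", stage, counts)

    enabled = {s: config.stages.get(s, True) for s in STAGES}

    for stage in STAGES:
        if not enabled[stage]:
            logger.info("stage %s disabled", stage)
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                sim_cfg = simulate.config_from_dict(
                    {"seed": config.seed, **config.simulation}
                )
                paths = simulate.write_fixture_dir(sim_cfg, out / "inputs")
                generated = {k: Path(v) for k, v in paths.items()}
                generated.update(state["inputs"])  # explicit inputs win
                state["inputs"] = generated
                record(
                    stage,
                    state["inputs"],
                    {"files": len(paths)},
                    {"seed": sim_cfg.seed, "noise_sd": sim_cfg.noise_sd},
                )
            elif stage == "array_de":
                inp = state["inputs"]
                probes = mio.read_probe_table(inp["probes"])
                retained, excluded = array_de.filter_probes(probes)
                normalized = array_de.lowess_normalize(
                    retained, span=config.lowess_span,
                    iterations=config.lowess_iterations,
                )
                folds = array_de.compute_fold_changes(normalized)
                calls = array_de.call_differential(
                    folds, config.up_threshold, config.down_threshold
                )
                annotation = pd.read_csv(inp["annotation"])
                matures = dict(zip(annotation["miRNA"], annotation["mature_sequence"]))
                labels = dict(zip(annotation["miRNA"], annotation["family_label"]))
                table = array_de.differential_table(calls, matures, labels)
                changed = table[["miRNA"]].copy()
                families = array_de.assign_families(
                    table, matures, family_labels=labels
                )
                fam_df = pd.DataFrame(
                    {
                        "family_id": [f.family_id for f in families],
                        "seed": [f.seed for f in families],
                        "label": [f.label or "" for f in families],
                        "members": [";".join(f.members) for f in families],
                    }
                )
                d = out / "array_de"
                d.mkdir(exist_ok=True)
                normalized.to_csv(d / "normalized.csv", index=False, float_format="%.6f")
                excluded.to_csv(d / "excluded_probes.csv", index=False)
                table.to_csv(d / "differential_calls.csv", index=False, float_format="%.6f")
                fam_df.to_csv(d / "families.csv", index=False)
                state["calls"] = calls
                state["diff_table"] = table
                state["families"] = families
                record(
                    stage,
                    {
                        "normalized": d / "normalized.csv",
                        "excluded": d / "excluded_probes.csv",
                        "calls": d / "differential_calls.csv",
                        "families": d / "families.csv",
                    },
                    {
                        "probes_in": len(probes),
                        "probes_retained": len(retained),
                        "up": int((table["direction"] == "up").sum()),
                        "down": int((table["direction"] == "down").sum()),
                        "families": len(families),
                    },
                    {
                        "span": config.lowess_span,
                        "iterations": config.lowess_iterations,
                        "up_threshold": config.up_threshold,
                        "down_threshold": config.down_threshold,
                    },
                )
            elif stage == "qpcr":
                inp = state["inputs"]
                ct = pd.read_csv(inp["ct"])
                mirna_genes = set(profiles.PLANTED_FOLD_CHANGES)
                rq_mirna = qpcr.delta_delta_ct(
                    ct[ct["gene"].isin(mirna_genes | {config.ct_reference})],
                    config.ct_reference,
                )
                mrna_rows = ct[~ct["gene"].isin(mirna_genes | {config.ct_reference})]
                rq_mrna = (
                    qpcr.delta_delta_ct(mrna_rows, config.mrna_reference)
                    if config.mrna_reference in set(mrna_rows["gene"])
                    else pd.DataFrame(columns=rq_mirna.columns)
                )
                d = out / "qpcr"
                d.mkdir(exist_ok=True)
                rq_all = pd.concat([rq_mirna, rq_mrna], ignore_index=True)
                rq_all.to_csv(d / "relative_quantities.csv", index=False, float_format="%.6f")
                report = None
                if "calls" in state:
                    report = qpcr.concordance(state["calls"], rq_mirna)
                    _write_json(report, d / "concordance.json")
                state["rq"] = rq_all
                state["concordance"] = report
                outputs = {"rq": d / "relative_quantities.csv"}
                if report is not None:
                    outputs["concordance"] = d / "concordance.json"
                record(
                    stage, outputs,
                    {"genes": len(rq_all)},
                    {"reference": config.ct_reference,
                     "mrna_reference": config.mrna_reference},
                )
            elif stage == "hormone":
                inp = state["inputs"]
                assay = hormone.normalize_by_protein(pd.read_csv(inp["hormone"]))
                tables = []
                for exp, (group, baseline) in config.hormone_baselines.items():
                    sub = assay[assay["group"].isin([group, baseline])]
                    if sub.empty:
                        continue
                    t = hormone.summary_table(
                        hormone.summarize_groups(sub, baseline=baseline)
                    )
                    t.insert(0, "experiment", exp)
                    tables.append(t)
                summary = pd.concat(tables, ignore_index=True)
                d = out / "hormone"
                d.mkdir(exist_ok=True)
                summary.to_csv(d / "group_summaries.csv", index=False, float_format="%.6f")
                state["hormone_summary"] = summary
                record(
                    stage,
                    {"summaries": d / "group_summaries.csv"},
                    {"groups": int(assay["group"].nunique())},
                    {"baselines": {k: list(v) for k, v in config.hormone_baselines.items()}},
                )
            elif stage == "targets":
                inp = state["inputs"]
                matures = mio.read_fasta(inp["matures"])
                utrs = mio.read_fasta(inp["utrs"])
                gene_map_df = pd.read_csv(inp["gene_map"])
                gene_map = dict(
                    zip(gene_map_df["transcript_id"], gene_map_df["gene_name"])
                )
                sites = targets.predict_targets(
                    matures, utrs,
                    energy_threshold=config.energy_threshold,
                    seed_window=config.seed_window,
                    max_gu=config.max_gu,
                    gene_map=gene_map,
                )
                per_mirna, per_tx = targets.summarize_targets(sites)
                orth = {
                    name.split("|")[0]: seq
                    for name, seq in mio.read_fasta(inp["orthologs"]).items()
                }
                conservation = targets.conservation_check(
                    profiles.SEEDS["ssc-miR-361-3p"], orth
                )
                d = out / "targets"
                d.mkdir(exist_ok=True)
                sites.to_csv(d / "target_sites.csv", index=False, float_format="%.3f")
                per_mirna.to_csv(d / "targets_per_mirna.csv", index=False)
                per_tx.to_csv(d / "mirnas_per_transcript.csv", index=False)
                _write_json(conservation, d / "fshb_site_conservation.json")
                state["sites"] = sites
                state["gene_map"] = gene_map
                state["conservation"] = conservation
                record(
                    stage,
                    {
                        "sites": d / "target_sites.csv",
                        "per_mirna": d / "targets_per_mirna.csv",
                        "per_transcript": d / "mirnas_per_transcript.csv",
                        "conservation": d / "fshb_site_conservation.json",
                    },
                    {
                        "candidates": len(sites),
                        "accepted": int(sites["accepted"].sum()),
                    },
                    {
                        "energy_threshold": config.energy_threshold,
                        "seed_window": list(config.seed_window),
                        "max_gu": config.max_gu,
                    },
                )
            elif stage == "genome_map":
                inp = state["inputs"]
                precursors = mio.read_fasta(inp["precursors"])
                genome_seqs = mio.read_fasta(inp["genome"])
                loci, unmapped = genome.map_precursors(precursors, genome_seqs)
                _, prec_matures = genome.loci_from_gff3(mio.read_gff3(inp["precursor_gff"]))
                if not prec_matures:
                    prec_matures = profiles.precursor_to_matures()
                mature_loci = genome.expand_to_matures(loci, prec_matures)
                mature_loci = genome.relative_positions(mature_loci, genome_seqs)
                clusters = genome.detect_clusters(loci, max_gap=config.cluster_gap)
                chrom_summary = genome.summarize_chromosomes(mature_loci)
                d = out / "genome_map"
                d.mkdir(exist_ok=True)
                mature_loci.to_csv(d / "mature_loci.csv", index=False, float_format="%.4f")
                pd.DataFrame({"unmapped_precursor": unmapped}).to_csv(
                    d / "unmapped.csv", index=False
                )
                cluster_df = pd.DataFrame(
                    {
                        "chromosome": [c.chromosome for c in clusters],
                        "members": [
                            ";".join(l.mirna_name for l in c.members) for c in clusters
                        ],
                        "gaps_bp": [";".join(map(str, c.gaps)) for c in clusters],
                    }
                )
                cluster_df.to_csv(d / "clusters.csv", index=False)
                chrom_summary.to_csv(d / "chromosome_summary.csv", index=False)
                state["mature_loci"] = mature_loci
                state["unmapped"] = unmapped
                state["clusters"] = clusters
                state["chrom_summary"] = chrom_summary
                state["prec_matures"] = prec_matures
                record(
                    stage,
                    {
                        "loci": d / "mature_loci.csv",
                        "unmapped": d / "unmapped.csv",
                        "clusters": d / "clusters.csv",
                        "chromosomes": d / "chromosome_summary.csv",
                    },
                    {
                        "loci": len(mature_loci),
                        "unmapped": len(unmapped),
                        "clusters": len(clusters),
                    },
                    {"cluster_gap": config.cluster_gap},
                )
            elif stage == "enrichment":
                inp = state["inputs"]
                if "sites" not in state:
                    raise ValueError("target prediction must run before enrichment")
                accepted = state["sites"][state["sites"]["accepted"]]
                query = set(accepted["gene_name"])
                gene_sets = enrichment.gene_sets_from_gmt(mio.read_gmt(inp["gmt"]))
                result = enrichment.enrich_pathways(
                    query, gene_sets,
                    min_observed=config.min_observed, fdr=config.fdr,
                )
                d = out / "enrichment"
                d.mkdir(exist_ok=True)
                result.to_csv(d / "enrichment.csv", index=False, float_format="%.6g")
                state["enrichment"] = result
                record(
                    stage,
                    {"enrichment": d / "enrichment.csv"},
                    {"query_genes": len(query), "sets_tested": len(result)},
                    {"min_observed": config.min_observed, "fdr": config.fdr},
                )
        except Exception as exc:  # halt dependents with a clear diagnostic
            raise StageError(stage, str(exc)) from exc
        manifest["stages"].setdefault(stage, {})["runtime_s"] = round(time.time() - t0, 3)

    _write_json(manifest, out / "manifest.json")
    report = write_report(manifest, state, out / "report.md")
    state["report"] = report
    state["manifest"] = manifest
    return manifest


def write_report(manifest: dict, state: dict, path: Path | None = None) -> str:
    """Human-readable run summary tabulating each stage's headline numbers."""
    if not manifest.get("stages"):
        raise ValueError("empty manifest: no stages were run")
    lines = ["# mirfsh run report", ""]

    def section(title: str):
        lines.extend(["## " + title, ""])

    section("Differential expression (array)")
    if "diff_table" in state:
        t = state["diff_table"]
        n_up = int((t["direction"] == "up").sum())
        n_down = int((t["direction"] == "down").sum())
        lines.append(
            f"{n_up + n_down} differentially expressed miRNAs "
            f"({n_up} up, {n_down} down); {len(state['families'])} seed families."
        )
        for _, row in t.iterrows():
            lines.append(
                f"- {row['miRNA']}: fold {row['fold_change_2dp']:.2f} "
                f"({row['direction']}), seed {row['seed']}"
            )
    else:
        lines.append("not run")
    lines.append("")

    section("qPCR validation")
    if state.get("concordance"):
        c = state["concordance"]
        r = c["pearson_r"]
        lines.append(
            f"{c['n_shared']} shared miRNAs: {c['n_significant_concordant']} "
            f"significant-concordant, {c['n_discordant']} discordant, "
            f"{c['n_non_significant']} non-significant."
        )
        if r is not None:
            lines.append(f"Pearson r (log2 array vs log2 RQ) = {r:.3f}.")
    else:
        lines.append("not run")
    lines.append("")

    section("FSH hormone response")
    if "hormone_summary" in state:
        s = state["hormone_summary"]
        for _, row in s[s["baseline"] != ""].iterrows():
            lines.append(
                f"- {row['experiment']}: {row['group']} vs {row['baseline']} "
                f"fold {row['fold_ratio_1dp']:.1f}, "
                f"change {row['percent_change_1dp']:+.1f}%, p = {row['p_value']:.4g}"
            )
    else:
        lines.append("not run")
    lines.append("")

    section("Target prediction")
    if "sites" in state:
        acc = state["sites"][state["sites"]["accepted"]]
        lines.append(
            f"{len(acc)} accepted sites over {acc['gene_name'].nunique()} genes "
            f"and {acc['mirna_name'].nunique()} miRNAs "
            f"(of {len(state['sites'])} seed-match candidates)."
        )
        cons = state.get("conservation")
        if cons:
            lines.append(
                f"miR-361-3p FSHB site: {cons['n_with_site']}/{cons['n_species']} "
                f"species carry the all-WC seed complement "
                f"({'conserved' if cons['conserved'] else 'not conserved'})."
            )
    else:
        lines.append("not run")
    lines.append("")

    section("Genomic mapping")
    if "mature_loci" in state:
        loci = state["mature_loci"]
        mapped = sorted(loci["miRNA"].unique())
        unmapped_prec = state.get("unmapped", [])
        prec_matures = state.get("prec_matures", {})
        unmapped_mirnas = sorted(
            m for p in unmapped_prec for m in prec_matures.get(p, [p])
        )
        lines.append(
            f"{len(mapped)} miRNAs mapped to "
            f"{loci['chromosome'].nunique()} chromosomes; "
            f"{len(unmapped_mirnas)} unmapped ({', '.join(unmapped_mirnas)})."
        )
        for _, row in state["chrom_summary"].iterrows():
            lines.append(f"- {row['chromosome']}: {row['n_mirnas']} miRNAs")
        for c in state.get("clusters", []):
            names = "/".join(l.mirna_name for l in c.members)
            lines.append(
                f"Cluster on {c.chromosome}: {names}, intergenic gap(s) "
                f"{', '.join(map(str, c.gaps))} bp."
            )
    else:
        lines.append("not run")
    lines.append("")

    section("Pathway enrichment")
    if "enrichment" in state:
        e = state["enrichment"]
        sig = e[e["significant"]]
        lines.append(
            f"{len(e)} sets tested (overlap >= "
            f"{manifest['parameters']['min_observed']}); "
            f"{len(sig)} significant at FDR {manifest['parameters']['fdr']}."
        )
        for _, row in e.iterrows():
            lines.append(
                f"- {row['set_id']}: observed {row['observed']}, "
                f"adjusted p = {row['p_adjusted']:.3g}"
                + (" *" if row["significant"] else "")
            )
    else:
        lines.append("not run")
    lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
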