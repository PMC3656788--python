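"""End-to-end orchestration: simulate/quantify/regions/deg/classify/regulons/
motifscan/kinetics, with a manifest for reproducibility.

A run is driven by a :class:`PipelineConfig` (flat YAML: paths, thresholds,
condition order, seed, output directory). Every stage writes its TSV/BED
outputs under the output directory; the manifest records the config hash, the
seed and per-stage row counts, so any output is re-derivable from the manifest
alone. Runs are byte-deterministic under a fixed seed (no timestamps are
written).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coverage_regions, degradome_classification, differential_expression
from . import genome_io, kinetics, motif_tools, regulon_inference, synthetic_data
from .expression_quant import (
    CoverageTrack,
    ExpressionTable,
    compute_nta_table,
    read_coverage_tsv,
    write_coverage_tsv,
)

log = logging.getLogger("degradome")

DEFAULT_THRESHOLDS = {
    "nta_expressed": 1.0,
    "upstream_max_len": 500,
    "min_base_depth": 1,
    "min_region_length": 30,
    "max_region_gap": 0,
    "min_specific_depth": 2.0,
    "deg_ratio_log2": 2.0,
    "deg_floor": 0.01,
    "deg_p_cutoff": 0.05,
    "degradome_ratio_min": 2.0,
    "degradome_p_max": 0.001,
    "motif_p_max": 1e-4,
    "motif_pseudocount": 0.25,
    "group_margin": 0.5,
    "tcs_max_flank": 5,
    "tcs_max_operon_gap": 100,
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    conditions: tuple[str, ...] = synthetic_data.DEFAULT_CONDITIONS
    simulate: synthetic_data.SimulationConfig | None = None
    paths: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    target_condition: str = "Cel"
    reference_conditions: tuple[str, ...] = ("Glu", "Ceb")

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "kinetics_params" in sim:
                sim["kinetics_params"] = synthetic_data.KineticsTruth(**sim["kinetics_params"])
            sim = synthetic_data.SimulationConfig(**sim)
        known = {"outdir", "seed", "conditions", "paths", "thresholds",
                 "target_condition", "reference_conditions"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "reference_conditions" in raw:
            raw["reference_conditions"] = tuple(raw["reference_conditions"])
        return cls(simulate=sim, **raw)

    def validate(self) -> None:
        """Fail fast before any stage runs."""
        if self.simulate is None:
            genome_ok = ("genome_genbank" in self.paths) or (
                "genome_fasta" in self.paths and "genome_gff3" in self.paths
            )
            if not genome_ok:
                raise ValueError("config must provide genome_genbank or "
                                 "genome_fasta + genome_gff3 (or a simulate block)")
            coverage = self.paths.get("coverage", {})
            for cond in self.conditions:
                if cond not in coverage:
                    raise ValueError(f"no coverage path declared for condition {cond}")
            for key, p in [("genome", self.paths.get("genome_genbank")
                            or self.paths.get("genome_fasta"))] + [
                    (c, coverage[c]) for c in self.conditions]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{key}: missing input file {p}")

    def config_hash(self) -> str:
        def default(o: Any) -> Any:
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()


def _fmt_float(x: float) -> str:
    return f"{x:.10g}"


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for k, v in sorted(config.thresholds.items()):
        log.info("threshold %s = %s", k, v)
    manifest: dict[str, Any] = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "conditions": list(config.conditions),
        "stages": {},
        "outputs": [],
    }

    state: dict[str, Any] = {}
    stages = [
        ("simulate", _stage_simulate),
        ("quantify", _stage_quantify),
        ("regions", _stage_regions),
        ("deg", _stage_deg),
        ("classify", _stage_classify),
        ("regulons", _stage_regulons),
        ("motifscan", _stage_motifscan),
        ("kinetics", _stage_kinetics),
    ]
    for name, fn in stages:
        try:
            info = fn(config, out, state)
        except Exception as exc:  # stage failure: record and stop
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            break
        if info is None:
            manifest["stages"][name] = {"status": "skipped"}
        else:
            info["status"] = "ok"
            manifest["stages"][name] = info
            manifest["outputs"].extend(info.get("files", []))
        _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> dict | None:
    if config.simulate is None:
        return None
    sim = config.simulate
    record, truth = synthetic_data.simulate_genome(sim)
    genome_io.write_fasta_gff3(record, out / "genome.fasta", out / "genome.gff3")
    genome_io.write_annotation_table(record, out / "annotation.tsv")
    truth.true_nta.to_csv(out / "truth_nta.tsv", sep="\t", index_label="gene_id")
    with open(out / "truth_groups.tsv", "w") as fh:
        fh.write("gene_id\tgroup\thigh_substrate\n")
        for gid, grp in truth.group_label.items():
            fh.write(f"{gid}\t{grp}\t{truth.high_substrate.get(gid, '')}\n")
    with open(out / "truth_sites.tsv", "w") as fh:
        fh.write(f"# consensus={truth.motif_consensus} seed={sim.seed}\n")
        fh.write("position\tstrand\tsequence\tgene_id\n")
        for s in truth.planted_sites:
            fh.write(f"{s.position}\t{s.strand}\t{s.sequence}\t{s.gene_id}\n")
    files = ["genome.fasta", "genome.gff3", "annotation.tsv", "truth_nta.tsv",
             "truth_groups.tsv", "truth_sites.tsv"]
    tracks: dict[str, CoverageTrack] = {}
    for cond in config.conditions:
        track = synthetic_data.simulate_coverage(record, truth, sim, cond)
        write_coverage_tsv(track, out / f"coverage_{cond}.tsv")
        tracks[cond] = track
        files.append(f"coverage_{cond}.tsv")
    timepoints = np.arange(0.0, 15.0)
    curve = synthetic_data.simulate_degradation_replicates(
        sim.kinetics_params, timepoints, n_replicates=3, seed=sim.seed)
    curve.to_csv(out / "kinetics.tsv", sep="\t", index=False)
    files.append("kinetics.tsv")
    with open(out / "growth.tsv", "w") as fh:
        fh.write("condition\tgrowth_rate\n")
        for c in config.conditions:
            fh.write(f"{c}\t{truth.growth_rates[c]}\n")
    files.append("growth.tsv")
    state["record"], state["truth"], state["tracks"] = record, truth, tracks
    state["kinetics_path"] = out / "kinetics.tsv"
    state["growth"] = {c: truth.growth_rates[c] for c in config.conditions}
    state["motif_sites"] = [s.sequence for s in truth.planted_sites]
    return {"rows": len(record.genes), "files": files}


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    if "record" in state:
        return
    paths = config.paths
    if "genome_genbank" in paths:
        record = genome_io.read_genome_record(
            paths["genome_genbank"], "genbank",
            annotation_table=paths.get("annotation"))
    else:
        record = genome_io.read_genome_record(
            paths["genome_fasta"], "fasta+gff3", gff3=paths["genome_gff3"],
            annotation_table=paths.get("annotation"))
    tracks = {
        cond: read_coverage_tsv(p, condition=cond, genome_length=record.length)
        for cond, p in paths["coverage"].items()
    }
    state["record"], state["tracks"] = record, tracks
    state["kinetics_path"] = paths.get("kinetics")
    if "growth" in paths:
        g = pd.read_csv(paths["growth"], sep="\t")
        state["growth"] = dict(zip(g["condition"], g["growth_rate"]))
    if "motif_sites" in paths:
        state["motif_sites"] = [
            line.strip() for line in open(paths["motif_sites"])
            if line.strip() and not line.startswith((">", "#"))
        ]


def _stage_quantify(config: PipelineConfig, out: Path, state: dict) -> dict:
    _load_inputs(config, state)
    expr = compute_nta_table(state["tracks"], state["record"])
    expr.to_tsv(out / "expression.tsv")
    state["expr"] = expr
    return {"rows": len(expr.genes), "files": ["expression.tsv"]}


def _stage_regions(config: PipelineConfig, out: Path, state: dict) -> dict:
    th = config.thresholds
    per_cond = {
        cond: coverage_regions.call_transcribed_regions(
            track,
            min_base_depth=int(th["min_base_depth"]),
            min_length=int(th["min_region_length"]),
            max_gap=int(th["max_region_gap"]),
        )
        for cond, track in state["tracks"].items()
    }
    classified = coverage_regions.classify_regions(
        per_cond, state["record"], tracks=state["tracks"],
        min_specific_depth=th["min_specific_depth"],
        upstream_window=int(th["upstream_max_len"]),
    )
    coverage_regions.write_regions_tsv(classified, str(out / "regions.tsv"))
    genome_io.write_regions_bed(
        [r.interval for r in classified], out / "regions.bed",
        genome_id=state["record"].id)
    state["regions"] = classified
    return {"rows": len(classified), "files": ["regions.tsv", "regions.bed"]}


def _stage_deg(config: PipelineConfig, out: Path, state: dict) -> dict:
    th = config.thresholds
    expr: ExpressionTable = state["expr"]
    record = state["record"]
    all_results = []
    for a, b in itertools.combinations(config.conditions, 2):
        all_results.extend(
            differential_expression.pairwise_deg(
                expr, a, b, record.length,
                ratio_log2=th["deg_ratio_log2"], floor=th["deg_floor"],
                p_cutoff=th["deg_p_cutoff"],
            )
        )
    differential_expression.deg_results_to_tsv(all_results, str(out / "deg.tsv"))
    state["deg"] = all_results
    return {"rows": len(all_results), "files": ["deg.tsv"]}


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> dict:
    th = config.thresholds
    expr: ExpressionTable = state["expr"]
    record = state["record"]
    target = config.target_condition
    refs = [c for c in config.reference_conditions if c in expr.conditions]
    files = []
    if target in expr.conditions and refs:
        p_matrix = pd.DataFrame(index=expr.genes, columns=refs, dtype=float)
        for r in state["deg"]:
            pair = r.condition_pair
            ref = None
            if pair[0] == target and pair[1] in refs:
                ref = pair[1]
            elif pair[1] == target and pair[0] in refs:
                ref = pair[0]
            if ref is not None:
                p_matrix.loc[r.gene_id, ref] = max(r.p_mars, r.p_fisher, r.p_lrt)
        p_matrix = p_matrix.fillna(1.0)
        degradome, specific = degradome_classification.degradome_membership(
            expr, p_matrix, target, refs,
            nta_min=th["nta_expressed"], ratio_min=th["degradome_ratio_min"],
            p_max=th["degradome_p_max"],
        )
        with open(out / "degradome.tsv", "w") as fh:
            fh.write("gene_id\tin_degradome\tin_specific_degradome\n")
            for gene in expr.genes:
                fh.write(f"{gene}\t{int(gene in degradome)}\t{int(gene in specific)}\n")
        files.append("degradome.tsv")
        state["degradome"] = (degradome, specific)

    zmat = degradome_classification.row_zscore(expr)
    zmat.z.to_csv(out / "zscores.tsv", sep="\t", index_label="gene_id")
    files.append("zscores.tsv")

    cazyme_genes = [g.gene_id for g in record.genes
                    if g.annotations.get("role") == "CAZyme"]
    if len(cazyme_genes) >= 8:
        z_caz = degradome_classification.row_zscore(expr, genes=cazyme_genes)
        groups = degradome_classification.cluster_and_label_groups(
            z_caz, n_clusters=min(7, len(cazyme_genes)), labeling="cazyme_groups",
            margin=th["group_margin"], condition_order=list(config.conditions),
        )
        degradome_classification.assignments_to_tsv(groups, str(out / "cazyme_groups.tsv"))
        files.append("cazyme_groups.tsv")
        state["groups"] = groups
    return {"rows": len(expr.genes), "files": files}


def _stage_regulons(config: PipelineConfig, out: Path, state: dict) -> dict:
    th = config.thresholds
    expr: ExpressionTable = state["expr"]
    record = state["record"]
    lines = ["metric\tunit_a\tunit_b\tvalue\tp"]

    clusters: dict[str, list[str]] = {}
    for g in record.genes:
        c = g.annotations.get("cluster")
        if c:
            clusters.setdefault(c, []).append(g.gene_id)
    core = clusters.get("cip-cel-like", [])
    lfp = clusters.get("lfp-like", [])
    if core and lfp:
        corr = regulon_inference.profile_r2(expr, core, lfp, aggregate="mean")
        lines.append(
            f"cluster_r2\tcip-cel-like\tlfp-like\t{corr.r2:.6g}\t{corr.slope_sign}")
    growth = state.get("growth")
    if core and growth:
        rankable = _rankable_conditions(growth, config.conditions)
        profile = expr.nta.loc[core].mean(axis=0)
        if len(rankable) >= 3:
            rho, p, defined = regulon_inference.growth_anticorrelation(
                profile, growth, rankable_conditions=rankable)
            if defined:
                lines.append(f"growth_spearman\tcip-cel-like\tgrowth\t{rho:.6g}\t{p:.6g}")
    loci = regulon_inference.tcs_locus_scan(
        record, max_flank=int(th["tcs_max_flank"]),
        max_operon_gap=int(th["tcs_max_operon_gap"]))
    regulon_inference.tcs_loci_to_tsv(loci, str(out / "tcs_loci.tsv"))
    with open(out / "regulons.tsv", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    state["tcs_loci"] = loci
    return {"rows": len(loci), "files": ["regulons.tsv", "tcs_loci.tsv"]}


def _rankable_conditions(growth: Mapping[str, float], conditions) -> list[str]:
    """One condition per distinct growth rate (first of each tie group)."""
    seen: set[float] = set()
    out = []
    for c in conditions:
        if c in growth and growth[c] not in seen:
            seen.add(growth[c])
            out.append(c)
    return out


def _stage_motifscan(config: PipelineConfig, out: Path, state: dict) -> dict | None:
    th = config.thresholds
    sites_in = state.get("motif_sites")
    if not sites_in:
        return None
    record = state["record"]
    width = len(sites_in[0])
    pssm = motif_tools.build_palindromic_pssm(
        sites_in, width=width, pseudocount=th["motif_pseudocount"],
        background=motif_tools.genome_background(record))
    motif_tools.write_meme_minimal(pssm, out / "pssm.meme")
    upstream = genome_io.extract_regions(
        record, "upstream", max_len=int(th["upstream_max_len"]))
    hits = motif_tools.scan_regions(upstream, record, pssm, p_max=th["motif_p_max"])
    annotated, separations = motif_tools.map_sites_to_genes(
        hits, record, window=int(th["upstream_max_len"]))
    motif_tools.sites_to_tsv(annotated, out / "motif_sites.tsv")
    motif_tools.sites_to_bed(annotated, out / "motif_sites.bed", genome_id=record.id)
    with open(out / "motif_pair_separations.tsv", "w") as fh:
        fh.write("gene_id\tseparations_bp\n")
        for gene, seps in sorted(separations.items()):
            fh.write(f"{gene}\t{','.join(map(str, seps))}\n")
    state["motif_hits"] = annotated
    return {"rows": len(annotated),
            "files": ["pssm.meme", "motif_sites.tsv", "motif_sites.bed",
                      "motif_pair_separations.tsv"]}


def _stage_kinetics(config: PipelineConfig, out: Path, state: dict) -> dict | None:
    path = state.get("kinetics_path")
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t")
    tcol, dcol = df.columns[:2]
    fit = kinetics.fit_sigmoid_extract(df[tcol].to_numpy(), df[dcol].to_numpy())
    with open(out / "kinetics_fit.tsv", "w") as fh:
        fh.write("K\tr\tt0\tpeak_rate\tlag_time\trss\tconverged\n")
        fh.write(
            f"{fit.K:.6g}\t{fit.r:.6g}\t{fit.t0:.6g}\t{fit.peak_rate:.6g}\t"
            f"{fit.lag_time:.6g}\t{fit.rss:.6g}\t{int(fit.converged)}\n")
    state["kinetics_fit"] = fit
    return {"rows": 1, "files": ["kinetics_fit.tsv"]}
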