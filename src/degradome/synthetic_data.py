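"""Synthetic genomes, coverage, expression structure, motifs and kinetics.

The generator emulates the statistical structure of a multi-substrate
bacterial RNA-Seq experiment on a small circular genome, with ground truth
exposed for every downstream stage: expression groups (Group I follows the
CCR signature — high under glucose/cellulose/xylan/corn-stover, repressed
under cellobiose/xylose, anti-correlated with growth rate; Group II genes are
high under exactly one substrate; Group III under corn stover only; Group IV
and background are flat), a 13-gene cellulosomal "cip-cel-like" cluster, a
14-gene "xyl-doc-like" cluster, three TCS loci (one per locus category),
planted 16-nt palindromic upstream motifs with a fixed central CG, per-base
coverage from 36-base uniquely-mapped reads with negative-binomial gene
counts, and noisy logistic degradation curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeRecord, reverse_complement
from .expression_quant import CoverageTrack
from .motif_tools import center_columns

DEFAULT_CONDITIONS = ("Glu", "Ceb", "Xyl", "Cel", "Xyn", "CS")

#: growth-rate defaults (1/h) with the ordering Ceb > Xyl > Xyn > Cel = CS = Glu
DEFAULT_GROWTH_RATES = {
    "Ceb": 0.42, "Xyl": 0.35, "Xyn": 0.28, "Cel": 0.20, "CS": 0.20, "Glu": 0.20,
}


@dataclass
class KineticsTruth:
    K: float = 6.0  # g/L degradable cellulose
    r: float = 1.0  # 1/day
    t0: float = 5.0  # day of peak rate
    noise_sd: float = 0.1  # g/L


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 200
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    group_fractions: dict = field(
        default_factory=lambda: {"I": 0.10, "II": 0.10, "III": 0.07,
                                 "IV": 0.08, "background": 0.65}
    )
    asd_per_condition: float | Mapping[str, float] = 20.0
    growth_rates: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_RATES))
    read_length: int = 36
    dispersion: float = 0.01  # negative-binomial overdispersion (var = mu + a*mu^2)
    motif_width: int = 16
    motif_center: str = "CG"
    motif_rate: float = 0.5  # fraction of Group-I genes with a planted upstream site
    site_fidelity: float = 0.97  # per-position probability of the consensus base
    kinetics_params: KineticsTruth = field(default_factory=KineticsTruth)
    effect_size: float = 8.0  # high/low NTA ratio between induced and repressed
    baseline_sigma: float = 0.6  # lognormal per-gene expression-level spread
    gc_content: float = 0.374
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_gap_range: tuple[int, int] = (50, 400)
    background_noise_depth: float = 0.0  # intergenic Poisson leak depth

    def __post_init__(self) -> None:
        total = sum(self.group_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("group_fractions must sum to 1")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if any(r <= 0 for r in self.growth_rates.values()):
            raise ValueError("growth rates must be positive")

    def asd_for(self, condition: str) -> float:
        if isinstance(self.asd_per_condition, Mapping):
            return float(self.asd_per_condition[condition])
        return float(self.asd_per_condition)


@dataclass
class PlantedSite:
    position: int  # 0-based start, + strand coordinates
    strand: str
    sequence: str  # strand-oriented
    gene_id: str


@dataclass
class SimTruth:
    group_label: dict[str, str]
    high_substrate: dict[str, str]  # Group II gene -> its induced substrate
    true_nta: pd.DataFrame
    planted_sites: list[PlantedSite]
    motif_consensus: str
    kinetics: KineticsTruth
    tcs_loci: list[tuple[str, list[str]]]  # (category, locus gene ids)
    growth_rates: dict[str, float]


def motif_consensus(width: int = 16) -> str:
    """A reverse-complement-palindromic consensus with the fixed central CG."""
    c_col, _ = center_columns(width)
    left_len = c_col
    right_len = width - left_len - 2
    pattern = "AAGTTATAAGTTATAAGTTAT"
    left = pattern[:left_len]
    right = reverse_complement(left)
    right = (right + "A" * right_len)[:right_len]
    return left + "CG" + right


# gene-plan entry: (group, role, cluster, cellulosomal, block_gap_class)
_OPERON_GAP = (20, 80)  # within-operon spacing
_UNIT_GAP = (150, 400)  # spacing that breaks an operon (gap > 100)


def _group_profile(group: str, high: str | None, conditions: Sequence[str],
                   effect: float) -> dict[str, float]:
    prof = {c: 1.0 for c in conditions}
    if group == "I":
        levels = {"Glu": effect, "Cel": effect, "Xyn": effect / 2,
                  "CS": effect, "Xyl": effect / 4, "Ceb": 1.0}
        for c in conditions:
            prof[c] = levels.get(c, 1.0)
    elif group == "II" and high is not None:
        prof[high] = effect
    elif group == "III":
        if "CS" in prof:
            prof["CS"] = effect
    elif group == "anti":  # LacI-family repressor pair: linear anti to Group I
        levels = {"Glu": effect, "Cel": effect, "Xyn": effect / 2,
                  "CS": effect, "Xyl": effect / 4, "Ceb": 1.0}
        for c in conditions:
            prof[c] = 1.0 + effect - levels.get(c, 1.0)
    elif group == "low":  # constitutive low (TCS operon itself)
        prof = {c: 0.3 for c in conditions}
    return prof


def simulate_genome(config: SimulationConfig) -> tuple[GenomeRecord, SimTruth]:
    """Generate a genome record plus full ground truth, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    conds = list(config.conditions)

    # --- gene plan ------------------------------------------------------
    # special blocks; entries: (group, role, cluster, cellulosomal, gap_before)
    blocks: list[list[tuple]] = []
    blocks.append([("I", "CAZyme", "cip-cel-like", True,
                    "unit" if k == 0 else "operon") for k in range(13)])
    blocks.append([("III", "CAZyme", "xyl-doc-like", True,
                    "unit" if k == 0 else "operon") for k in range(14)])
    # TCS locus A (category I): CAZyme | ABC x3 | SBP + sensor + regulator
    locus_a = [("II:Cel", "CAZyme", "tcs-a", False, "unit"),
               ("II:Cel", "ABC", "tcs-a", False, "unit"),
               ("II:Cel", "ABC", "tcs-a", False, "operon"),
               ("II:Cel", "ABC", "tcs-a", False, "operon"),
               ("low", "SBP", "tcs-a", False, "unit"),
               ("low", "TCS_sensor", "tcs-a", False, "operon"),
               ("low", "TCS_regulator", "tcs-a", False, "operon")]
    blocks.append(locus_a)
    # TCS locus B (category II): CAZyme inside the TCS operon
    blocks.append([("low", "TCS_sensor", "tcs-b", False, "unit"),
                   ("low", "TCS_regulator", "tcs-b", False, "operon"),
                   ("II:Xyn", "CAZyme", "tcs-b", False, "operon")])
    # TCS locus C (category III): bare sensor + regulator pair
    blocks.append([("low", "TCS_sensor", "tcs-c", False, "unit"),
                   ("low", "TCS_regulator", "tcs-c", False, "operon")])
    # LacI-family repressor pair anti-correlated with the Group-I profile
    blocks.append([("anti", "other", "lfp-like", False, "unit"),
                   ("anti", "other", "lfp-like", False, "operon")])

    n_special = sum(len(b) for b in blocks)
    if n < n_special + 10:
        raise ValueError(f"n_genes={n} too small for the fixed locus layout "
                         f"({n_special} special genes)")

    frac = config.group_fractions
    n_i = max(13, round(frac["I"] * n))
    n_ii = max(5, round(frac["II"] * n))
    n_iii = max(14, round(frac["III"] * n))
    n_iv = round(frac["IV"] * n)
    scattered: list[tuple] = []
    for _ in range(n_i - 13):
        scattered.append(("I", "CAZyme", "", True, "unit"))
    substrate_cycle = [c for c in ("Cel", "Ceb", "Xyl", "Xyn") if c in conds] or conds
    for k in range(n_ii - 5):  # 5 Group-II genes already live in the TCS loci
        sub = substrate_cycle[k % len(substrate_cycle)]
        scattered.append((f"II:{sub}", "CAZyme", "", False, "unit"))
    for _ in range(n_iii - 14):
        scattered.append(("III", "CAZyme", "", True, "unit"))
    for _ in range(n_iv):
        scattered.append(("IV", "CAZyme", "", False, "unit"))
    n_bg = n - n_special - len(scattered)
    for _ in range(n_bg):
        scattered.append(("background", "other", "", False, "unit"))
    order = rng.permutation(len(scattered))
    scattered = [scattered[i] for i in order]

    # interleave the blocks at deterministic offsets through the scattered list
    plan: list[tuple] = []
    insert_every = max(1, len(scattered) // (len(blocks) + 1))
    si = 0
    for b, block in enumerate(blocks):
        take = min(insert_every, len(scattered) - si)
        plan.extend(scattered[si : si + take])
        si += take
        plan.extend(block)
    plan.extend(scattered[si:])

    # --- layout ---------------------------------------------------------
    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.intergenic_gap_range
    genes: list[GeneModel] = []
    truth_group: dict[str, str] = {}
    high_substrate: dict[str, str] = {}
    pos = int(rng.integers(lo_gap, hi_gap + 1))
    prev_cluster = ""
    for idx, (group, role, cluster, cello, gap_class) in enumerate(plan):
        if genes:
            if gap_class == "operon":
                gap = int(rng.integers(*_OPERON_GAP))
            elif cluster or prev_cluster:
                # block boundaries must break operon adjacency
                gap = int(rng.integers(*_UNIT_GAP))
            else:
                gap = int(rng.integers(lo_gap, hi_gap + 1))
            pos = genes[-1].end + gap
        length = int(rng.integers(lo_len, hi_len + 1))
        if cluster:
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SYN_{idx + 1:04d}"
        if pos + length > config.genome_length:
            raise ValueError(
                f"genome_length={config.genome_length} too short for "
                f"{config.n_genes} genes with the configured lengths and gaps"
            )
        ann = {"role": role, "cluster": cluster, "cellulosomal": cello,
               "cazy_family": "GH" if role == "CAZyme" else ""}
        genes.append(GeneModel(gene_id, pos, pos + length, strand, "CDS", ann))
        if group.startswith("II:"):
            truth_group[gene_id] = "II"
            high_substrate[gene_id] = group.split(":", 1)[1]
        elif group in ("anti", "low"):
            truth_group[gene_id] = "background"
        else:
            truth_group[gene_id] = group
        ann["sim_profile"] = group
        prev_cluster = cluster

    # --- sequence -------------------------------------------------------
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.genome_length,
                     p=base_p)

    # --- planted motifs --------------------------------------------------
    consensus = motif_consensus(config.motif_width)
    w = config.motif_width
    group_i_genes = [g for g in genes if truth_group[g.gene_id] == "I"]
    n_sites = math.ceil(config.motif_rate * len(group_i_genes))
    # prefer genes whose upstream gap comfortably holds a site
    def upstream_room(g: GeneModel) -> int:
        gi = genes.index(g)
        if g.strand == "+":
            prev_end = genes[gi - 1].end if gi > 0 else 0
            return g.start - prev_end
        next_start = genes[gi + 1].start if gi + 1 < len(genes) else config.genome_length
        return next_start - g.end

    candidates = sorted(group_i_genes, key=upstream_room, reverse=True)[:n_sites]
    candidates.sort(key=lambda g: g.start)  # deterministic planting order
    planted: list[PlantedSite] = []
    for g in candidates:
        room = upstream_room(g)
        if room < w + 8:
            raise ValueError("intergenic gaps too small to plant motif sites")
        site = _sample_site(rng, consensus, config.site_fidelity, w)
        offset = int(rng.integers(5, min(100, room - w - 2) + 1))
        if g.strand == "+":
            start = g.start - offset - w
            seq[start : start + w] = np.frombuffer(site.encode(), dtype="S1")
        else:
            start = g.end + offset
            seq[start : start + w] = np.frombuffer(
                reverse_complement(site).encode(), dtype="S1")
        planted.append(PlantedSite(start, g.strand, site, g.gene_id))

    record = GenomeRecord(
        id=f"synthetic_{config.seed}",
        sequence=seq.tobytes().decode(),
        circular=True,
        genes=genes,
        source_format="fasta+gff3",
    )

    # --- expression truth -------------------------------------------------
    raw = pd.DataFrame(index=[g.gene_id for g in genes], columns=conds, dtype=float)
    for g in genes:
        profile_key = g.annotations["sim_profile"]
        if profile_key.startswith("II:"):
            prof = _group_profile("II", profile_key.split(":", 1)[1], conds,
                                  config.effect_size)
        else:
            prof = _group_profile(profile_key, None, conds, config.effect_size)
        baseline = float(rng.lognormal(0.0, config.baseline_sigma))
        raw.loc[g.gene_id] = pd.Series(prof) * baseline
    lengths = np.array([g.length for g in genes], dtype=float)
    # column scaling so that the gene-length-weighted mean NTA is exactly 1
    for c in conds:
        total = float((raw[c].to_numpy() * lengths).sum())
        raw[c] *= config.genome_length / total

    tcs_loci = [
        ("I", [g.gene_id for g in genes if g.annotations["cluster"] == "tcs-a"
               and g.annotations["role"] in ("SBP", "TCS_sensor", "TCS_regulator")]),
        ("II", [g.gene_id for g in genes if g.annotations["cluster"] == "tcs-b"]),
        ("III", [g.gene_id for g in genes if g.annotations["cluster"] == "tcs-c"]),
    ]
    truth = SimTruth(
        group_label=truth_group,
        high_substrate=high_substrate,
        true_nta=raw,
        planted_sites=planted,
        motif_consensus=consensus,
        kinetics=config.kinetics_params,
        tcs_loci=tcs_loci,
        growth_rates=dict(config.growth_rates),
    )
    return record, truth


def _sample_site(rng: np.random.Generator, consensus: str, fidelity: float,
                 width: int) -> str:
    c_col, g_col = center_columns(width)
    out = []
    for j, base in enumerate(consensus):
        if j in (c_col, g_col):
            out.append(base)  # fixed central CG
        elif rng.random() < fidelity:
            out.append(base)
        else:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(out)


def simulate_coverage(
    record: GenomeRecord,
    truth: SimTruth,
    config: SimulationConfig,
    condition: str,
) -> CoverageTrack:
    """Per-base depth from 36-base reads with negative-binomial gene counts.

    Per-gene read counts are NB-distributed with mean TA * length / read
    length, where TA = true NTA x configured ASD; read starts are uniform
    within the gene and reads never span gene boundaries.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = list(config.conditions).index(condition)
    rng = np.random.default_rng([config.seed, 7919, cond_idx])
    asd = config.asd_for(condition)
    L = record.length
    rl = config.read_length
    delta = np.zeros(L + 1, dtype=np.int64)
    for g in record.genes:
        nta = float(truth.true_nta.loc[g.gene_id, condition])
        mu = nta * asd * g.length / rl
        if mu <= 0:
            continue
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
            count = int(rng.poisson(lam))
        else:
            count = int(rng.poisson(mu))
        if count == 0:
            continue
        span = g.length - rl
        if span <= 0:
            starts = np.full(count, g.start)
            ends = np.full(count, g.end)
        else:
            starts = rng.integers(g.start, g.start + span + 1, size=count)
            ends = starts + rl
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
    depth = np.cumsum(delta[:-1])
    if config.background_noise_depth > 0:
        gene_mask = np.zeros(L, dtype=bool)
        for g in record.genes:
            gene_mask[g.start : g.end] = True
        leak = rng.poisson(config.background_noise_depth, size=L)
        depth = depth + np.where(gene_mask, 0, leak)
    return CoverageTrack(condition, depth.astype(np.int64), record.id)


def simulate_degradation_curve(
    params: KineticsTruth,
    timepoints: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy logistic degradation measurements (day, degraded g/L)."""
    t = np.asarray(timepoints, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")
    rng = np.random.default_rng([seed, 104729])
    d = params.K / (1.0 + np.exp(-params.r * (t - params.t0)))
    if params.noise_sd > 0:
        d = d + rng.normal(0.0, params.noise_sd, size=t.size)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame({"day": t, "degraded_g_per_L": d})


def simulate_degradation_replicates(
    params: KineticsTruth,
    timepoints: Sequence[float],
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated degradation measurements, long format (day, degraded, replicate).

    Degradation curves are fitted on pooled biological replicates; three
    replicates per condition is the experimental design emulated here.
    """
    frames = []
    for rep in range(n_replicates):
        df = simulate_degradation_curve(params, timepoints, seed=(seed * 97 + rep))
        df["replicate"] = rep + 1
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
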