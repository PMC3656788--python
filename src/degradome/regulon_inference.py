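"""Co-expression and regulator-target linkage.

Two regulatory signatures are quantified. The carbon catabolite repression
(CCR) signature is an anti-correlation between a gene group's expression and
the culture growth rate across substrates (preferred sugars repress the core
cellulosomal genes). Two-component system (TCS) regulation shows up as genomic
loci where a sensor-kinase/response-regulator pair sits next to CAZyme and
sugar ABC-transporter genes whose expression tracks a single substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_quant import ExpressionTable, exact_spearman_p
from .genome_io import GeneModel, GenomeRecord


@dataclass
class ProfileCorrelation:
    unit_a: str
    unit_b: str
    r2: float
    slope_sign: str
    n_conditions: int
    defined: bool = True


@dataclass
class TcsLocus:
    genes: list[str]
    category: str  # I (SBP in operon) | II (CAZyme in operon) | III (TCS alone)
    sensors: list[str] = field(default_factory=list)
    regulators: list[str] = field(default_factory=list)
    flanking_cazymes: list[str] = field(default_factory=list)
    flanking_abc: list[str] = field(default_factory=list)


def _pearson_profile(a: np.ndarray, b: np.ndarray, name_a: str, name_b: str
                     ) -> ProfileCorrelation:
    n = a.size
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return ProfileCorrelation(name_a, name_b, float("nan"), ".", n, defined=False)
    r = float(np.corrcoef(a, b)[0, 1])
    return ProfileCorrelation(name_a, name_b, r * r, "+" if r >= 0 else "-", n)


def profile_r2(
    expr: ExpressionTable | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    aggregate: str = "mean",
    log: bool = False,
    log_floor: float = 0.01,
) -> ProfileCorrelation | list[ProfileCorrelation]:
    """Squared Pearson correlation of expression profiles across conditions.

    ``aggregate='mean'`` correlates the per-condition mean NTA of the two
    groups; ``aggregate='none'`` returns every pairwise gene-gene correlation.
    Raw NTA by default; ``log=True`` correlates log10 values with zeros floored.
    """
    nta = expr.nta if isinstance(expr, ExpressionTable) else expr
    if not group_a or not group_b:
        raise ValueError("gene groups must be non-empty")
    if nta.shape[1] < 3:
        raise ValueError("need at least 3 shared conditions")
    sub_a = nta.loc[list(group_a)].to_numpy(dtype=float)
    sub_b = nta.loc[list(group_b)].to_numpy(dtype=float)
    if log:
        sub_a = np.log10(np.where(sub_a > 0, sub_a, log_floor))
        sub_b = np.log10(np.where(sub_b > 0, sub_b, log_floor))
    if aggregate == "mean":
        return _pearson_profile(
            sub_a.mean(axis=0), sub_b.mean(axis=0),
            "+".join(group_a), "+".join(group_b),
        )
    if aggregate == "none":
        out = []
        for ga, row_a in zip(group_a, sub_a):
            for gb, row_b in zip(group_b, sub_b):
                out.append(_pearson_profile(row_a, row_b, ga, gb))
        return out
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def growth_anticorrelation(
    expr_profile: Mapping[str, float] | pd.Series,
    growth: Mapping[str, float] | pd.Series,
    rankable_conditions: Sequence[str] | None = None,
    alternative: str = "less",
) -> tuple[float, float, bool]:
    """Spearman correlation between an expression profile and growth rates.

    Conditions with tied growth (e.g. equally slow substrates) can be excluded
    via ``rankable_conditions``. Returns (rho, p, defined); the p-value is an
    exact permutation tail for n <= 8 (one-sided 'less' by default, the CCR
    direction), asymptotic otherwise.
    """
    profile = pd.Series(expr_profile, dtype=float)
    growth_s = pd.Series(growth, dtype=float)
    conds = list(rankable_conditions) if rankable_conditions is not None else [
        c for c in profile.index if c in growth_s.index
    ]
    if len(conds) < 3:
        raise ValueError("need at least 3 rankable conditions")
    x = profile[conds].to_numpy()
    y = growth_s[conds].to_numpy()
    if np.unique(y).size == 1:
        return float("nan"), float("nan"), False
    rho = float(stats.spearmanr(x, y).statistic)
    if len(conds) <= 8:
        p = exact_spearman_p(len(conds), rho, alternative=alternative)
    else:
        p = float(stats.spearmanr(x, y, alternative=alternative).pvalue)
    return rho, p, True


TCS_ROLES = ("TCS_sensor", "TCS_regulator")


def _operon_members(genes: list[GeneModel], i: int, j: int, max_gap: int) -> tuple[int, int]:
    """Extend the run [i, j] of gene indices to the full same-strand operon."""
    strand = genes[i].strand
    lo, hi = i, j
    while lo > 0 and genes[lo - 1].strand == strand and \
            genes[lo].start - genes[lo - 1].end <= max_gap:
        lo -= 1
    while hi + 1 < len(genes) and genes[hi + 1].strand == strand and \
            genes[hi + 1].start - genes[hi].end <= max_gap:
        hi += 1
    return lo, hi


def tcs_locus_scan(
    record: GenomeRecord,
    max_flank: int = 5,
    max_operon_gap: int = 100,
) -> list[TcsLocus]:
    """Locate TCS loci and classify them by operon content.

    A locus seeds on an adjacent same-strand sensor + regulator pair; the
    operon is extended over same-strand neighbors with intergenic gaps up to
    ``max_operon_gap``. Category I when the operon also carries a sugar-binding
    protein (SBP) gene, II when it carries a CAZyme, III otherwise. CAZyme and
    ABC-transporter genes within ``max_flank`` genes on either side are
    collected as the putative regulon. Output is sorted by locus start, so it
    is invariant to gene input order and stable under rotation of a circular
    record.
    """
    genes = record.genes  # already position-sorted
    roles = [g.annotations.get("role", "other") for g in genes]
    loci: list[TcsLocus] = []
    used: set[int] = set()
    for i in range(len(genes) - 1):
        pair = {roles[i], roles[i + 1]}
        if pair != set(TCS_ROLES):
            continue
        if genes[i].strand != genes[i + 1].strand:
            continue
        if genes[i + 1].start - genes[i].end > max_operon_gap:
            continue
        if i in used or (i + 1) in used:
            continue
        lo, hi = _operon_members(genes, i, i + 1, max_operon_gap)
        used.update(range(lo, hi + 1))
        operon = genes[lo : hi + 1]
        operon_roles = [g.annotations.get("role", "other") for g in operon]
        if "SBP" in operon_roles:
            category = "I"
        elif "CAZyme" in operon_roles:
            category = "II"
        else:
            category = "III"
        n = len(genes)
        flank_idx: list[int] = []
        for off in range(1, max_flank + 1):
            left = lo - off
            right = hi + off
            if record.circular:
                flank_idx.extend([left % n, right % n])
            else:
                if left >= 0:
                    flank_idx.append(left)
                if right < n:
                    flank_idx.append(right)
        flank_idx = [ix for ix in dict.fromkeys(flank_idx) if not lo <= ix <= hi]
        loci.append(
            TcsLocus(
                genes=[g.gene_id for g in operon],
                category=category,
                sensors=[g.gene_id for g, r in zip(operon, operon_roles)
                         if r == "TCS_sensor"],
                regulators=[g.gene_id for g, r in zip(operon, operon_roles)
                            if r == "TCS_regulator"],
                flanking_cazymes=sorted(
                    genes[ix].gene_id for ix in flank_idx if roles[ix] == "CAZyme"
                ),
                flanking_abc=sorted(
                    genes[ix].gene_id for ix in flank_idx if roles[ix] == "ABC"
                ),
            )
        )
    loci.sort(key=lambda l: record.gene(l.genes[0]).start)
    return loci


def tcs_loci_to_tsv(loci: Sequence[TcsLocus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("category\tgenes\tsensors\tregulators\tflanking_cazymes\tflanking_abc\n")
        for l in loci:
            fh.write(
                f"{l.category}\t{','.join(l.genes)}\t{','.join(l.sensors)}\t"
                f"{','.join(l.regulators)}\t{','.join(l.flanking_cazymes)}\t"
                f"{','.join(l.flanking_abc)}\n"
            )
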