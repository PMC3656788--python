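"""Degradome membership, Row Z-scores, expression classes and enrichment.

The "degradome" of a target substrate is the set of genes expressed (NTA > 1)
under it; the substrate-specific degradome additionally requires a >2-fold NTA
ratio and p < 0.001 against every reference substrate. Expression classes come
from hierarchical clustering of Row Z-scores; clusters are labeled either by
the condition maximizing their mean NTA (C-classes) or by the CAZyme group
rule set (Group I: high under Glu/Cel/Xyn/CS versus Ceb/Xyl, the CCR
signature; Group II: high under exactly one substrate; Group III: corn-stover
dominant; Group IV: the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression_quant import ExpressionTable


@dataclass
class ZscoreMatrix:
    z: pd.DataFrame
    zero_variance_genes: list[str] = field(default_factory=list)


@dataclass
class GeneClassAssignment:
    gene_id: str
    class_label: str
    max_condition: str
    subclass: str | None = None


@dataclass
class EnrichmentResult:
    term_id: str
    set_count: int
    set_size: int
    term_count: int
    universe_size: int
    p: float
    q: float
    representation_ratio: float


def degradome_membership(
    expr: ExpressionTable,
    p_matrix: pd.DataFrame,
    target: str,
    refs: Sequence[str],
    nta_min: float = 1.0,
    ratio_min: float = 2.0,
    p_max: float = 0.001,
) -> tuple[set[str], set[str]]:
    """Degradome and target-specific degradome gene sets.

    ``p_matrix`` holds, per gene (rows) and reference condition (columns), the
    p-value of the target-vs-reference differential expression call (the
    maximum of the three consensus test p-values). Membership uses strict
    inequalities throughout: NTA > nta_min, ratio > ratio_min, p < p_max.
    """
    if target in refs:
        raise ValueError("target condition cannot be its own reference")
    nta_t = expr.nta[target]
    degradome = set(nta_t.index[nta_t > nta_min])
    specific: set[str] = set()
    for gene in degradome:
        ok = True
        for ref in refs:
            nta_r = expr.nta.loc[gene, ref]
            ratio_ok = nta_r == 0 or (nta_t[gene] / nta_r) > ratio_min
            if nta_r == 0 and nta_t[gene] == 0:
                ratio_ok = False
            p_ok = gene in p_matrix.index and p_matrix.loc[gene, ref] < p_max
            if not (ratio_ok and p_ok):
                ok = False
                break
        if ok:
            specific.add(gene)
    return degradome, specific


def row_zscore(
    expr: ExpressionTable | pd.DataFrame,
    genes: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
    ddof: int = 1,
) -> ZscoreMatrix:
    """Per-gene standardization of NTA across conditions (sample SD).

    Zero-variance rows become all-zero and are flagged rather than dropped.
    """
    nta = expr.nta if isinstance(expr, ExpressionTable) else expr
    if genes is not None:
        nta = nta.loc[list(genes)]
    if conditions is not None:
        nta = nta[list(conditions)]
    if nta.shape[1] < 2:
        raise ValueError("row z-scores need at least 2 conditions")
    mean = nta.mean(axis=1)
    sd = nta.std(axis=1, ddof=ddof)
    flat = sd.index[sd == 0].tolist()
    sd = sd.replace(0.0, np.nan)
    z = nta.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
    return ZscoreMatrix(z=z, zero_variance_genes=flat)


#: default condition sets for the CAZyme group rules (CCR-high vs CCR-repressed)
CCR_HIGH = ("Glu", "Cel", "Xyn", "CS")
CCR_LOW = ("Ceb", "Xyl")
CS_CONDITION = "CS"
SINGLE_SUBSTRATES = ("Cel", "Ceb", "Xyl", "Xyn")


def _label_group(mean_z: pd.Series, margin: float) -> str:
    conds = list(mean_z.index)
    high = [c for c in CCR_HIGH if c in conds]
    low = [c for c in CCR_LOW if c in conds]
    # CCR signature: every repressing-sugar condition below every induced one,
    # not just on average (a single induced substrate must not qualify)
    if (high and low
            and mean_z[high].mean() - mean_z[low].mean() >= margin
            and mean_z[high].min() > mean_z[low].max()):
        return "I"
    top = mean_z.idxmax()
    rest = mean_z.drop(top)
    # "high under exactly one substrate" demands clear dominance: flat genes
    # carry a mild anti-depth compositional echo (higher NTA under conditions
    # with less total transcription), so the runner-up must trail decisively
    dominant = (mean_z[top] - rest.mean() >= margin
                and mean_z[top] - rest.max() >= 2 * margin)
    if top == CS_CONDITION and dominant:
        return "III"
    if top in SINGLE_SUBSTRATES and dominant:
        return "II"
    return "IV"


def cluster_and_label_groups(
    zmat: ZscoreMatrix | pd.DataFrame,
    n_clusters: int,
    labeling: str = "by_max_condition",
    expr: ExpressionTable | pd.DataFrame | None = None,
    linkage_method: str = "average",
    metric: str = "correlation",
    margin: float = 0.5,
    condition_order: Sequence[str] | None = None,
) -> list[GeneClassAssignment]:
    """Hierarchical clustering of Row Z-scores plus cluster labeling.

    ``by_max_condition`` labels clusters C1, C2, ... in the given condition
    order, by the condition maximizing the cluster's mean NTA (``expr``
    required); ``cazyme_groups`` applies the Group I-IV rule set to the
    cluster-mean z-profile with contrast ``margin``. Ties in max-condition
    labeling break by the configured condition order, so labels are invariant
    to gene input order.
    """
    z = zmat.z if isinstance(zmat, ZscoreMatrix) else zmat
    if n_clusters > len(z):
        raise ValueError("more clusters requested than genes")
    order = list(condition_order or z.columns)
    # correlation distance is undefined for flat rows; give them a tiny slope
    values = z.to_numpy(dtype=float).copy()
    flat = values.std(axis=1) == 0
    if flat.any() and metric == "correlation":
        values[flat] += np.linspace(0.0, 1e-9, values.shape[1])
    dist = pdist(values, metric=metric)
    tree = hierarchy.linkage(dist, method=linkage_method)
    labels = hierarchy.fcluster(tree, t=n_clusters, criterion="maxclust")

    assignments: list[GeneClassAssignment] = []
    cluster_ids = sorted(set(labels))
    if labeling == "by_max_condition":
        if expr is None:
            raise ValueError("by_max_condition labeling requires expr")
        nta = expr.nta if isinstance(expr, ExpressionTable) else expr
        nta = nta.loc[z.index, order]
        cluster_label: dict[int, tuple[str, str]] = {}
        next_c = 1
        # deterministic: clusters ranked by first max condition in order
        ranked = []
        for cid in cluster_ids:
            members = z.index[labels == cid]
            means = nta.loc[members].mean(axis=0)
            best = max(order, key=lambda c: (means[c], -order.index(c)))
            ranked.append((cid, best, means[best]))
        ranked.sort(key=lambda t: order.index(t[1]))
        for cid, best, _ in ranked:
            cluster_label[cid] = (f"C{next_c}", best)
            next_c += 1
        for gene, cid in zip(z.index, labels):
            lab, best = cluster_label[cid]
            sub = None
            # secondary-condition subclass: positive z under a non-max condition
            zrow = z.loc[gene]
            secondary = [c for c in order if c != best and zrow[c] > 0]
            if secondary:
                sub = f"{lab}-{secondary[0]}-high"
            assignments.append(GeneClassAssignment(gene, lab, best, sub))
    elif labeling == "cazyme_groups":
        cluster_label2: dict[int, str] = {}
        for cid in cluster_ids:
            members = z.index[labels == cid]
            mean_z = z.loc[members, order].mean(axis=0)
            cluster_label2[cid] = _label_group(mean_z, margin)
        for gene, cid in zip(z.index, labels):
            zrow = z.loc[gene, order]
            assignments.append(
                GeneClassAssignment(gene, cluster_label2[cid], str(zrow.idxmax()))
            )
    else:
        raise ValueError(f"unknown labeling {labeling!r}")
    return assignments


#: preset matching the COG screen that drops classes with <20 expressed genes
MIN_TERM_COUNT_COG = 20


def enrichment_test(
    gene_set: Iterable[str],
    term_table: pd.DataFrame | Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    min_count: int = 5,
) -> list[EnrichmentResult]:
    """Flat-term hypergeometric over-representation with BH correction.

    ``term_table`` is either a DataFrame with ``gene_id`` and ``term_id``
    columns or a mapping gene -> terms. The universe defaults to all genes
    carrying at least one term; terms with fewer than ``min_count`` members in
    the universe are skipped.
    """
    if isinstance(term_table, pd.DataFrame):
        pairs = list(zip(term_table["gene_id"], term_table["term_id"]))
    else:
        pairs = [(g, t) for g, ts in term_table.items() for t in ts]
    gene_terms: dict[str, set[str]] = {}
    for g, t in pairs:
        gene_terms.setdefault(g, set()).add(t)
    universe_set = set(universe) if universe is not None else set(gene_terms)
    if not universe_set:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe_set
    if not gene_set:
        return []

    term_members: dict[str, set[str]] = {}
    for g in universe_set:
        for t in gene_terms.get(g, ()):
            term_members.setdefault(t, set()).add(g)

    M = len(universe_set)
    n = len(gene_set)
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        if K < min_count:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        ratio = (k / n) / (K / M)
        rows.append((term, k, n, K, M, p, ratio))
    if not rows:
        return []
    qvals = stats.false_discovery_control([r[5] for r in rows], method="bh")
    return [
        EnrichmentResult(term, k, n, K, M, p, float(q), ratio)
        for (term, k, n, K, M, p, ratio), q in zip(rows, qvals)
    ]


def assignments_to_tsv(assignments: Sequence[GeneClassAssignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass_label\tmax_condition\tsubclass\n")
        for a in assignments:
            fh.write(f"{a.gene_id}\t{a.class_label}\t{a.max_condition}\t{a.subclass or ''}\n")
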