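"""Palindromic operator-motif PSSMs with exact p-values and region scanning.

LacI-family regulators bind palindromic operators (cre-like sites); the
conserved CG dinucleotide at the motif center is enforced as a model
constraint: the two central columns of the position probability matrix are
overridden so that C and then G carry essentially all the probability mass.
Scan p-values are exact under an i.i.d. background: the null score
distribution is computed by positionwise convolution over scores discretized
at 1/100 bit, and every window whose survival probability is at or below the
threshold is reported.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GenomeRecord, GenomicRegion, region_sequence, reverse_complement

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def center_columns(width: int) -> tuple[int, int]:
    """The two central columns constrained to C then G.

    Even widths use the middle pair; odd widths place the pair at
    (w//2 - 1, w//2).
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    return (width // 2 - 1, width // 2)


@dataclass
class Pssm:
    probs: np.ndarray  # 4 x width, rows in ACGT order
    background: np.ndarray
    pseudocount: float = 0.25
    fixed_center: bool = True

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probs must be 4 x width")
        if not np.allclose(self.probs.sum(axis=0), 1.0):
            raise ValueError("each PSSM column must sum to 1")
        if self.fixed_center:
            c_col, g_col = center_columns(self.width)
            if self.probs[:, c_col].argmax() != _INDEX["C"]:
                raise ValueError("fixed-center PSSM must have C as the modal base "
                                 f"in column {c_col}")
            if self.probs[:, g_col].argmax() != _INDEX["G"]:
                raise ValueError("fixed-center PSSM must have G as the modal base "
                                 f"in column {g_col}")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(prob / background) per cell, in bits."""
        return np.log2(self.probs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))


@dataclass
class MotifSite:
    position: int  # 0-based start on the + strand
    strand: str
    score: float  # bits
    p: float
    sequence: str  # strand-oriented matched sequence
    assigned_gene: str | None = None
    offset_to_start: int | None = None


def build_palindromic_pssm(
    sites: Sequence[str],
    width: int = 16,
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
    fixed_center: bool = True,
) -> Pssm:
    """Build a PSSM from aligned sites with the fixed central-CG constraint.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount); the
    two center columns are then overridden so C (respectively G) receives
    1 - 3*eps with eps = pseudocount / (n + 4*pseudocount).
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    for idx, s in enumerate(sites):
        if len(s) != width:
            raise ValueError(f"site {idx} has length {len(s)}, expected {width}")
        if any(b not in ALPHABET for b in s.upper()):
            raise ValueError(f"site {idx} contains non-ACGT characters")
    n = len(sites)
    counts = np.zeros((4, width))
    for s in sites:
        for j, b in enumerate(s.upper()):
            counts[_INDEX[b], j] += 1
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    if fixed_center:
        eps = pseudocount / (n + 4 * pseudocount)
        c_col, g_col = center_columns(width)
        probs[:, c_col] = eps
        probs[_INDEX["C"], c_col] = 1 - 3 * eps
        probs[:, g_col] = eps
        probs[_INDEX["G"], g_col] = 1 - 3 * eps
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    bg = bg / bg.sum()
    return Pssm(probs=probs, background=bg, pseudocount=pseudocount,
                fixed_center=fixed_center)


def genome_background(record: GenomeRecord) -> np.ndarray:
    """Mononucleotide frequencies of the record (N bases ignored)."""
    seq = record.sequence
    counts = np.array([seq.count(b) for b in ALPHABET], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


@dataclass
class ScoreDistribution:
    """Exact null distribution of the integer-binned log-odds score."""

    int_scores: np.ndarray  # ascending achievable binned scores
    survival: np.ndarray  # P(S >= int_scores[i]) under the background
    granularity: float
    int_matrix: np.ndarray  # 4 x width integer-binned log-odds

    def pvalue_int(self, int_score: int) -> float:
        idx = np.searchsorted(self.int_scores, int_score, side="left")
        if idx >= self.int_scores.size:
            return 0.0
        return float(self.survival[idx])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / self.granularity)))

    def score_threshold(self, p_max: float) -> int:
        """Smallest integer score whose survival probability is <= p_max."""
        ok = self.int_scores[self.survival <= p_max]
        return int(ok[0]) if ok.size else int(self.int_scores[-1]) + 1


def score_pvalue_table(
    pssm: Pssm,
    background: Sequence[float] | None = None,
    granularity: float = 0.01,
) -> ScoreDistribution:
    """Exact survival function of the window score under an i.i.d. background.

    Per-column log-odds are rounded to ``granularity``-bit bins, and the score
    distribution of a random background word of length = width is accumulated
    by dynamic-programming convolution; scanning uses the same binned matrix,
    so reported p-values are exact for the binned score.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = np.asarray(background, dtype=float) if background is not None else pssm.background
    bg = bg / bg.sum()
    int_matrix = np.rint(pssm.log_odds / granularity).astype(np.int64)
    cur: dict[int, float] = {0: 1.0}
    for j in range(pssm.width):
        nxt: dict[int, float] = {}
        for s, p in cur.items():
            for b in range(4):
                s2 = s + int(int_matrix[b, j])
                nxt[s2] = nxt.get(s2, 0.0) + p * bg[b]
        cur = nxt
    int_scores = np.array(sorted(cur), dtype=np.int64)
    pmf = np.array([cur[s] for s in int_scores])
    survival = pmf[::-1].cumsum()[::-1]
    # guard against drift: total mass is 1 up to float error
    survival = np.minimum(survival, 1.0)
    return ScoreDistribution(int_scores, survival, granularity, int_matrix)


def _window_int_score(int_matrix: np.ndarray, window: str) -> int | None:
    score = 0
    for j, b in enumerate(window):
        i = _INDEX.get(b)
        if i is None:
            return None  # N or other ambiguity: skip this window
        score += int(int_matrix[i, j])
    return score


def scan_sequence(
    seq: str,
    pssm: Pssm,
    table: ScoreDistribution,
    p_max: float = 1e-4,
    both_strands: bool = True,
    origin: int = 0,
) -> list[MotifSite]:
    """Scan one + strand sequence; positions are offset by ``origin``."""
    w = pssm.width
    seq = seq.upper()
    if len(seq) < w:
        return []
    threshold = table.score_threshold(p_max)
    g = table.granularity
    sites: list[MotifSite] = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        fwd = _window_int_score(table.int_matrix, window)
        if fwd is None:
            continue
        rc = None
        if both_strands:
            rc_window = reverse_complement(window)
            rc = _window_int_score(table.int_matrix, rc_window)
        fwd_hit = fwd >= threshold
        rc_hit = rc is not None and rc >= threshold
        if fwd_hit and rc_hit and window == reverse_complement(window):
            # perfect palindrome: one unstranded report
            sites.append(
                MotifSite(origin + i, ".", fwd * g, table.pvalue_int(fwd), window)
            )
            continue
        if fwd_hit:
            sites.append(
                MotifSite(origin + i, "+", fwd * g, table.pvalue_int(fwd), window)
            )
        if rc_hit:
            sites.append(
                MotifSite(origin + i, "-", rc * g, table.pvalue_int(rc),
                          reverse_complement(window))
            )
    return sites


def scan_regions(
    regions: Sequence[GenomicRegion],
    record: GenomeRecord,
    pssm: Pssm,
    p_max: float = 1e-4,
    both_strands: bool = True,
    table: ScoreDistribution | None = None,
    background: Sequence[float] | None = None,
) -> list[MotifSite]:
    """Report every window with p <= p_max over the given regions.

    The null table defaults to the record's mononucleotide background.
    Overlapping regions may yield duplicate positions; hits are deduplicated
    on (position, strand). Regions shorter than the motif are skipped.
    """
    if table is None:
        bg = background if background is not None else genome_background(record)
        table = score_pvalue_table(pssm, background=bg)
    seen: set[tuple[int, str]] = set()
    sites: list[MotifSite] = []
    for region in regions:
        seq = record.sequence[region.start : region.end]
        for site in scan_sequence(seq, pssm, table, p_max=p_max,
                                  both_strands=both_strands, origin=region.start):
            key = (site.position, site.strand)
            if key not in seen:
                seen.add(key)
                sites.append(site)
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def map_sites_to_genes(
    sites: Sequence[MotifSite],
    record: GenomeRecord,
    window: int = 500,
) -> tuple[list[MotifSite], dict[str, list[int]]]:
    """Assign sites to the nearest downstream gene and compute start offsets.

    A site is assigned to the nearest downstream gene on the matching strand
    (unstranded palindrome hits match either strand) within ``window`` bases.
    ``offset_to_start`` is relative to the first base of the translation
    start, negative upstream. The second return value maps each gene to the
    start-to-start separations (bases, + strand coordinates) of all site pairs
    in its upstream region.
    """
    L = record.length
    annotated: list[MotifSite] = []
    by_gene: dict[str, list[MotifSite]] = {}
    for site in sites:
        best: tuple[int, str] | None = None  # (distance, gene_id)
        for g in record.genes:
            if site.strand != "." and g.strand != site.strand:
                continue
            w = len(site.sequence)
            if g.strand == "+":
                d = g.start - site.position  # distance from site start to ATG
                if record.circular and d < 0:
                    d += L
            else:
                # 5'-most site base in gene orientation is position + w - 1
                d = site.position + w - g.end
                if record.circular and d < 0:
                    d += L
            if 0 <= d <= window and (best is None or d < best[0]):
                best = (d, g.gene_id)
        new = MotifSite(site.position, site.strand, site.score, site.p, site.sequence)
        if best is not None:
            new.assigned_gene = best[1]
            new.offset_to_start = -best[0]
        annotated.append(new)
        if new.assigned_gene:
            by_gene.setdefault(new.assigned_gene, []).append(new)
    separations = {
        gene: sorted(
            abs(a.position - b.position)
            for i, a in enumerate(gsites)
            for b in gsites[i + 1 :]
        )
        for gene, gsites in by_gene.items()
        if len(gsites) > 1
    }
    return annotated, separations


def write_meme_minimal(pssm: Pssm, path: str | os.PathLike, name: str = "motif_1") -> None:
    """Serialize in MEME minimal text format for interoperability."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, pssm.background)) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pssm.width}\n")
        for j in range(pssm.width):
            fh.write(" ".join(f"{pssm.probs[i, j]:.6f}" for i in range(4)) + "\n")


def sites_to_tsv(sites: Sequence[MotifSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("position\tstrand\tscore_bits\tp\tsequence\tassigned_gene\toffset_to_start\n")
        for s in sites:
            fh.write(
                f"{s.position}\t{s.strand}\t{s.score:.4f}\t{s.p:.6g}\t{s.sequence}\t"
                f"{s.assigned_gene or ''}\t"
                f"{s.offset_to_start if s.offset_to_start is not None else ''}\n"
            )


def sites_to_bed(sites: Sequence[MotifSite], path: str | os.PathLike,
                 genome_id: str = "genome") -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{genome_id}\t{s.position}\t{s.position + len(s.sequence)}\t"
                f"{s.assigned_gene or 'site'}\t{int(round(s.score * 100))}\t{s.strand}\n"
            )
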