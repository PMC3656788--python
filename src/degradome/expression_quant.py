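"""Transcript quantification: TA, ASD and NTA.

The expression unit is the normalized transcript abundance (NTA): the mean
per-base unique-hit depth of a gene (TA) divided by the sample's average
sequencing depth (ASD = total mapped bases / genome length). NTA is therefore
scale-free: a gene transcribed at the genome-average level has NTA = 1, and
"expressed" means NTA strictly greater than 1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeRecord


@dataclass
class CoverageTrack:
    """Per-base unique-hit depth for one condition."""

    condition: str
    depth: np.ndarray
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("depth values must be non-negative")


def read_coverage_tsv(path: str | os.PathLike, condition: str | None = None,
                      genome_length: int | None = None) -> CoverageTrack:
    """Read coverage from 2-column TSV (`pos, depth`, 1-based) or 4-column bedGraph."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    name = condition or os.path.splitext(os.path.basename(str(path)))[0]
    if df.shape[1] == 2:
        pos = df[0].to_numpy(dtype=np.int64) - 1
        L = genome_length or int(pos.max()) + 1
        depth = np.zeros(L, dtype=np.int64)
        depth[pos] = df[1].to_numpy(dtype=np.int64)
    elif df.shape[1] == 4:
        starts = df[1].to_numpy(dtype=np.int64)
        ends = df[2].to_numpy(dtype=np.int64)
        L = genome_length or int(ends.max())
        depth = np.zeros(L, dtype=np.int64)
        for s, e, v in zip(starts, ends, df[3].to_numpy(dtype=np.int64)):
            depth[s:e] += v
        return CoverageTrack(name, depth, str(df[0].iloc[0]))
    else:
        raise ValueError(f"{path}: expected 2-column TSV or 4-column bedGraph")
    return CoverageTrack(name, depth)


def write_coverage_tsv(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write coverage as 1-based `pos, depth` TSV (zero-depth bases omitted)."""
    nz = np.nonzero(track.depth)[0]
    with open(path, "w") as fh:
        fh.write(f"# condition={track.condition} genome={track.genome_id} "
                 f"length={track.depth.size}\n")
        for p in nz:
            fh.write(f"{p + 1}\t{track.depth[p]}\n")


@dataclass
class ExpressionTable:
    """Genes x conditions NTA matrix with the per-condition ASD that produced it."""

    nta: pd.DataFrame
    ta: pd.DataFrame
    asd: pd.Series
    gene_lengths: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def genes(self) -> list[str]:
        return list(self.nta.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.nta.columns)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#asd:\t" + "\t".join(f"{self.asd[c]:.10g}" for c in self.conditions) + "\n")
        self.nta.to_csv(path, sep="\t", mode="a", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "ExpressionTable":
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("#asd:"):
            raise ValueError(f"{path}: missing '#asd:' header line")
        asd_values = [float(x) for x in header.strip().split("\t")[1:]]
        nta = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        asd = pd.Series(asd_values, index=nta.columns)
        ta = nta.mul(asd, axis=1)
        return cls(nta=nta, ta=ta, asd=asd)


def compute_asd(track: CoverageTrack) -> float:
    """Average sequencing depth: total per-base hits divided by genome length."""
    if track.depth.size == 0:
        raise ValueError("cannot compute ASD on a zero-length genome")
    return float(track.depth.sum()) / track.depth.size


def compute_nta_table(
    tracks: Mapping[str, CoverageTrack] | Sequence[CoverageTrack],
    record: GenomeRecord,
) -> ExpressionTable:
    """Per-gene TA and NTA for every condition.

    TA_j = (sum of depth over the bases of gene j) / gene length;
    NTA_j = TA_j / ASD. Gene bases are counted strand-blind, and bases shared
    by overlapping genes count fully toward each gene.
    """
    if not isinstance(tracks, Mapping):
        tracks = {t.condition: t for t in tracks}
    conditions = list(tracks)
    genes = [g.gene_id for g in record.genes]
    for g in record.genes:
        if g.end > record.length:
            raise ValueError(f"gene {g.gene_id} outside genome")
    ta = pd.DataFrame(0.0, index=genes, columns=conditions)
    asd = pd.Series(0.0, index=conditions)
    for cond, track in tracks.items():
        if track.depth.size != record.length:
            raise ValueError(
                f"track {cond} length {track.depth.size} != genome length {record.length}"
            )
        asd[cond] = compute_asd(track)
        cum = np.concatenate([[0], np.cumsum(track.depth, dtype=np.float64)])
        for g in record.genes:
            total = cum[g.end] - cum[g.start]
            ta.loc[g.gene_id, cond] = total / g.length
    nta = ta.div(asd, axis=1).fillna(0.0)
    lengths = pd.Series({g.gene_id: g.length for g in record.genes}, dtype=float)
    return ExpressionTable(nta=nta, ta=ta, asd=asd, gene_lengths=lengths)


def is_expressed(nta_value: float, threshold: float = 1.0) -> bool:
    """A gene is expressed when NTA strictly exceeds the threshold."""
    return nta_value > threshold


@dataclass
class CorrelationResult:
    coefficient: float
    p: float
    defined: bool = True
    method: str = ""


def exact_spearman_p(n: int, rho_obs: float, alternative: str = "two-sided") -> float:
    """Exact permutation p-value for Spearman's rho with distinct ranks, n <= 8."""
    if n > 8:
        raise ValueError("exact enumeration supported only for n <= 8")
    base = np.arange(n, dtype=float)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        rho = float(np.corrcoef(base, np.asarray(perm, dtype=float))[0, 1])
        if alternative == "less":
            count += rho <= rho_obs + 1e-12
        elif alternative == "greater":
            count += rho >= rho_obs - 1e-12
        else:
            count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def correlate_quantifications(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson_r2_on_log",
    log_floor: float = 0.01,
    alternative: str = "two-sided",
) -> CorrelationResult:
    """Validate one quantification against another.

    ``pearson_r2_on_log`` is the cross-platform check used for qRT-PCR versus
    RNA-Seq: squared Pearson correlation of log-transformed values, zeros
    replaced by ``log_floor``. ``spearman`` is the rank correlation used for
    replicate agreement, with an exact permutation p-value at n <= 8 and the
    asymptotic p otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(float("nan"), float("nan"), defined=False, method=method)
    if method == "pearson_r2_on_log":
        if (x < 0).any() or (y < 0).any():
            raise ValueError("log mode requires non-negative values")
        lx = np.log10(np.where(x > 0, x, log_floor))
        ly = np.log10(np.where(y > 0, y, log_floor))
        r, p = stats.pearsonr(lx, ly)
        return CorrelationResult(float(r**2), float(p), method=method)
    if method == "spearman":
        res = stats.spearmanr(x, y, alternative=alternative)
        rho = float(res.statistic)
        if x.size <= 8 and np.unique(x).size == x.size and np.unique(y).size == y.size:
            p = exact_spearman_p(x.size, rho, alternative)
        else:
            p = float(res.pvalue)
        return CorrelationResult(rho, p, method=method)
    raise ValueError(f"unknown correlation method {method!r}")
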