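"""Genome records, gene models and region arithmetic.

This module is the coordinate backbone of the pipeline. Everything internal
is 0-based half-open; file output follows the 1-based inclusive convention of
GenBank/GFF3 (BED stays 0-based half-open per the BED standard).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "other")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A single gene feature on the chromosome (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"gene {self.gene_id}: unknown feature type {self.feature_type}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A chromosome sequence plus its ordered gene models."""

    id: str
    sequence: str
    circular: bool = True
    genes: list[GeneModel] = field(default_factory=list)
    source_format: str = "genbank"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start}, {g.end}) exceeds genome "
                    f"length {self.length}"
                )
            if g.gene_id in seen:
                raise ValueError(f"duplicate locus tag {g.gene_id}")
            seen.add(g.gene_id)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def feature_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes:
            counts[g.feature_type] = counts.get(g.feature_type, 0) + 1
        return counts


@dataclass
class GenomicRegion:
    """An interval on the genome; strand '.' means unstranded."""

    start: int
    end: int
    strand: str = "."
    kind: str = "arbitrary"
    anchor_gene: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError("region strand must be '+', '-' or '.'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return self.start < other.end and other.start < self.end


def region_sequence(record: GenomeRecord, region: GenomicRegion) -> str:
    """Sequence of a region, reverse-complemented for '-' strand regions."""
    seq = record.sequence[region.start : region.end]
    return reverse_complement(seq) if region.strand == "-" else seq


# ---------------------------------------------------------------------------
# readers / writers


def _feature_type(gff_or_gb_type: str) -> str:
    return gff_or_gb_type if gff_or_gb_type in ("CDS", "tRNA", "rRNA") else "other"


def read_genome_record(
    path: str | os.PathLike,
    format: str = "genbank",
    gff3: str | os.PathLike | None = None,
    annotation_table: str | os.PathLike | None = None,
) -> GenomeRecord:
    """Read a genome from a GenBank flat file or a FASTA + GFF3 pair.

    Coordinates are converted to 0-based half-open. CDS/tRNA/rRNA features
    become :class:`GeneModel` entries; qualifiers or a side annotation TSV
    populate ``GeneModel.annotations``.
    """
    if format == "genbank":
        record = _read_genbank(path)
    elif format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= path")
        record = _read_fasta_gff3(path, gff3)
    else:
        raise ValueError(f"unknown genome format: {format!r}")
    if annotation_table is not None:
        apply_annotation_table(record, load_annotation_table(annotation_table))
    return record


def _read_genbank(path: str | os.PathLike) -> GenomeRecord:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    genes = []
    length = len(rec.seq)
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        start, end = int(feat.location.start), int(feat.location.end)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"feature at {start}..{end} out of bounds for genome of length {length}"
            )
        tag = feat.qualifiers.get("locus_tag", [f"feat_{start}_{end}"])[0]
        ann = {
            k: v[0]
            for k, v in feat.qualifiers.items()
            if k in ("product", "gene", "cazy_family", "cellulosomal", "cluster", "role")
        }
        genes.append(
            GeneModel(tag, start, end, "-" if feat.location.strand == -1 else "+",
                      _feature_type(feat.type), ann)
        )
    circular = rec.annotations.get("topology", "circular") == "circular"
    return GenomeRecord(rec.id, str(rec.seq), circular, genes, "genbank")


def _read_fasta_gff3(fasta: str | os.PathLike, gff3: str | os.PathLike) -> GenomeRecord:
    import gffutils

    rec = SeqIO.read(str(fasta), "fasta")
    db = gffutils.create_db(str(gff3), dbfn=":memory:", force=True, keep_order=True)
    genes = []
    length = len(rec.seq)
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        if feat.featuretype == "gene":
            # only use bare 'gene' lines when no typed child exists
            if any(True for _ in db.children(feat)):
                continue
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if not (0 <= start < end <= length):
            raise ValueError(
                f"{gff3}: feature {feat.id} at {feat.start}..{feat.end} exceeds "
                f"genome length {length}"
            )
        tag = feat.attributes.get("ID", [f"feat_{start}_{end}"])[0]
        ann = {
            k: feat.attributes[k][0]
            for k in ("cazy_family", "cellulosomal", "cluster", "role", "product")
            if k in feat.attributes and len(feat.attributes[k])
        }
        ftype = feat.featuretype if feat.featuretype != "gene" else "CDS"
        genes.append(GeneModel(tag, start, end, feat.strand, _feature_type(ftype), ann))
    circular = "circular=true" in rec.description.lower()
    return GenomeRecord(rec.id, str(rec.seq), circular, genes, "fasta+gff3")


def write_fasta_gff3(
    record: GenomeRecord, fasta_path: str | os.PathLike, gff3_path: str | os.PathLike
) -> None:
    """Write a record as a FASTA + GFF3 pair (GFF3 coordinates 1-based inclusive)."""
    desc = f"circular={'true' if record.circular else 'false'}"
    with open(fasta_path, "w") as fh:
        fh.write(f">{record.id} {desc}\n")
        seq = record.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        for g in record.genes:
            attrs = [f"ID={g.gene_id}"]
            for k, v in sorted(g.annotations.items()):
                if v not in ("", None):
                    attrs.append(f"{k}={v}")
            fh.write(
                "\t".join(
                    [
                        record.id,
                        "degradome",
                        g.feature_type if g.feature_type != "other" else "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


ANNOTATION_COLUMNS = ("gene_id", "cazy_family", "cellulosomal", "cluster", "role")


def load_annotation_table(path: str | os.PathLike) -> dict[str, dict]:
    """Read the side annotation TSV (`gene_id, cazy_family, cellulosomal, cluster, role`)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        out[row.gene_id] = {
            "cazy_family": row.cazy_family,
            "cellulosomal": row.cellulosomal.lower() in ("1", "true", "yes"),
            "cluster": row.cluster,
            "role": row.role or "other",
        }
    return out


def apply_annotation_table(record: GenomeRecord, table: Mapping[str, dict]) -> None:
    for g in record.genes:
        if g.gene_id in table:
            g.annotations.update(table[g.gene_id])


def write_annotation_table(record: GenomeRecord, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for g in record.genes:
            a = g.annotations
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        str(a.get("cazy_family", "")),
                        "true" if a.get("cellulosomal") else "false",
                        str(a.get("cluster", "")),
                        str(a.get("role", "other")),
                    ]
                )
                + "\n"
            )


def write_regions_bed(
    regions: Iterable[GenomicRegion], path: str | os.PathLike, genome_id: str = "genome"
) -> None:
    """BED6 output (0-based half-open per the BED standard)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.anchor_gene or f"{r.kind}_{i}"
            fh.write(f"{genome_id}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# region extraction


def extract_regions(
    record: GenomeRecord,
    mode: str,
    max_len: int = 500,
    truncate_at_neighbor: bool = True,
) -> list[GenomicRegion]:
    """Derive upstream or intergenic regions from a genome record.

    Upstream mode returns, per gene, the region 5' of its translation start on
    the gene's own strand, of length ``min(max_len, distance to the nearest
    annotated feature)`` when ``truncate_at_neighbor``. Intergenic mode returns
    the maximal intervals covered by no gene. On circular records regions may
    wrap the origin; a wrapping region is returned as two sub-intervals that
    share the anchor gene.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if mode == "upstream":
        if not record.genes:
            raise ValueError("upstream mode requires at least one gene")
        return _upstream_regions(record, max_len, truncate_at_neighbor)
    if mode == "intergenic":
        return _intergenic_regions(record)
    raise ValueError(f"unknown region mode {mode!r}")


def _upstream_regions(
    record: GenomeRecord, max_len: int, truncate: bool
) -> list[GenomicRegion]:
    L = record.length
    regions: list[GenomicRegion] = []
    for g in record.genes:
        others = [o for o in record.genes if o.gene_id != g.gene_id]
        if g.strand == "+":
            tss = g.start
            if truncate and others:
                gap = min((tss - o.end) % L if record.circular else _lin_gap(tss - o.end)
                          for o in others)
            else:
                gap = L
            if not record.circular:
                gap = min(gap, tss)
            length = min(max_len, gap)
            if length <= 0:
                continue
            lo = tss - length
            if lo >= 0:
                regions.append(GenomicRegion(lo, tss, "+", "upstream", g.gene_id))
            else:  # wraps the origin
                regions.append(GenomicRegion(L + lo, L, "+", "upstream", g.gene_id))
                if tss > 0:
                    regions.append(GenomicRegion(0, tss, "+", "upstream", g.gene_id))
        else:
            tss = g.end  # first upstream base sits at g.end for '-' genes
            if truncate and others:
                gap = min((o.start - tss) % L if record.circular else _lin_gap(o.start - tss)
                          for o in others)
            else:
                gap = L
            if not record.circular:
                gap = min(gap, L - tss)
            length = min(max_len, gap)
            if length <= 0:
                continue
            hi = tss + length
            if hi <= L:
                regions.append(GenomicRegion(tss, hi, "-", "upstream", g.gene_id))
            else:
                regions.append(GenomicRegion(tss, L, "-", "upstream", g.gene_id))
                if hi - L > 0:
                    regions.append(GenomicRegion(0, hi - L, "-", "upstream", g.gene_id))
    return regions


def _lin_gap(d: int) -> int:
    # on a linear genome a neighbor on the wrong side never truncates
    return d if d >= 0 else 10**12


def _intergenic_regions(record: GenomeRecord) -> list[GenomicRegion]:
    L = record.length
    if not record.genes:
        return [GenomicRegion(0, L, ".", "intergenic")]
    merged: list[list[int]] = []
    for g in record.genes:  # genes sorted by start
        if merged and g.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], g.end)
        else:
            merged.append([g.start, g.end])
    gaps: list[GenomicRegion] = []
    for (s1, e1), (s2, _) in zip(merged, merged[1:]):
        if s2 > e1:
            gaps.append(GenomicRegion(e1, s2, ".", "intergenic"))
    first_start, last_end = merged[0][0], merged[-1][1]
    if record.circular:
        # wrap-around gap represented as two sub-intervals
        if last_end < L:
            gaps.append(GenomicRegion(last_end, L, ".", "intergenic"))
        if first_start > 0:
            gaps.insert(0, GenomicRegion(0, first_start, ".", "intergenic"))
    else:
        if first_start > 0:
            gaps.insert(0, GenomicRegion(0, first_start, ".", "intergenic"))
        if last_end < L:
            gaps.append(GenomicRegion(last_end, L, ".", "intergenic"))
    return gaps
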