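"""Transcribed-region calling and core / condition-specific classification.

A base is "expressed" when its unique-hit depth reaches ``min_base_depth``;
maximal runs of expressed bases (tolerating internal gaps up to ``max_gap``
and discarding runs shorter than ``min_length``) are the transcribed regions
of one condition. Across conditions, regions fall into the core set
(transcribed under every substrate) or the condition-specific set (transcribed
under exactly one substrate, not overlapping any other condition's transcribed
regions, and with mean depth strictly greater than two).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression_quant import CoverageTrack
from .genome_io import GenomeRecord, GenomicRegion


@dataclass
class TranscribedRegion:
    interval: GenomicRegion
    conditions_expressed: set[str]
    mean_depth: dict[str, float] = field(default_factory=dict)
    category: str = "other"  # core | condition_specific | other
    context: str = "cds_overlap"  # cds_overlap | intergenic | putative_5utr


def call_transcribed_regions(
    track: CoverageTrack,
    min_base_depth: int = 1,
    min_length: int = 30,
    max_gap: int = 0,
) -> list[GenomicRegion]:
    """Maximal runs of bases with depth >= min_base_depth.

    Internal gaps of up to ``max_gap`` consecutive sub-threshold bases are
    bridged; runs shorter than ``min_length`` are discarded.
    """
    if min_base_depth < 1 or min_length < 1 or max_gap < 0:
        raise ValueError("thresholds must be positive (max_gap >= 0)")
    mask = track.depth >= min_base_depth
    if not mask.any():
        return []
    # run boundaries on the padded mask
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, int(e)])
    return [
        GenomicRegion(int(s), int(e), ".", "arbitrary")
        for s, e in merged
        if e - s >= min_length
    ]


def _expressed_mask(regions: Sequence[GenomicRegion], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in regions:
        mask[r.start : r.end] = True
    return mask


def _assign_context(
    region: GenomicRegion, record: GenomeRecord, upstream_window: int
) -> str:
    for g in record.genes:
        if region.start < g.end and g.start < region.end:
            return "cds_overlap"
    # intergenic; check the upstream window of each gene (5' side, same strand
    # requirement is carried by the gene since regions are unstranded)
    L = record.length
    for g in record.genes:
        if g.strand == "+":
            lo = g.start - upstream_window
            if lo >= 0:
                windows = [(lo, g.start)]
            elif record.circular:
                windows = [(L + lo, L), (0, g.start)]
            else:
                windows = [(0, g.start)]
        else:
            hi = g.end + upstream_window
            if hi <= L:
                windows = [(g.end, hi)]
            elif record.circular:
                windows = [(g.end, L), (0, hi - L)]
            else:
                windows = [(g.end, L)]
        for ws, we in windows:
            if ws < we and region.start < we and ws < region.end:
                return "putative_5utr"
    return "intergenic"


def classify_regions(
    per_condition_regions: Mapping[str, Sequence[GenomicRegion]],
    record: GenomeRecord,
    tracks: Mapping[str, CoverageTrack] | None = None,
    min_specific_depth: float = 2.0,
    upstream_window: int = 500,
) -> list[TranscribedRegion]:
    """Split transcribed regions into core / condition-specific / other.

    Core regions are the maximal intervals expressed under *every* condition
    (interval intersection). A condition-specific region must be expressed
    under exactly one condition, share no base with any region transcribed
    under another condition, and have mean depth strictly greater than
    ``min_specific_depth`` in its condition (the depth filter requires
    ``tracks``).
    """
    conditions = list(per_condition_regions)
    L = record.length
    masks = {c: _expressed_mask(per_condition_regions[c], L) for c in conditions}
    if tracks is not None:
        for c, t in tracks.items():
            if t.depth.size != L:
                raise ValueError(f"track {c} does not match genome length {L}")

    out: list[TranscribedRegion] = []

    # core = per-base AND across all conditions
    core_mask = np.ones(L, dtype=bool)
    for c in conditions:
        core_mask &= masks[c]
    for s, e in _mask_runs(core_mask):
        region = GenomicRegion(s, e, ".", "arbitrary")
        depths = {}
        if tracks is not None:
            depths = {c: float(tracks[c].depth[s:e].mean()) for c in conditions}
        out.append(
            TranscribedRegion(
                region,
                set(conditions),
                depths,
                category="core",
                context=_assign_context(region, record, upstream_window),
            )
        )

    # candidate condition-specific regions: evaluate each called region
    for c in conditions:
        other_mask = np.zeros(L, dtype=bool)
        for o in conditions:
            if o != c:
                other_mask |= masks[o]
        for r in per_condition_regions[c]:
            overlap_other = bool(other_mask[r.start : r.end].any())
            expressed_in = {c} | {
                o for o in conditions if o != c and masks[o][r.start : r.end].any()
            }
            depths = {}
            if tracks is not None:
                depths = {
                    cond: float(tracks[cond].depth[r.start : r.end].mean())
                    for cond in expressed_in
                }
            category = "other"
            if not overlap_other:
                mean_depth = depths.get(c)
                if mean_depth is not None and mean_depth > min_specific_depth:
                    category = "condition_specific"
            out.append(
                TranscribedRegion(
                    r,
                    expressed_in,
                    depths,
                    category=category,
                    context=_assign_context(r, record, upstream_window),
                )
            )
    return out


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def write_regions_tsv(regions: Sequence[TranscribedRegion], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tcategory\tcontext\tconditions_expressed\tmean_depths\n")
        for r in regions:
            conds = ",".join(sorted(r.conditions_expressed))
            depths = ",".join(
                f"{c}={r.mean_depth[c]:.4g}" for c in sorted(r.mean_depth)
            )
            fh.write(
                f"{r.interval.start}\t{r.interval.end}\t{r.category}\t"
                f"{r.context}\t{conds}\t{depths}\n"
            )
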