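"""Transcribed-region calling and core / condition-specific classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degradome.coverage_regions import (
    call_transcribed_regions,
    classify_regions,
)
from degradome.expression_quant import CoverageTrack
from degradome.genome_io import GeneModel, GenomeRecord, GenomicRegion


def _oracle_runs(depth, min_depth, min_len, max_gap):
    mask = [d >= min_depth for d in depth]
    runs, i = [], 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= max_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(s, e) for s, e in merged if e - s >= min_len]


def test_zero_track_yields_no_regions():
    track = CoverageTrack("c", np.zeros(100, dtype=int))
    assert call_transcribed_regions(track) == []


def test_saturated_track_yields_one_genome_spanning_region():
    track = CoverageTrack("c", np.full(100, 3))
    regions = call_transcribed_regions(track, min_base_depth=1, min_length=1)
    assert [(r.start, r.end) for r in regions] == [(0, 100)]


def test_small_vector_example():
    track = CoverageTrack("c", np.array([0, 1, 1, 0, 0, 1]))
    regions = call_transcribed_regions(track, min_base_depth=1, min_length=1, max_gap=0)
    assert [(r.start, r.end) for r in regions] == [(1, 3), (5, 6)]


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    depth=st.lists(st.integers(0, 4), min_size=1, max_size=120),
    min_len=st.integers(1, 6),
    max_gap=st.integers(0, 4),
)
def test_region_calling_matches_brute_force_oracle(depth, min_len, max_gap):
    track = CoverageTrack("c", np.array(depth))
    got = [(r.start, r.end)
           for r in call_transcribed_regions(track, 1, min_len, max_gap)]
    assert got == _oracle_runs(depth, 1, min_len, max_gap)


def _two_condition_setup():
    """200 bp genome; A and B expressed runs with known relationships."""
    record = GenomeRecord("g", "A" * 200, circular=False,
                          genes=[GeneModel("cds1", 10, 60, "+")])
    depth_a = np.zeros(200, dtype=int)
    depth_b = np.zeros(200, dtype=int)
    depth_a[10:60] = 5       # shared with B -> core
    depth_b[10:60] = 4
    depth_a[100:140] = 5     # A-only, depth 5 -> condition_specific
    depth_a[160:190] = 2     # A-only, mean depth exactly 2.0 -> rejected
    tracks = {"A": CoverageTrack("A", depth_a), "B": CoverageTrack("B", depth_b)}
    regions = {
        c: call_transcribed_regions(t, min_base_depth=1, min_length=10)
        for c, t in tracks.items()
    }
    return record, tracks, regions


def test_core_and_condition_specific_classification():
    record, tracks, regions = _two_condition_setup()
    out = classify_regions(regions, record, tracks=tracks)
    core = [r for r in out if r.category == "core"]
    assert [(r.interval.start, r.interval.end) for r in core] == [(10, 60)]
    assert core[0].conditions_expressed == {"A", "B"}
    specific = [r for r in out if r.category == "condition_specific"]
    assert [(r.interval.start, r.interval.end) for r in specific] == [(100, 140)]


def test_mean_depth_exactly_two_is_rejected():
    record, tracks, regions = _two_condition_setup()
    out = classify_regions(regions, record, tracks=tracks)
    at_boundary = [r for r in out if r.interval.start == 160]
    assert len(at_boundary) == 1
    assert at_boundary[0].mean_depth["A"] == 2.0
    assert at_boundary[0].category == "other"


def test_single_condition_region_overlapping_other_condition_is_rejected():
    record = GenomeRecord("g", "A" * 100, circular=False, genes=[])
    depth_a = np.zeros(100, dtype=int)
    depth_b = np.zeros(100, dtype=int)
    depth_a[10:50] = 5
    depth_b[40:80] = 5  # overlaps A's region by 10 bases
    tracks = {"A": CoverageTrack("A", depth_a), "B": CoverageTrack("B", depth_b)}
    regions = {c: call_transcribed_regions(t, min_length=10) for c, t in tracks.items()}
    out = classify_regions(regions, record, tracks=tracks)
    assert all(r.category != "condition_specific" for r in out)


def test_core_regions_equal_per_base_boolean_and_oracle():
    rng = np.random.default_rng(7)
    L = 2000
    record = GenomeRecord("g", "A" * L, circular=False, genes=[])
    tracks = {}
    for c in ("A", "B", "C"):
        depth = np.zeros(L, dtype=int)
        for _ in range(15):
            s = int(rng.integers(0, L - 60))
            depth[s : s + int(rng.integers(20, 60))] += int(rng.integers(1, 6))
        tracks[c] = CoverageTrack(c, depth)
    regions = {c: call_transcribed_regions(t, min_length=1) for c, t in tracks.items()}
    out = classify_regions(regions, record, tracks=tracks)
    got = np.zeros(L, dtype=bool)
    for r in out:
        if r.category == "core":
            got[r.interval.start : r.interval.end] = True
    oracle = np.ones(L, dtype=bool)
    for c in tracks:
        mask = np.zeros(L, dtype=bool)
        for r in regions[c]:
            mask[r.start : r.end] = True
        oracle &= mask
    assert np.array_equal(got, oracle)


def test_no_condition_specific_region_overlaps_other_conditions():
    rng = np.random.default_rng(11)
    L = 3000
    record = GenomeRecord("g", "A" * L, circular=False, genes=[])
    tracks = {}
    for c in ("A", "B"):
        depth = np.zeros(L, dtype=int)
        for _ in range(20):
            s = int(rng.integers(0, L - 80))
            depth[s : s + int(rng.integers(30, 80))] += 3
        tracks[c] = CoverageTrack(c, depth)
    regions = {c: call_transcribed_regions(t) for c, t in tracks.items()}
    out = classify_regions(regions, record, tracks=tracks)
    masks = {c: np.zeros(L, dtype=bool) for c in tracks}
    for c in tracks:
        for r in regions[c]:
            masks[c][r.start : r.end] = True
    for r in out:
        if r.category != "condition_specific":
            continue
        (cond,) = r.conditions_expressed
        for other in tracks:
            if other != cond:
                assert not masks[other][r.interval.start : r.interval.end].any()


def test_context_assignment():
    record = GenomeRecord(
        "g", "A" * 1000, circular=False,
        genes=[GeneModel("cds1", 500, 700, "+")],
    )
    depth = np.zeros(1000, dtype=int)
    depth[550:600] = 3   # overlaps the CDS
    depth[400:450] = 3   # within the 500 bp upstream window of cds1
    depth[0:40] = 3      # far from any gene? still within window (500-40=460<500)
    tracks = {"A": CoverageTrack("A", depth)}
    regions = {"A": call_transcribed_regions(tracks["A"], min_length=10)}
    out = classify_regions(regions, record, tracks=tracks, upstream_window=100)
    by_start = {r.interval.start: r.context for r in out if r.category != "core"}
    assert by_start[550] == "cds_overlap"
    assert by_start[400] == "putative_5utr"
    assert by_start[0] == "intergenic"


def test_planted_single_condition_genes_are_recovered():
    """Genes transcribed under exactly one condition are called specific."""
    rng = np.random.default_rng(3)
    L = 20000
    genes, planted = [], []
    pos = 100
    for i in range(20):
        length = 400
        gid = f"g{i}"
        genes.append(GeneModel(gid, pos, pos + length, "+"))
        if i % 2 == 0:
            planted.append((pos, pos + length))
        pos += length + 300
    record = GenomeRecord("g", "A" * L, circular=False, genes=genes)
    depth_a = np.zeros(L, dtype=int)
    depth_b = np.zeros(L, dtype=int)
    for i, g in enumerate(genes):
        cov = int(rng.integers(5, 15))
        depth_a[g.start : g.end] = cov
        if (g.start, g.end) not in planted:
            depth_b[g.start : g.end] = cov
    tracks = {"A": CoverageTrack("A", depth_a), "B": CoverageTrack("B", depth_b)}
    regions = {c: call_transcribed_regions(t) for c, t in tracks.items()}
    out = classify_regions(regions, record, tracks=tracks)
    specific_spans = {(r.interval.start, r.interval.end) for r in out
                      if r.category == "condition_specific"}
    recall = sum(1 for span in planted if span in specific_spans) / len(planted)
    assert recall >= 0.9
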