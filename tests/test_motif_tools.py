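"""Palindromic PSSM construction, exact p-values and scanning."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from degradome.genome_io import GeneModel, GenomeRecord, GenomicRegion
from degradome.motif_tools import (
    build_palindromic_pssm,
    center_columns,
    genome_background,
    map_sites_to_genes,
    scan_regions,
    scan_sequence,
    score_pvalue_table,
)
from degradome.genome_io import reverse_complement

CIP_CEL_SITE = "AAGTTATCGTTAATTA"  # a 16-nt cre-like operator site


def _centered_sites(rng, n, width):
    c, g = center_columns(width)
    sites = []
    for _ in range(n):
        s = list(rng.choice(list("ACGT"), size=width))
        s[c], s[g] = "C", "G"
        sites.append("".join(s))
    return sites


def test_operator_site_has_central_cg_and_builds():
    c, g = center_columns(16)
    assert (CIP_CEL_SITE[c], CIP_CEL_SITE[g]) == ("C", "G")
    pssm = build_palindromic_pssm([CIP_CEL_SITE, CIP_CEL_SITE])
    assert pssm.consensus[c] == "C" and pssm.consensus[g] == "G"


def test_identical_sites_zero_pseudocount_give_probability_one_columns():
    pssm = build_palindromic_pssm([CIP_CEL_SITE] * 4, pseudocount=0.0)
    assert np.allclose(pssm.probs.max(axis=0), 1.0)


def test_pseudocount_smoothing_formula():
    sites = ["AAACGTTT", "TAACGTTA"]  # width 8 -> center columns (3, 4) are C, G
    pssm = build_palindromic_pssm(sites, width=8, pseudocount=0.25)
    # non-center column 0: counts A=1, T=1 -> (1 + 0.25) / (2 + 1)
    a = "ACGT".index("A")
    assert pssm.probs[a, 0] == pytest.approx(1.25 / 3)
    # center override: eps = 0.25 / 3
    c = "ACGT".index("C")
    assert pssm.probs[c, 3] == pytest.approx(1 - 3 * 0.25 / 3)


def test_sites_with_n_or_wrong_length_are_rejected():
    with pytest.raises(ValueError):
        build_palindromic_pssm(["AANCGTTT", "TAACGTTA"], width=8)
    with pytest.raises(ValueError):
        build_palindromic_pssm(["AAACGTT", "TAACGTTA"], width=8)


@pytest.mark.parametrize("width", [4, 6, 8])
def test_dp_survival_equals_exhaustive_enumeration(width):
    rng = np.random.default_rng(width)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    pssm = build_palindromic_pssm(_centered_sites(rng, 6, width), width=width,
                                  background=bg)
    table = score_pvalue_table(pssm, background=bg)
    scores: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=width):
        sc = int(sum(table.int_matrix[b, j] for j, b in enumerate(word)))
        pr = float(np.prod([bg[b] for b in word]))
        scores[sc] = scores.get(sc, 0.0) + pr
    ints = np.array(sorted(scores))
    surv = np.array([scores[s] for s in ints])[::-1].cumsum()[::-1]
    assert np.array_equal(ints, table.int_scores)
    np.testing.assert_allclose(surv, table.survival, atol=1e-12)


def test_pvalue_boundaries_and_consensus_maximality():
    rng = np.random.default_rng(3)
    bg = np.full(4, 0.25)
    pssm = build_palindromic_pssm(_centered_sites(rng, 5, 6), width=6, background=bg)
    table = score_pvalue_table(pssm, background=bg)
    assert table.pvalue_int(int(table.int_scores[0])) == pytest.approx(1.0)
    # p at the maximum score equals the background mass of the argmax word(s)
    top_mass = 0.0
    for word in itertools.product(range(4), repeat=6):
        sc = int(sum(table.int_matrix[b, j] for j, b in enumerate(word)))
        if sc == int(table.int_scores[-1]):
            top_mass += float(np.prod([bg[b] for b in word]))
    assert table.pvalue_int(int(table.int_scores[-1])) == pytest.approx(top_mass)
    # consensus scores at least as high as any other word
    cons_score = sum(int(table.int_matrix[:, j].max()) for j in range(6))
    assert cons_score == int(table.int_scores[-1])


def test_region_shorter_than_width_yields_no_hits():
    rng = np.random.default_rng(0)
    pssm = build_palindromic_pssm(_centered_sites(rng, 4, 8), width=8)
    table = score_pvalue_table(pssm)
    assert scan_sequence("ACGTACG", pssm, table, p_max=1.0) == []


def test_windows_containing_n_are_skipped():
    rng = np.random.default_rng(1)
    pssm = build_palindromic_pssm(_centered_sites(rng, 4, 8), width=8)
    table = score_pvalue_table(pssm)
    hits = scan_sequence("AAANCGTTTAAA", pssm, table, p_max=1.0)
    assert all("N" not in h.sequence for h in hits)
    assert {h.position for h in hits} <= {4}


def test_reverse_complement_scan_symmetry():
    rng = np.random.default_rng(5)
    pssm = build_palindromic_pssm(_centered_sites(rng, 5, 8), width=8)
    table = score_pvalue_table(pssm)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    fwd = scan_sequence(seq, pssm, table, p_max=1e-2)
    rev = scan_sequence(reverse_complement(seq), pssm, table, p_max=1e-2)
    flip = {"+": "-", "-": "+", ".": "."}
    mirrored = {(len(seq) - h.position - 8, flip[h.strand]) for h in rev}
    assert {(h.position, h.strand) for h in fwd} == mirrored


def test_planted_sites_recovered_from_upstream_scan(sim_bundle):
    from degradome.genome_io import extract_regions

    record, truth = sim_bundle["record"], sim_bundle["truth"]
    pssm = build_palindromic_pssm(
        [s.sequence for s in truth.planted_sites],
        background=genome_background(record))
    upstream = extract_regions(record, "upstream", max_len=500)
    hits = scan_regions(upstream, record, pssm, p_max=1e-4)
    found = {h.position for h in hits}
    recall = np.mean([s.position in found for s in truth.planted_sites])
    assert recall >= 0.95


def test_site_to_gene_assignment_offsets_and_orphans():
    genes = [GeneModel("gplus", 500, 900, "+"), GeneModel("gminus", 1200, 1500, "-")]
    record = GenomeRecord("g", "A" * 2000, circular=False, genes=genes)
    from degradome.motif_tools import MotifSite

    sites = [
        MotifSite(400, "+", 10.0, 1e-5, "A" * 16),   # 100 bases upstream of gplus
        MotifSite(500, "+", 10.0, 1e-5, "A" * 16),   # starts exactly at the ATG
        MotifSite(1520, "-", 10.0, 1e-5, "A" * 16),  # upstream of the minus gene
        MotifSite(0, "-", 10.0, 1e-5, "A" * 16),     # no matching gene in window
    ]
    annotated, _ = map_sites_to_genes(sites, record, window=200)
    assert annotated[0].assigned_gene == "gplus"
    assert annotated[0].offset_to_start == -100
    assert annotated[1].offset_to_start == 0
    assert annotated[2].assigned_gene == "gminus"
    assert annotated[2].offset_to_start == -(1520 + 16 - 1500)
    assert annotated[3].assigned_gene is None


def test_dual_sites_in_one_upstream_region_report_pair_separation():
    # two operator sites 87 bases apart in the same upstream region
    genes = [GeneModel("cip", 1000, 1600, "+")]
    record = GenomeRecord("g", "A" * 2000, circular=False, genes=genes)
    from degradome.motif_tools import MotifSite

    near = MotifSite(1000 - 120, "+", 12.0, 1e-5, "A" * 16)
    far = MotifSite(1000 - 120 - 87, "+", 12.0, 1e-5, "A" * 16)
    annotated, separations = map_sites_to_genes([near, far], record, window=500)
    assert all(a.assigned_gene == "cip" for a in annotated)
    assert separations["cip"] == [87]
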