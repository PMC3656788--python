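"""Profile correlations, CCR growth signature and TCS locus scanning."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from degradome.expression_quant import ExpressionTable
from degradome.genome_io import GeneModel, GenomeRecord
from degradome.regulon_inference import (
    growth_anticorrelation,
    profile_r2,
    tcs_locus_scan,
)


def _expr(nta: pd.DataFrame) -> ExpressionTable:
    return ExpressionTable(nta=nta, ta=nta.copy(),
                           asd=pd.Series(1.0, index=nta.columns),
                           gene_lengths=pd.Series(500.0, index=nta.index))


def test_exact_negative_linearity_gives_r2_one_negative_slope():
    conds = list("abcdef")
    a = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0])
    nta = pd.DataFrame([a, -2 * a + 30], index=["x", "y"], columns=conds)
    corr = profile_r2(_expr(nta), ["x"], ["y"])
    assert corr.r2 == pytest.approx(1.0) and corr.slope_sign == "-"


def test_profile_r2_symmetric_and_affine_invariant():
    rng = np.random.default_rng(0)
    conds = list("abcdef")
    nta = pd.DataFrame(rng.uniform(1, 10, size=(2, 6)), index=["x", "y"],
                       columns=conds)
    expr = _expr(nta)
    ab = profile_r2(expr, ["x"], ["y"])
    ba = profile_r2(expr, ["y"], ["x"])
    assert ab.r2 == pytest.approx(ba.r2)
    nta2 = nta.copy()
    nta2.loc["y"] = 3.5 * nta2.loc["y"] + 2.0
    assert profile_r2(_expr(nta2), ["x"], ["y"]).r2 == pytest.approx(ab.r2)


def test_constant_profile_flags_undefined():
    conds = list("abcd")
    nta = pd.DataFrame([[1, 2, 3, 4], [5, 5, 5, 5]], index=["x", "flat"],
                       columns=conds, dtype=float)
    corr = profile_r2(_expr(nta), ["x"], ["flat"])
    assert not corr.defined


def test_shared_latent_profile_pairs_exceed_r2_07_on_synthetic(sim_bundle):
    record, expr = sim_bundle["record"], sim_bundle["expr"]
    core = [g.gene_id for g in record.genes
            if g.annotations.get("cluster") == "cip-cel-like"]
    pairs = profile_r2(expr, core, core, aggregate="none")
    vals = [p.r2 for p in pairs if p.unit_a != p.unit_b and p.defined]
    assert np.mean([v > 0.7 for v in vals]) >= 0.9


def test_ccr_anticorrelation_exact_permutation_p():
    growth = {"Ceb": 0.42, "Xyl": 0.35, "Xyn": 0.28, "Cel": 0.20}
    profile = {"Ceb": 1.0, "Xyl": 2.0, "Xyn": 4.0, "Cel": 8.0}
    rho, p, defined = growth_anticorrelation(profile, growth,
                                             rankable_conditions=list(growth))
    assert defined and rho == pytest.approx(-1.0)
    assert p == pytest.approx(1 / 24)


def test_identical_orderings_give_rho_plus_one():
    growth = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
    profile = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
    rho, p, defined = growth_anticorrelation(profile, growth, alternative="greater")
    assert defined and rho == pytest.approx(1.0) and p == pytest.approx(1 / 24)


def test_all_tied_growth_is_undefined():
    growth = {"a": 0.2, "b": 0.2, "c": 0.2}
    profile = {"a": 1.0, "b": 2.0, "c": 3.0}
    rho, p, defined = growth_anticorrelation(profile, growth)
    assert not defined


def _locus_record(extra=()):
    """Category-I style locus: CAZyme | ABC x3 | SBP+sensor+regulator operon."""
    spec = [
        ("cdpA", "CAZyme"), ("cuaA", "ABC"), ("cuaB", "ABC"), ("cuaC", "ABC"),
        ("cuaD", "SBP"), ("cuaS", "TCS_sensor"), ("cuaR", "TCS_regulator"),
    ]
    genes, pos = [], 100
    for i, (name, role) in enumerate(spec):
        gap = 200 if name in ("cuaA", "cuaD") else 50  # operon breaks
        if i:
            pos = genes[-1].end + gap
        genes.append(GeneModel(name, pos, pos + 300, "+", "CDS", {"role": role}))
    for gm in extra:
        genes.append(gm)
    L = max(g.end for g in genes) + 500
    return GenomeRecord("g", "A" * L, circular=False, genes=genes)


def test_sbp_inside_tcs_operon_is_category_one():
    record = _locus_record()
    loci = tcs_locus_scan(record)
    assert len(loci) == 1
    locus = loci[0]
    assert locus.category == "I"
    assert set(locus.genes) == {"cuaD", "cuaS", "cuaR"}
    assert "cdpA" in locus.flanking_cazymes
    assert set(locus.flanking_abc) == {"cuaA", "cuaB", "cuaC"}


def test_cazyme_inside_operon_is_category_two_and_bare_pair_is_three():
    genes = [
        GeneModel("s1", 100, 400, "+", "CDS", {"role": "TCS_sensor"}),
        GeneModel("r1", 450, 750, "+", "CDS", {"role": "TCS_regulator"}),
        GeneModel("c1", 800, 1100, "+", "CDS", {"role": "CAZyme"}),
        GeneModel("s2", 2000, 2300, "-", "CDS", {"role": "TCS_sensor"}),
        GeneModel("r2", 2350, 2650, "-", "CDS", {"role": "TCS_regulator"}),
    ]
    record = GenomeRecord("g", "A" * 3000, circular=False, genes=genes)
    loci = tcs_locus_scan(record)
    assert [l.category for l in loci] == ["II", "III"]


def test_genome_without_tcs_roles_yields_no_loci(toy_record):
    assert tcs_locus_scan(toy_record) == []


def test_synthetic_genome_contains_all_three_locus_categories(sim_bundle):
    loci = tcs_locus_scan(sim_bundle["record"])
    assert sorted(l.category for l in loci) == ["I", "II", "III"]
    cat1 = next(l for l in loci if l.category == "I")
    assert cat1.flanking_abc and cat1.flanking_cazymes
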