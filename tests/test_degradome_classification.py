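"""Degradome membership, Row Z-scores, class labeling and enrichment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from degradome.degradome_classification import (
    cluster_and_label_groups,
    degradome_membership,
    enrichment_test,
    row_zscore,
)
from degradome.expression_quant import ExpressionTable


def _expr(nta: pd.DataFrame) -> ExpressionTable:
    asd = pd.Series(1.0, index=nta.columns)
    return ExpressionTable(nta=nta, ta=nta.copy(), asd=asd,
                           gene_lengths=pd.Series(500.0, index=nta.index))


def _membership_fixture():
    nta = pd.DataFrame(
        {
            "Cel": [0.5, 5.0, 5.0, 4.0],
            "Glu": [0.1, 2.0, 2.0, 2.0],
            "Ceb": [0.1, 2.0, 2.0, 1.0],
        },
        index=["low", "specific", "ratio2", "late"],
    )
    nta.loc["ratio2", ["Glu", "Ceb"]] = 2.5  # ratio exactly 2.0 against both refs
    p = pd.DataFrame(1e-4, index=nta.index, columns=["Glu", "Ceb"])
    return _expr(nta), p


def test_degradome_requires_nta_above_one():
    expr, p = _membership_fixture()
    degradome, _ = degradome_membership(expr, p, "Cel", ["Glu", "Ceb"])
    assert "low" not in degradome and "specific" in degradome


def test_specific_set_requires_ratio_and_p_against_every_reference():
    expr, p = _membership_fixture()
    _, specific = degradome_membership(expr, p, "Cel", ["Glu", "Ceb"])
    assert "specific" in specific  # ratios 2.5 > 2, p = 1e-4 < 1e-3
    p2 = p.copy()
    p2.loc["specific", "Ceb"] = 0.01  # one reference fails the p criterion
    _, specific2 = degradome_membership(expr, p2, "Cel", ["Glu", "Ceb"])
    assert "specific" not in specific2


def test_ratio_exactly_two_is_excluded():
    expr, p = _membership_fixture()
    _, specific = degradome_membership(expr, p, "Cel", ["Glu", "Ceb"])
    assert "ratio2" not in specific  # strict > 2


def test_membership_ref_order_independent_and_target_not_ref():
    expr, p = _membership_fixture()
    a = degradome_membership(expr, p, "Cel", ["Glu", "Ceb"])
    b = degradome_membership(expr, p[["Ceb", "Glu"]], "Cel", ["Ceb", "Glu"])
    assert a == b
    with pytest.raises(ValueError):
        degradome_membership(expr, p, "Cel", ["Cel"])


def test_row_zscore_sample_sd_and_zero_variance_flag():
    nta = pd.DataFrame({"a": [2.0, 3.0], "b": [4.0, 3.0], "c": [6.0, 3.0]},
                       index=["g1", "flat"])
    z = row_zscore(_expr(nta))
    np.testing.assert_allclose(z.z.loc["g1"], [-1.0, 0.0, 1.0])
    assert (z.z.loc["flat"] == 0).all()
    assert z.zero_variance_genes == ["flat"]
    assert abs(float(z.z.sum(axis=1).abs().max())) < 1e-9


def test_two_archetypes_separate_exactly_and_get_condition_labels():
    conds = ["Glu", "Ceb", "Cel"]
    rows = {}
    for i in range(5):
        rows[f"cel{i}"] = [1.0, 1.0, 9.0]   # cellulose-max class
    for i in range(5):
        rows[f"ceb{i}"] = [1.0, 9.0, 1.0]   # cellobiose-max class
    nta = pd.DataFrame.from_dict(rows, orient="index", columns=conds)
    expr = _expr(nta)
    z = row_zscore(expr)
    got = cluster_and_label_groups(z, n_clusters=2, labeling="by_max_condition",
                                   expr=expr, condition_order=conds)
    by_gene = {a.gene_id: a for a in got}
    # clusters labeled in condition order: Ceb-max first (C1), Cel-max second (C2)
    assert all(by_gene[f"ceb{i}"].class_label == "C1" for i in range(5))
    assert all(by_gene[f"cel{i}"].class_label == "C2" for i in range(5))
    assert by_gene["ceb0"].max_condition == "Ceb"


def test_labels_invariant_to_gene_input_order():
    rng = np.random.default_rng(0)
    conds = ["Glu", "Ceb", "Cel"]
    nta = pd.DataFrame(
        rng.uniform(0.5, 1.5, size=(12, 3))
        + np.repeat([[0, 0, 8], [0, 8, 0], [8, 0, 0]], 4, axis=0),
        index=[f"g{i}" for i in range(12)], columns=conds,
    )
    expr = _expr(nta)
    a = cluster_and_label_groups(row_zscore(expr), 3, "by_max_condition", expr=expr,
                                 condition_order=conds)
    shuffled = nta.iloc[rng.permutation(12)]
    expr2 = _expr(shuffled)
    b = cluster_and_label_groups(row_zscore(expr2), 3, "by_max_condition", expr=expr2,
                                 condition_order=conds)
    la = {x.gene_id: x.class_label for x in a}
    lb = {x.gene_id: x.class_label for x in b}
    assert la == lb


def test_subclass_marks_positive_z_under_secondary_condition():
    conds = ["Glu", "Ceb", "Cel"]
    nta = pd.DataFrame(
        {"Glu": [6.0, 1.0], "Ceb": [1.0, 1.0], "Cel": [9.0, 9.0]},
        index=["dual", "pure"],
    )[conds]
    expr = _expr(nta)
    got = cluster_and_label_groups(row_zscore(expr), 1, "by_max_condition",
                                   expr=expr, condition_order=conds)
    by_gene = {a.gene_id: a for a in got}
    assert by_gene["dual"].subclass is not None and "Glu" in by_gene["dual"].subclass
    assert by_gene["pure"].subclass is None


def test_cazyme_group_recovery_on_synthetic_truth(sim_bundle):
    record, truth, expr = (sim_bundle[k] for k in ("record", "truth", "expr"))
    caz = [g.gene_id for g in record.genes if g.annotations.get("role") == "CAZyme"]
    z = row_zscore(expr, genes=caz)
    groups = cluster_and_label_groups(z, n_clusters=7, labeling="cazyme_groups")
    agree = np.mean([a.class_label == truth.group_label[a.gene_id] for a in groups])
    assert agree >= 0.9


def test_enrichment_exact_hypergeometric_corner():
    term_table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(20)],
        "term_id": ["T1"] * 5 + ["T2"] * 15,
    })
    res = enrichment_test([f"g{i}" for i in range(5)], term_table)
    by_term = {r.term_id: r for r in res}
    assert by_term["T1"].p == pytest.approx(1 / math.comb(20, 5))
    assert by_term["T1"].representation_ratio == pytest.approx(4.0)


def test_enrichment_saturation_and_empty_set():
    term_table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(20)],
        "term_id": ["T1"] * 10 + ["T2"] * 10,
    })
    res = enrichment_test([f"g{i}" for i in range(20)], term_table)
    assert all(r.p == pytest.approx(1.0) for r in res)
    assert all(r.representation_ratio == pytest.approx(1.0) for r in res)
    assert enrichment_test([], term_table) == []
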