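"""Consensus differential expression between two conditions.

Three statistics are computed on per-gene counts (k, library total N):

* the MA-plot random-sampling z-test (MARS): M = log2(k1/N1) - log2(k2/N2) is
  tested conditionally on A = (log2(k1/N1) + log2(k2/N2)) / 2 under binomial
  sampling at the pooled proportion;
* Fisher's exact test on the 2x2 table (k1, N1-k1; k2, N2-k2), two-sided by
  the minimum-likelihood convention;
* a likelihood-ratio test of pooled versus separate binomial proportions
  against chi-square(1).

A gene is called differentially expressed by consensus when all three p-values
pass the cutoff, |log2 NTA ratio| >= 2, and neither side of the ratio sits
below the 0.01 NTA floor (positive ratios need numerator >= 0.01, negative
ratios need denominator >= 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

LOG2 = math.log(2.0)

#: named p-value cutoffs: the stringent genome-wide screen and the per-pair filter
P_CUTOFF_PRESETS = {"results_strict": 0.001, "methods_default": 0.05}


@dataclass
class DegTests:
    M: float
    A: float
    z: float
    p_mars: float
    p_fisher: float
    p_lrt: float
    defined: bool = True


@dataclass
class DegResult:
    gene_id: str
    condition_pair: tuple[str, str]
    log2_ratio: float
    p_mars: float
    p_fisher: float
    p_lrt: float
    consensus_deg: bool
    filter_reason: str | None = None


def _xlogy(x: float, y: float) -> float:
    return 0.0 if x == 0 else x * math.log(y)


def deg_tests(k1: int, N1: int, k2: int, N2: int) -> DegTests:
    """MARS z, Fisher exact and likelihood-ratio p-values for one gene."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= k1 <= N1 and 0 <= k2 <= N2):
        raise ValueError("counts must satisfy 0 <= k <= N")
    if k1 == 0 and k2 == 0:
        nan = float("nan")
        return DegTests(nan, nan, nan, nan, nan, nan, defined=False)

    # MARS: continuity-correct zero counts so the logs are finite
    a1, a2 = (k1, k2) if (k1 > 0 and k2 > 0) else (k1 + 0.5, k2 + 0.5)
    x = math.log2(a1 / N1)
    y = math.log2(a2 / N2)
    M = x - y
    A = (x + y) / 2.0
    p_hat = (k1 + k2) / (N1 + N2)
    # delta-method variances of log2(k/N) under Binomial(N, p_hat)
    var_x = (1.0 - p_hat) / (N1 * p_hat * LOG2**2)
    var_y = (1.0 - p_hat) / (N2 * p_hat * LOG2**2)
    mu_m = 0.0  # E[M] under H0: equal proportions
    mu_a = math.log2(p_hat)
    var_m = var_x + var_y
    var_a = (var_x + var_y) / 4.0
    cov_ma = (var_x - var_y) / 2.0
    cond_mean = mu_m + cov_ma / var_a * (A - mu_a)
    cond_var = var_m - cov_ma**2 / var_a
    z = (M - cond_mean) / math.sqrt(cond_var) if cond_var > 0 else float("inf")
    p_mars = float(2.0 * stats.norm.sf(abs(z)))

    table = [[k1, N1 - k1], [k2, N2 - k2]]
    p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])

    # LRT: pooled vs separate binomial proportions, -2*dlogL ~ chi2(1)
    p1, p2 = k1 / N1, k2 / N2
    ll_alt = (
        _xlogy(k1, p1) + _xlogy(N1 - k1, 1 - p1)
        + _xlogy(k2, p2) + _xlogy(N2 - k2, 1 - p2)
    )
    ll_null = (
        _xlogy(k1, p_hat) + _xlogy(N1 - k1, 1 - p_hat)
        + _xlogy(k2, p_hat) + _xlogy(N2 - k2, 1 - p_hat)
    )
    g = max(0.0, 2.0 * (ll_alt - ll_null))
    p_lrt = float(stats.chi2.sf(g, df=1))
    return DegTests(M, A, z, p_mars, p_fisher, p_lrt)


def consensus_deg(
    gene_id: str,
    condition_pair: tuple[str, str],
    nta_a: float,
    nta_b: float,
    tests: DegTests,
    ratio_log2: float = 2.0,
    floor: float = 0.01,
    p_cutoff: float = P_CUTOFF_PRESETS["methods_default"],
) -> DegResult:
    """Apply the ratio / floor / p-value filters and the three-test consensus.

    Filters, in order: (1) |log2(NTA_a / NTA_b)| must reach ``ratio_log2``;
    (2) positive ratios with numerator NTA below ``floor`` are ignored;
    (3) negative ratios with denominator NTA below ``floor`` are not selected;
    (4) every one of the three p-values must be <= ``p_cutoff``.
    """
    if nta_b > 0 and nta_a > 0:
        log2_ratio = math.log2(nta_a / nta_b)
    elif nta_a > 0:
        log2_ratio = float("inf")
    elif nta_b > 0:
        log2_ratio = float("-inf")
    else:
        log2_ratio = float("nan")

    reason: str | None = None
    if not tests.defined or math.isnan(log2_ratio):
        reason = "ratio_below_cutoff"
    elif abs(log2_ratio) < ratio_log2:
        reason = "ratio_below_cutoff"
    elif log2_ratio > 0 and nta_a < floor:
        reason = "numerator_floor"
    elif log2_ratio < 0 and nta_b < floor:
        reason = "denominator_floor"
    elif not (
        tests.p_mars <= p_cutoff
        and tests.p_fisher <= p_cutoff
        and tests.p_lrt <= p_cutoff
    ):
        reason = "p_above_cutoff"
    return DegResult(
        gene_id=gene_id,
        condition_pair=condition_pair,
        log2_ratio=log2_ratio,
        p_mars=tests.p_mars,
        p_fisher=tests.p_fisher,
        p_lrt=tests.p_lrt,
        consensus_deg=reason is None,
        filter_reason=reason,
    )


def counts_from_expression(ta: float, gene_length: float, asd: float,
                           genome_length: int) -> tuple[int, int]:
    """Reconstruct (k, N) from a quantification when only TA/ASD are available.

    k = round(TA x gene length) approximates the per-gene base count and
    N = round(ASD x genome length) the library's total mapped bases; a
    documented approximation used when raw counts were not supplied.
    """
    return int(round(ta * gene_length)), int(round(asd * genome_length))


def pairwise_deg(
    expr,
    cond_a: str,
    cond_b: str,
    genome_length: int,
    ratio_log2: float = 2.0,
    floor: float = 0.01,
    p_cutoff: float = P_CUTOFF_PRESETS["methods_default"],
) -> list[DegResult]:
    """Run the consensus DEG call for every gene between two conditions."""
    results = []
    for gene in expr.genes:
        ta_a, ta_b = expr.ta.loc[gene, cond_a], expr.ta.loc[gene, cond_b]
        length = expr.gene_lengths[gene]
        k1, N1 = counts_from_expression(ta_a, length, expr.asd[cond_a], genome_length)
        k2, N2 = counts_from_expression(ta_b, length, expr.asd[cond_b], genome_length)
        tests = deg_tests(k1, N1, k2, N2)
        results.append(
            consensus_deg(
                gene, (cond_a, cond_b),
                expr.nta.loc[gene, cond_a], expr.nta.loc[gene, cond_b],
                tests, ratio_log2=ratio_log2, floor=floor, p_cutoff=p_cutoff,
            )
        )
    return results


def deg_results_to_tsv(results: Sequence[DegResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tcond_a\tcond_b\tlog2_ratio\tp_mars\tp_fisher\tp_lrt\t"
            "consensus_deg\tfilter_reason\n"
        )
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.condition_pair[0]}\t{r.condition_pair[1]}\t"
                f"{r.log2_ratio:.6g}\t{r.p_mars:.6g}\t{r.p_fisher:.6g}\t"
                f"{r.p_lrt:.6g}\t{int(r.consensus_deg)}\t{r.filter_reason or ''}\n"
            )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional column; raw p-values are the default report)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
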