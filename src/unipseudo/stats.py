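"""Downstream statistics: Fisher exact tests, BH-FDR, hypergeometric overlap
of pseudogene lists, functional-group enrichment, and conserved-set
false-positive validation."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .ontology import FunctionalGroup


def fisher_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test by the point-probability method
    (R convention): sum the probabilities of all tables, with the observed
    margins, whose point probability is <= the observed table's.

    Returns (odds_ratio, p).  A zero margin gives p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    row1, col1, n = a + b, a + c, a + b + c + d
    odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return odds, 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    observed = pmf[a - lo]
    # relative tolerance matches R's fisher.test
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return odds, min(1.0, p)


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    m = len(p_values)
    if m == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


@dataclass
class OverlapTest:
    label: str
    n1: int
    n2: int
    universe: int
    observed: int
    expected: float
    p_hyper: float


def overlap_hypergeometric(
    n1: int, n2: int, universe: int, observed: int, label: str = ""
) -> OverlapTest:
    """Upper-tail hypergeometric test of list overlap.

    expected = n1*n2/N; p = P(X >= observed), X ~ Hypergeom(N, n1, n2).
    """
    if universe < max(n1, n2):
        raise ValueError("universe smaller than a list")
    if observed > min(n1, n2):
        raise ValueError("observed overlap exceeds the smaller list")
    expected = n1 * n2 / universe
    p = float(sps.hypergeom.sf(observed - 1, universe, n1, n2))
    return OverlapTest(label, n1, n2, universe, observed, expected, min(1.0, p))


def conserved_set_validation(
    final_calls: set[str] | list[str], conserved_set: set[str] | list[str]
) -> float:
    """False-positive ratio: flagged conserved genes / conserved-set size,
    as a percentage."""
    conserved = set(conserved_set)
    if not conserved:
        raise ValueError("conserved set is empty")
    flagged = set(final_calls) & conserved
    return 100.0 * len(flagged) / len(conserved)


@dataclass
class EnrichmentResult:
    group: str
    comparison: str  # "background" | "control"
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    fdr_p: float = float("nan")
    significant: bool = False


def enrichment_tests(
    groups: list[FunctionalGroup],
    pseudogenes: set[str],
    background: set[str],
    control_pseudogenes: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher tests of pseudogene representation per functional group.

    A group is an enriched functional group (EFG) when its FDR-adjusted p is
    below alpha against the species' own non-pseudogene background OR against
    the control lineage's pseudogene list.
    """
    results: list[EnrichmentResult] = []
    comparisons: list[tuple[str, set[str]]] = [("background", background)]
    if control_pseudogenes is not None:
        comparisons.append(("control", control_pseudogenes))
    for comp_name, other in comparisons:
        for g in groups:
            a = len(pseudogenes & g.members)
            b = len(pseudogenes - g.members)
            c = len(other & g.members)
            d = len(other - g.members)
            odds, p = fisher_two_sided(a, b, c, d)
            results.append(EnrichmentResult(g.name, comp_name, a, b, c, d, odds, p))
    adjusted = bh_fdr([r.p for r in results])
    for r, q in zip(results, adjusted):
        r.fdr_p = q
        # one-sided enrichment direction on top of the two-sided p
        r.significant = q < alpha and r.a * r.d > r.b * r.c
    return results


def enriched_group_names(results: list[EnrichmentResult]) -> set[str]:
    return {r.group for r in results if r.significant}


@dataclass
class PairOverlapReport:
    pair_tests: dict[str, tuple[int, int]] = field(default_factory=dict)
    comparisons: list[tuple[str, str, float]] = field(default_factory=list)


def pair_overlap_report(
    lists: dict[str, set[str]],
    pair_plan: list[tuple[str, str, str]],
) -> PairOverlapReport:
    """Overlap counts per species pair and Fisher comparisons between pairs.

    ``pair_plan``: (species_a, species_b, label).  For each pair the overlap
    and the pooled list size (n1 + n2, counting shared genes twice) are
    reported; every pair of pairs is compared with a two-sided Fisher test on
    (overlap, pooled - overlap) counts.
    """
    report = PairOverlapReport()
    labels = []
    for sp_a, sp_b, label in pair_plan:
        inter = len(lists[sp_a] & lists[sp_b])
        pooled = len(lists[sp_a]) + len(lists[sp_b])
        report.pair_tests[label] = (inter, pooled)
        labels.append(label)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            o1, t1 = report.pair_tests[labels[i]]
            o2, t2 = report.pair_tests[labels[j]]
            _, p = fisher_two_sided(o1, t1 - o1, o2, t2 - o2)
            report.comparisons.append((labels[i], labels[j], p))
    return report
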