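"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementations under test: the
alignment oracle is a plain memoized recursion that scans all intron donors
per cell; the Fisher/hypergeometric oracles enumerate tables with math.comb.
"""
from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")
_STOPS = {"TAA", "TAG", "TGA"}


def oracle_align_score(protein: str, genome: str, params) -> float:
    """Optimum of the spliced-alignment scoring scheme by exhaustive
    recursion over the full DP space (whole protein, free genome ends)."""
    m, n = len(protein), len(genome)

    def codon_score(i: int, j: int) -> float:
        codon = genome[j - 3 : j]
        if any(b not in "ACGT" for b in codon):
            return params.mismatch_floor
        if codon in _STOPS:
            return params.stop_penalty
        aa = str(Seq(codon).translate())
        return float(_BLOSUM[protein[i - 1], aa])

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == 0:
            return 0.0
        cands = [best(i - 1, j) + params.gap_codon]
        if j >= 3:
            cands.append(best(i - 1, j - 3) + codon_score(i, j))
            cands.append(best(i, j - 3) + params.gap_codon)
        if j >= 1:
            cands.append(best(i - 1, j - 1) + params.frameshift)
            cands.append(best(i, j - 1) + params.frameshift)
        if j >= 2:
            cands.append(best(i - 1, j - 2) + params.frameshift)
            cands.append(best(i, j - 2) + params.frameshift)
        for jp in range(0, j - params.min_intron + 1):
            bonus = (
                params.canonical_bonus
                if genome[jp : jp + 2] == "GT" and genome[j - 2 : j] == "AG"
                else 0.0
            )
            cands.append(best(i, jp) + params.intron_open + bonus)
        return max(cands)

    return max(best(m, j) for j in range(n + 1))


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with math.comb."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def oracle_hypergeom_upper(n1: int, n2: int, universe: int, observed: int) -> float:
    """P(X >= observed) by direct summation with math.comb."""
    total = 0.0
    for x in range(observed, min(n1, n2) + 1):
        total += (
            math.comb(n1, x)
            * math.comb(universe - n1, n2 - x)
            / math.comb(universe, n2)
        )
    return total


def oracle_best_chain_coverage(intervals: list[tuple[int, int]], protein_len: int) -> float:
    """Max covered fraction over all non-overlapping subsets (brute force)."""
    best = 0.0
    n = len(intervals)
    for mask in range(1 << n):
        chosen = [intervals[i] for i in range(n) if mask >> i & 1]
        chosen.sort()
        if any(chosen[i][1] > chosen[i + 1][0] for i in range(len(chosen) - 1)):
            continue
        best = max(best, sum(e - s for s, e in chosen) / protein_len)
    return best


def oracle_bh(pvals: list[float]) -> list[float]:
    """Hand-stepped Benjamini-Hochberg (independent of the implementation)."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
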