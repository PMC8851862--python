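"""Assemble hits into non-overlapping 'copies' along protein coordinates.

A copy is a set of pairwise non-overlapping hits maximizing covered protein
length; copies covering at least ``min_cov`` of the protein flag potential
functional redundancy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .search import Hit


@dataclass
class CopyChain:
    gene_id: str
    members: list[tuple[int, int]]  # protein intervals, aa
    covered_fraction: float
    redundant: bool = False
    hits: list[Hit] = field(default_factory=list)


def _max_coverage_chain(intervals: list[tuple[int, int, int]]) -> list[int]:
    """Weighted interval scheduling: pick non-overlapping intervals maximizing
    total covered length.  intervals: (start, end, original index)."""
    order = sorted(intervals, key=lambda t: t[1])
    n = len(order)
    best = [0] * (n + 1)
    choice: list[list[int]] = [[] for _ in range(n + 1)]
    for i in range(1, n + 1):
        s, e, idx = order[i - 1]
        # latest j with end <= s
        j = i - 1
        while j > 0 and order[j - 1][1] > s:
            j -= 1
        take = best[j] + (e - s)
        if take > best[i - 1]:
            best[i] = take
            choice[i] = choice[j] + [idx]
        else:
            best[i] = best[i - 1]
            choice[i] = choice[i - 1]
    return choice[n]


def chain_hits_into_copies(
    hits: list[Hit],
    protein_length: int,
    min_cov: float = 0.8,
    evalue_threshold: float = 1e-3,
    gene_id: str = "",
) -> list[CopyChain]:
    """Iteratively peel off maximum-coverage non-overlapping hit chains.

    Hits above the E-value threshold are removed first.  Each returned chain
    reports covered_fraction and a redundancy flag (>= min_cov).
    """
    pool = [h for h in hits if h.evalue <= evalue_threshold]
    chains: list[CopyChain] = []
    while pool:
        intervals = [(h.prot_start, h.prot_end, i) for i, h in enumerate(pool)]
        picked = _max_coverage_chain(intervals)
        if not picked:
            break
        members = sorted((pool[i].prot_start, pool[i].prot_end) for i in picked)
        covered = sum(e - s for s, e in members) / protein_length
        chains.append(
            CopyChain(
                gene_id=gene_id,
                members=members,
                covered_fraction=covered,
                redundant=covered >= min_cov,
                hits=[pool[i] for i in picked],
            )
        )
        picked_set = set(picked)
        pool = [h for i, h in enumerate(pool) if i not in picked_set]
    return chains
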