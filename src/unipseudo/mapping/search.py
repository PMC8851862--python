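"""Candidate locus discovery: seeded translated search with empirical E-values.

One seed-and-extend search replaces the two external mappers; a locus must
satisfy two independent criteria — a local-similarity E-value at or below the
threshold AND a colinear multi-hit chain consistent with one gene structure —
or it is discarded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..coords import Interval
from ..genetics import BLOSUM62_ORD, revcomp, translate


@dataclass
class Hit:
    """Ungapped translated hit in plus-strand genome coordinates."""

    chrom: str
    strand: str
    prot_start: int  # aa, 0-based half-open
    prot_end: int
    start: int  # nt, plus strand, 0-based half-open
    end: int
    score: float
    evalue: float = float("inf")


@dataclass
class CandidateLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    flank: int = 5000
    evidence: dict = field(default_factory=dict)
    evalue: float = float("inf")
    chain_cov: float = 0.0
    chain_score: float = 0.0
    hits: list[Hit] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return bool(self.evidence.get("similarity_pass")) and bool(
            self.evidence.get("chain_pass")
        )

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class SearchParams:
    seed_k: int = 5
    min_seeds: int = 2  # seeds per diagonal cluster before extension
    xdrop: float = 14.0
    min_hit_score: float = 25.0
    evalue_threshold: float = 1e-3
    n_decoys: int = 200
    min_chain_cov: float = 0.4
    flank: int = 5000
    max_locus_gap: int = 10000
    merge_overlap: float = 0.5
    decoy_seed: int = 1234


class GenomeIndex:
    """Six-frame translated k-mer index of an assembly."""

    def __init__(self, genome: dict[str, str], k: int = 5):
        self.genome = genome
        self.k = k
        # (chrom, strand) -> oriented sequence; '-' entries are revcomps
        self.oriented: dict[tuple[str, str], str] = {}
        # (chrom, strand, frame) -> aa string
        self.frames: dict[tuple[str, str, int], str] = {}
        self.kmers: dict[str, list[tuple[str, str, int, int]]] = {}
        for chrom, seq in genome.items():
            for strand in "+-":
                s = seq if strand == "+" else revcomp(seq)
                self.oriented[(chrom, strand)] = s
                for frame in range(3):
                    aa = translate(s[frame:])
                    self.frames[(chrom, strand, frame)] = aa
                    for i in range(len(aa) - k + 1):
                        kmer = aa[i : i + k]
                        if "*" in kmer or "X" in kmer:
                            continue
                        self.kmers.setdefault(kmer, []).append((chrom, strand, frame, i))

    def aa_at(self, chrom: str, strand: str, local_nt: int) -> str:
        frame = local_nt % 3
        aa = self.frames[(chrom, strand, frame)]
        idx = (local_nt - frame) // 3
        return aa[idx] if 0 <= idx < len(aa) else "*"


def _extend_cluster(
    index: GenomeIndex,
    protein: str,
    chrom: str,
    strand: str,
    diag: int,
    pmin: int,
    pmax: int,
    params: SearchParams,
) -> tuple[int, int, float] | None:
    """X-drop ungapped extension along one diagonal.

    diag = local_nt_start - 3 * prot_pos.  Returns (prot_start, prot_end,
    score) in protein coordinates, or None if below the score floor.
    """
    m = len(protein)
    seq_len = len(index.oriented[(chrom, strand)])
    blo = BLOSUM62_ORD
    frames = [index.frames[(chrom, strand, f)] for f in range(3)]

    def pair_score(i: int) -> float:
        nt = diag + 3 * i
        if nt < 0 or nt + 3 > seq_len:
            return -1e9
        f = nt % 3
        aa = frames[f][(nt - f) // 3]
        if aa == "*":
            return -8.0
        return blo[ord(protein[i])][ord(aa)]

    # seed segment score
    score = sum(pair_score(i) for i in range(pmin, pmax))
    best, lo, hi = score, pmin, pmax
    # extend right
    cur = score
    i = pmax
    while i < m:
        cur += pair_score(i)
        i += 1
        if cur > best:
            best, hi = cur, i
        if best - cur > params.xdrop:
            break
    # extend left
    cur = best
    i = pmin - 1
    while i >= 0:
        cur += pair_score(i)
        if cur > best:
            best, lo = cur, i
        if best - cur > params.xdrop:
            break
        i -= 1
    if best < params.min_hit_score:
        return None
    return lo, hi, best


def _raw_hits(index: GenomeIndex, protein: str, params: SearchParams) -> list[Hit]:
    k = params.seed_k
    seeds: dict[tuple[str, str, int], list[int]] = {}
    for i in range(len(protein) - k + 1):
        for chrom, strand, frame, aa_pos in index.kmers.get(protein[i : i + k], ()):
            local_nt = frame + 3 * aa_pos
            diag = local_nt - 3 * i
            seeds.setdefault((chrom, strand, diag), []).append(i)
    hits: list[Hit] = []
    for (chrom, strand, diag), positions in seeds.items():
        positions.sort()
        # split seed runs separated by > 30 aa into distinct clusters
        clusters: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - clusters[-1][-1] > 30:
                clusters.append([p])
            else:
                clusters[-1].append(p)
        for cl in clusters:
            if len(cl) < params.min_seeds:
                continue
            ext = _extend_cluster(
                index, protein, chrom, strand, diag, cl[0], cl[-1] + k, params
            )
            if ext is None:
                continue
            lo, hi, score = ext
            local_start = diag + 3 * lo
            local_end = diag + 3 * hi
            seq_len = len(index.oriented[(chrom, strand)])
            if strand == "+":
                start, end = local_start, local_end
            else:
                start, end = seq_len - local_end, seq_len - local_start
            hits.append(Hit(chrom, strand, lo, hi, start, end, score))
    # deduplicate identical extents (several clusters can extend to one hit)
    uniq: dict[tuple, Hit] = {}
    for h in hits:
        key = (h.chrom, h.strand, h.prot_start, h.prot_end, h.start, h.end)
        if key not in uniq or h.score > uniq[key].score:
            uniq[key] = h
    return list(uniq.values())


def _decoy_scores(
    index: GenomeIndex, protein: str, params: SearchParams
) -> np.ndarray:
    rng = np.random.default_rng(params.decoy_seed)
    scores = np.zeros(params.n_decoys)
    letters = list(protein)
    for d in range(params.n_decoys):
        rng.shuffle(letters)
        hits = _raw_hits(index, "".join(letters), params)
        if hits:
            scores[d] = max(h.score for h in hits)
    return scores


def empirical_evalue(score: float, decoy_scores: np.ndarray) -> float:
    """P(random protein achieves >= score), extreme-value tail fit."""
    if len(decoy_scores) == 0:
        return 1.0
    positive = decoy_scores[decoy_scores > 0]
    if len(positive) < 5 or np.ptp(positive) < 1e-9:
        top = float(decoy_scores.max())
        return 1e-9 if score > top else 1.0
    loc, scale = stats.gumbel_r.fit(positive)
    p = float(stats.gumbel_r.sf(score, loc, scale))
    # never report below what the empirical sample alone can support
    return max(p, 1e-12)


def find_candidate_loci(
    protein: str,
    index: GenomeIndex,
    gene_id: str = "",
    params: SearchParams = SearchParams(),
) -> list[CandidateLocus]:
    """Locate candidate orthologous loci for one protein.

    Each locus carries two evidence flags; only loci with both true should
    enter downstream alignment.  Hits with E-value above the threshold are
    discarded before locus assembly.
    """
    if not protein:
        raise ValueError("empty protein")
    hits = _raw_hits(index, protein, params)
    if not hits:
        return []
    decoys = _decoy_scores(index, protein, params)
    for h in hits:
        h.evalue = empirical_evalue(h.score, decoys)
    hits = [h for h in hits if h.evalue <= params.evalue_threshold]
    if not hits:
        return []

    loci: list[CandidateLocus] = []
    m = len(protein)
    by_key: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda h: h.start)
        # split into locus clusters by genomic gap
        clusters: list[list[Hit]] = [[group[0]]]
        for h in group[1:]:
            if h.start - clusters[-1][-1].end > params.max_locus_gap:
                clusters.append([h])
            else:
                clusters[-1].append(h)
        seq_len = len(index.genome[chrom])
        for cl in clusters:
            chain = _best_colinear_chain(cl, strand)
            cov = _protein_coverage(chain, m)
            chain_score = sum(h.score for h in chain)
            start = max(0, min(h.start for h in chain) - params.flank)
            end = min(seq_len, max(h.end for h in chain) + params.flank)
            loci.append(
                CandidateLocus(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    flank=params.flank,
                    evidence={
                        "similarity_pass": min(h.evalue for h in cl)
                        <= params.evalue_threshold,
                        "chain_pass": cov >= params.min_chain_cov,
                    },
                    evalue=min(h.evalue for h in cl),
                    chain_cov=cov,
                    chain_score=chain_score,
                    hits=cl,
                )
            )
    loci = _merge_overlapping(loci, params.merge_overlap)
    loci.sort(key=lambda l: (-l.chain_score, l.evalue, l.chrom, l.start))
    return loci


def _best_colinear_chain(hits: list[Hit], strand: str) -> list[Hit]:
    """Highest-scoring chain with consistent protein/genome ordering."""
    order = sorted(hits, key=lambda h: (h.start, h.prot_start))
    n = len(order)
    score = [h.score for h in order]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = order[j], order[i]
            # extensions overrun exon boundaries, so tolerate modest overlap
            if strand == "+":
                ok = b.prot_start >= a.prot_end - 20 and b.start >= a.end - 60
            else:
                ok = b.prot_end <= a.prot_start + 20 and b.start >= a.end - 60
            if ok and score[j] + order[i].score > score[i]:
                score[i] = score[j] + order[i].score
                prev[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(order[best])
        best = prev[best]
    return chain[::-1]


def _protein_coverage(hits: list[Hit], protein_len: int) -> float:
    covered = np.zeros(protein_len, dtype=bool)
    for h in hits:
        covered[h.prot_start : h.prot_end] = True
    return float(covered.mean())


def _merge_overlapping(loci: list[CandidateLocus], frac: float) -> list[CandidateLocus]:
    """Merge loci on the same chromosome overlapping by more than ``frac``."""
    out: list[CandidateLocus] = []
    for loc in sorted(loci, key=lambda l: (l.chrom, l.start)):
        merged = False
        for prev in out:
            if prev.chrom != loc.chrom:
                continue
            ov = max(0, min(prev.end, loc.end) - max(prev.start, loc.start))
            if ov > frac * min(prev.end - prev.start, loc.end - loc.start):
                prev.start = min(prev.start, loc.start)
                prev.end = max(prev.end, loc.end)
                if loc.evalue < prev.evalue:
                    prev.evalue = loc.evalue
                    prev.strand = loc.strand
                prev.chain_cov = max(prev.chain_cov, loc.chain_cov)
                prev.chain_score = max(prev.chain_score, loc.chain_score)
                prev.evidence = {
                    "similarity_pass": prev.evidence["similarity_pass"]
                    or loc.evidence["similarity_pass"],
                    "chain_pass": prev.evidence["chain_pass"]
                    or loc.evidence["chain_pass"],
                }
                prev.hits.extend(loc.hits)
                merged = True
                break
        if not merged:
            out.append(loc)
    return out
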