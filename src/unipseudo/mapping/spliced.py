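"""Frameshift- and intron-aware protein-to-genome alignment.

Semi-global dynamic programme: the whole protein is aligned, genome flanks
are free.  States: codon match (BLOSUM62 over the translated codon), codon
insertion/deletion (3 nt), frameshift (1-2 nt, heavy penalty), intron
(open cost, canonical GT..AG bonus, introns fall between codons), and stop
traversal (recorded and penalised, never terminating).  Ties are broken by a
fixed move priority (match > frameshift > codon gap > intron), then leftmost
genome coordinate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..coords import Interval
from ..genetics import (
    BLOSUM62_MATRIX,
    CODON_AA_TABLE,
    STOP_AA,
    X_AA,
    encode_dna,
    encode_protein,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme.  The stop penalty sits below one frameshift so a
    genuine premature stop is never re-read as a pair of compensating
    frameshifts; two frameshifts (-30) always lose to one stop (-12)."""

    frameshift: float = -15.0
    intron_open: float = -10.0
    canonical_bonus: float = 5.0
    stop_penalty: float = -12.0
    gap_codon: float = -12.0
    min_intron: int = 30
    mismatch_floor: float = -4.0  # codons containing non-ACGT bases


# move codes
M_NONE, M_MATCH, M_STOP, M_PDEL, M_GINS, M_FSDEL1, M_FSDEL2, M_FSINS1, M_FSINS2, M_INTRON, M_INTRON_C = range(11)

_CODON_CONSUME_NT = {M_MATCH: 3, M_STOP: 3, M_FSDEL1: 2, M_FSDEL2: 1}


@njit(cache=True)
def _dp_kernel(prot, gen, blosum, codon_aa, stop_aa, x_aa,
               fs, intron_open, canon_bonus, stop_pen, gap_codon,
               min_intron, mismatch_floor):  # pragma: no cover - numba
    m = prot.shape[0]
    n = gen.shape[0]
    NEG = -1e18
    D = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    move = np.zeros((m + 1, n + 1), dtype=np.int8)
    origin = np.full((m + 1, n + 1), -1, dtype=np.int32)

    # codon amino-acid index at genome position j-3..j (index by start pos)
    codon_at = np.full(n, -1, dtype=np.int8)
    for j in range(n - 2):
        a, b, c = gen[j], gen[j + 1], gen[j + 2]
        if a < 4 and b < 4 and c < 4:
            codon_at[j] = codon_aa[16 * a + 4 * b + c]

    for j in range(n + 1):
        D[0, j] = 0.0
    for i in range(1, m + 1):
        D[i, 0] = D[i - 1, 0] + gap_codon
        move[i, 0] = 3  # M_PDEL

    for i in range(m + 1):
        best_any = NEG
        best_any_j = -1
        best_gt = NEG
        best_gt_j = -1
        for j in range(n + 1):
            # admit donor candidate j' = j - min_intron into the running maxima
            jp = j - min_intron
            if jp >= 0:
                v = D[i, jp]
                if v > best_any:
                    best_any = v
                    best_any_j = jp
                if jp + 1 < n and gen[jp] == 2 and gen[jp + 1] == 3:  # G, T
                    if v > best_gt:
                        best_gt = v
                        best_gt_j = jp
            if i == 0:
                continue  # row 0 fixed to 0 (free leading genome)
            best = D[i, j]
            bmove = move[i, j]
            borigin = -1
            # 1. codon match / stop traversal
            if j >= 3:
                ci = codon_at[j - 3]
                if ci >= 0:
                    if ci == stop_aa:
                        s = D[i - 1, j - 3] + stop_pen
                        if s > best:
                            best = s
                            bmove = 2  # M_STOP
                    else:
                        s = D[i - 1, j - 3] + blosum[prot[i - 1], ci]
                        if s > best:
                            best = s
                            bmove = 1  # M_MATCH
                else:
                    s = D[i - 1, j - 3] + mismatch_floor
                    if s > best:
                        best = s
                        bmove = 1
            # 2-3. frameshift deletions (codon shown by 2 or 1 nt)
            if j >= 2:
                s = D[i - 1, j - 2] + fs
                if s > best:
                    best = s
                    bmove = 5  # M_FSDEL1
            if j >= 1:
                s = D[i - 1, j - 1] + fs
                if s > best:
                    best = s
                    bmove = 6  # M_FSDEL2
            # 4-5. frameshift insertions (1 or 2 extra nt)
            if j >= 1:
                s = D[i, j - 1] + fs
                if s > best:
                    best = s
                    bmove = 7  # M_FSINS1
            if j >= 2:
                s = D[i, j - 2] + fs
                if s > best:
                    best = s
                    bmove = 8  # M_FSINS2
            # 6. protein codon deleted from genome
            s = D[i - 1, j] + gap_codon
            if s > best:
                best = s
                bmove = 3  # M_PDEL
            # 7. genome codon insertion
            if j >= 3:
                s = D[i, j - 3] + gap_codon
                if s > best:
                    best = s
                    bmove = 4  # M_GINS
            # 8. canonical intron (donor GT, acceptor AG)
            if j >= 2 and gen[j - 2] == 0 and gen[j - 1] == 2:  # A, G
                if best_gt > NEG:
                    s = best_gt + intron_open + canon_bonus
                    if s > best:
                        best = s
                        bmove = 10  # M_INTRON_C
                        borigin = best_gt_j
            # 9. any intron
            if best_any > NEG:
                s = best_any + intron_open
                if s > best:
                    best = s
                    bmove = 9  # M_INTRON
                    borigin = best_any_j
            D[i, j] = best
            move[i, j] = bmove
            origin[i, j] = borigin
    return D, move, origin


_py_dp_kernel = _dp_kernel.py_func if _HAVE_NUMBA else _dp_kernel


@dataclass
class RawEvent:
    """Raw frameshift/stop observation in segment-local coordinates."""

    kind: str  # premature_stop | frameshift_ins | frameshift_del
    protein_pos: int  # 1-based codon on the reference protein
    genome_pos: int  # 0-based, segment-local
    size: int = 0  # nt, for frameshifts


@dataclass
class SplicedAlignment:
    gene_id: str
    chrom: str
    strand: str
    offset: int  # chromosome coordinate of segment position 0 (plus strand)
    seg_len: int
    score: float
    coverage: float
    blocks: list[tuple[int, int, int, int]]  # (prot_start, prot_end, g_start, g_end)
    introns: list[tuple[int, int, bool]]  # (g_start, g_end, canonical)
    events: list[RawEvent] = field(default_factory=list)
    # per reference codon (0-based): segment-local genome start of its codon,
    # or -1 if unaligned; parallel identity flags
    codon_pos: np.ndarray | None = None
    codon_identical: np.ndarray | None = None
    protein_length: int = 0

    def genome_coord(self, local: int) -> int:
        """Segment-local position -> chromosome plus-strand coordinate.

        For minus-strand alignments ``offset`` is the locus end, so local
        position x maps to offset - x."""
        if self.strand == "+":
            return self.offset + local
        return self.offset - local

    def identity_profile(self) -> list[float]:
        out = []
        for ps, pe, _, _ in self.blocks:
            ids = self.codon_identical[ps:pe]
            out.append(float(np.mean(ids)) if len(ids) else 0.0)
        return out

    def window_identity(self, protein_pos: int, window_codons: int = 10) -> float:
        """Mean codon identity over +-window_codons around a 1-based codon."""
        i = protein_pos - 1
        lo = max(0, i - window_codons)
        hi = min(self.protein_length, i + window_codons + 1)
        mask = self.codon_pos[lo:hi] >= 0
        if not mask.any():
            return 0.0
        return float(np.mean(self.codon_identical[lo:hi][mask]))

    def boundary_distance(self, local_pos: int) -> int:
        """Distance (nt) from a segment-local position to the nearest
        inferred intron boundary; large when there are no introns."""
        best = 10**9
        for s, e, _ in self.introns:
            best = min(best, abs(local_pos - s), abs(local_pos - e))
        return best


def align_protein_to_segment(
    protein: str,
    segment: str,
    params: AlignParams = AlignParams(),
    gene_id: str = "",
    chrom: str = "",
    strand: str = "+",
    offset: int = 0,
) -> SplicedAlignment:
    """Align ``protein`` against a genomic ``segment`` (given 5'->3' in the
    reading orientation; for minus-strand loci pass the reverse complement
    and the matching offset)."""
    if len(segment) < 3:
        raise AlignmentError("segment shorter than one codon")
    if not protein:
        raise AlignmentError("empty protein")
    prot = encode_protein(protein)
    gen = encode_dna(segment)
    kernel = _dp_kernel if _HAVE_NUMBA else _py_dp_kernel
    D, move, origin = kernel(
        prot,
        gen,
        BLOSUM62_MATRIX,
        CODON_AA_TABLE,
        np.int8(STOP_AA),
        np.int8(X_AA),
        params.frameshift,
        params.intron_open,
        params.canonical_bonus,
        params.stop_penalty,
        params.gap_codon,
        params.min_intron,
        params.mismatch_floor,
    )
    m, n = len(prot), len(gen)
    row = D[m]
    best_j = int(np.flatnonzero(row == row.max())[0])  # leftmost optimum
    score = float(row[best_j])
    return _traceback(
        protein, move, origin, m, best_j, score, params, gene_id, chrom, strand, offset, n
    )


def _traceback(
    protein, move, origin, m, j, score, params, gene_id, chrom, strand, offset, seg_len
) -> SplicedAlignment:
    i = m
    events: list[RawEvent] = []
    introns: list[tuple[int, int, bool]] = []
    codon_pos = np.full(m, -1, dtype=np.int64)
    codon_identical = np.zeros(m, dtype=bool)
    consumed: list[tuple[int, int, int]] = []  # (prot_idx, g_start, g_end) codon cells
    aligned_res = 0
    while i > 0:
        mv = move[i, j]
        if mv == M_NONE:
            break
        if mv in (M_MATCH, M_STOP):
            g = j - 3
            codon_pos[i - 1] = g
            consumed.append((i - 1, g, j))
            aligned_res += 1
            if mv == M_STOP:
                events.append(RawEvent("premature_stop", i, g, 0))
            i, j = i - 1, g
        elif mv == M_FSDEL1:
            events.append(RawEvent("frameshift_del", i, j - 2, 1))
            codon_pos[i - 1] = j - 2
            consumed.append((i - 1, j - 2, j))
            aligned_res += 1
            i, j = i - 1, j - 2
        elif mv == M_FSDEL2:
            events.append(RawEvent("frameshift_del", i, j - 1, 2))
            codon_pos[i - 1] = j - 1
            consumed.append((i - 1, j - 1, j))
            aligned_res += 1
            i, j = i - 1, j - 1
        elif mv == M_FSINS1:
            events.append(RawEvent("frameshift_ins", i + 1, j - 1, 1))
            j -= 1
        elif mv == M_FSINS2:
            events.append(RawEvent("frameshift_ins", i + 1, j - 2, 2))
            j -= 2
        elif mv == M_PDEL:
            i -= 1
        elif mv == M_GINS:
            j -= 3
        elif mv in (M_INTRON, M_INTRON_C):
            jp = int(origin[i, j])
            introns.append((jp, j, mv == M_INTRON_C))
            j = jp
        else:  # pragma: no cover
            break

    events.reverse()
    introns.reverse()
    consumed.reverse()

    # identity flags are filled later by annotate_identity
    blocks: list[tuple[int, int, int, int]] = []
    for pi, gs, ge in consumed:
        if blocks and blocks[-1][1] == pi and blocks[-1][3] == gs:
            ps, pe, bs, be = blocks[-1]
            blocks[-1] = (ps, pi + 1, bs, ge)
        else:
            blocks.append((pi, pi + 1, gs, ge))

    aln = SplicedAlignment(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        offset=offset,
        seg_len=seg_len,
        score=score,
        coverage=aligned_res / m,
        blocks=blocks,
        introns=introns,
        events=events,
        codon_pos=codon_pos,
        codon_identical=codon_identical,
        protein_length=m,
    )
    return aln


def annotate_identity(aln: SplicedAlignment, protein: str, segment: str) -> None:
    """Fill codon_identical by re-translating the aligned codons."""
    from ..genetics import translate

    for idx in range(aln.protein_length):
        g = int(aln.codon_pos[idx])
        if g < 0:
            continue
        codon = segment[g : g + 3]
        if len(codon) == 3:
            aln.codon_identical[idx] = translate(codon) == protein[idx]


def align_locus(
    protein: str,
    genome: dict[str, str],
    locus: Interval,
    params: AlignParams = AlignParams(),
    gene_id: str = "",
) -> SplicedAlignment:
    """Align a protein to a genomic locus, honouring strand."""
    from ..genetics import revcomp

    seq = genome[locus.chrom][locus.start : locus.end]
    if locus.strand == "-":
        seg = revcomp(seq)
        offset = locus.end  # genome_coord(local) = end - local
    else:
        seg = seq
        offset = locus.start
    aln = align_protein_to_segment(
        protein, seg, params, gene_id=gene_id, chrom=locus.chrom,
        strand=locus.strand, offset=offset,
    )
    annotate_identity(aln, protein, seg)
    return aln
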