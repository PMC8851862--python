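"""Codon alignment construction and Gblocks-style masking.

Alignment is protein-guided: a centre-star progressive alignment of the
translated CDS, back-translated to codons, adequate for the synthetic
divergence ceiling (0.3).  Masking removes gap/ambiguity columns with two
flanking codons (6 bp rounded outward to codon boundaries) on each side plus
low-conservation windows, iterated to a fixed point so masking is idempotent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from ..genetics import BLOSUM62, translate


class GroupError(ValueError):
    pass


@dataclass
class OrthologGroup:
    gene_id: str
    cds: dict[str, str]  # species -> CDS, disruptions already excised
    tree: str  # newick; foreground tagged or named below
    foreground: str
    min_members: int = 2

    def __post_init__(self) -> None:
        if len(self.cds) < self.min_members:
            raise GroupError(f"{self.gene_id}: fewer than {self.min_members} members")
        if self.foreground not in self.cds:
            raise GroupError(f"{self.gene_id}: foreground {self.foreground} absent")
        for sp, seq in self.cds.items():
            if len(seq) % 3:
                raise GroupError(f"{self.gene_id}/{sp}: CDS length not a multiple of 3")
            aa = translate(seq)
            if "*" in aa[:-1] or not aa:
                raise GroupError(f"{self.gene_id}/{sp}: CDS untranslatable")


@dataclass
class CodonAlignment:
    """Codon-columned MSA: species -> list of codons ('---' = gap)."""

    rows: dict[str, list[str]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, idx: int) -> dict[str, str]:
        return {sp: row[idx] for sp, row in self.rows.items()}


@dataclass
class FilteredCodonAlignment:
    alignment: CodonAlignment  # retained columns only
    retained_columns: list[int]  # original codon column indices
    removal_mask: dict[int, str] = field(default_factory=dict)  # idx -> reason
    dropped: bool = False

    @property
    def final_length_nt(self) -> int:
        return 3 * len(self.retained_columns)


def _pairwise_protein(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.mode = "global"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def build_codon_alignment(group: OrthologGroup) -> CodonAlignment:
    """Centre-star protein alignment back-translated to whole codons."""
    species = sorted(group.cds)
    prots = {sp: translate(group.cds[sp]).rstrip("*") for sp in species}
    center = max(species, key=lambda sp: (len(prots[sp]), sp))
    others = [sp for sp in species if sp != center]

    m = len(prots[center])
    # per pairwise alignment: insertions before each center residue (and end)
    inserts: dict[str, list[list[str]]] = {}
    aligned_to: dict[str, list[str]] = {}  # per center residue: aa or '-'
    for sp in others:
        ca, oa = _pairwise_protein(prots[center], prots[sp])
        ins: list[list[str]] = [[] for _ in range(m + 1)]
        matched: list[str] = []
        ci = 0
        for x, y in zip(ca, oa):
            if x == "-":
                ins[ci].append(y)
            else:
                matched.append(y)
                ci += 1
        inserts[sp] = ins
        aligned_to[sp] = matched

    slot_width = [0] * (m + 1)
    for sp in others:
        for i in range(m + 1):
            slot_width[i] = max(slot_width[i], len(inserts[sp][i]))

    def codon_feed(sp: str):
        cds = group.cds[sp]
        pos = 0

        def next_codon() -> str:
            nonlocal pos
            c = cds[pos : pos + 3]
            pos += 3
            return c

        return next_codon

    rows: dict[str, list[str]] = {sp: [] for sp in species}
    feeds = {sp: codon_feed(sp) for sp in species}
    for i in range(m + 1):
        width = slot_width[i]
        for sp in species:
            if sp == center:
                rows[sp].extend(["---"] * width)
            else:
                found = inserts[sp][i]
                rows[sp].extend(feeds[sp]() for _ in found)
                rows[sp].extend(["---"] * (width - len(found)))
        if i < m:
            rows[center].append(feeds[center]())
            for sp in others:
                aa = aligned_to[sp][i]
                rows[sp].append(feeds[sp]() if aa != "-" else "---")
    return CodonAlignment(rows=rows)


def _column_conservation(col: dict[str, str]) -> float:
    aas = [translate(c) for c in col.values()]
    best = max(aas.count(a) for a in set(aas))
    return best / len(aas)


def mask_alignment(
    aln: CodonAlignment,
    gap_flank_nt: int = 6,
    min_len_nt: int = 150,
    quality_window: int = 5,
    min_conservation: float = 0.5,
) -> FilteredCodonAlignment:
    """Remove gap/ambiguity columns (+flanks) and low-quality windows.

    The flank is ``gap_flank_nt`` rounded outward to whole codons.  Both rules
    are iterated until stable, so mask(mask(x)) == mask(x).  Alignments ending
    below ``min_len_nt`` are flagged dropped.
    """
    flank_codons = -(-gap_flank_nt // 3)
    n = aln.n_columns
    retained = list(range(n))
    mask: dict[int, str] = {}

    def is_bad(idx: int) -> bool:
        col = aln.column(idx)
        return any(c == "---" or any(b not in "ACGT" for b in c) for c in col.values())

    changed = True
    while changed:
        changed = False
        # gap/ambiguity columns + flanks (flanks measured on retained columns)
        bad_positions = [p for p, idx in enumerate(retained) if is_bad(idx)]
        to_drop: set[int] = set()
        for p in bad_positions:
            for q in range(max(0, p - flank_codons), min(len(retained), p + flank_codons + 1)):
                to_drop.add(q)
        if to_drop:
            for p in to_drop:
                mask[retained[p]] = "gap_flank"
            retained = [idx for p, idx in enumerate(retained) if p not in to_drop]
            changed = True
            continue
        # low-quality windows on the surviving columns
        cons = [_column_conservation(aln.column(idx)) for idx in retained]
        drop: set[int] = set()
        for p in range(0, max(0, len(retained) - quality_window + 1)):
            window = cons[p : p + quality_window]
            if sum(window) / quality_window < min_conservation:
                drop.update(range(p, p + quality_window))
        if drop:
            for p in drop:
                mask[retained[p]] = "low_quality"
            retained = [idx for p, idx in enumerate(retained) if p not in drop]
            changed = True

    filtered = CodonAlignment(
        rows={sp: [row[i] for i in retained] for sp, row in aln.rows.items()}
    )
    out = FilteredCodonAlignment(
        alignment=filtered, retained_columns=retained, removal_mask=mask
    )
    out.dropped = out.final_length_nt < min_len_nt
    return out
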