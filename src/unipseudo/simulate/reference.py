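"""Reference genome/proteome generation.

Genes are multi-exon, plus-strand, non-overlapping, with ATG starts, GT..AG
introns and a single terminal stop.  Intron boundaries fall on codon
boundaries (phase-0 introns), which keeps the spliced aligner's
intron-between-codons model exact on synthetic data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..coords import Interval
from ..genetics import SENSE_CODONS, translate
from ..models import GeneModel
from .config import ConfigError, SimConfig


@dataclass
class GenePart:
    kind: str  # "exon" | "intron"
    seq: str


@dataclass
class Segment:
    """One structural piece of a chromosome: an intergenic spacer or a gene."""

    kind: str  # "intergenic" | "gene"
    seq: str = ""
    gene_id: str = ""
    parts: list[GenePart] = field(default_factory=list)


@dataclass
class ReferenceBundle:
    """Assembly plus the structural parts needed to evolve a query from it."""

    config: SimConfig
    assembly: dict[str, str]
    genes: list[GeneModel]
    segments: dict[str, list[Segment]]

    @property
    def gene_index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.n_codons for g in self.genes}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one terminal stop."""
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 1)]
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _make_gene_parts(rng: np.random.Generator, config: SimConfig) -> list[GenePart]:
    n_codons = int(rng.integers(config.codons_per_gene[0], config.codons_per_gene[1] + 1))
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    cds = _random_cds(rng, n_codons)
    total_codons = n_codons + 1  # incl. terminal stop
    n_exons = min(n_exons, total_codons)
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, total_codons), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *(int(c) * 3 for c in cuts), total_codons * 3]
    parts: list[GenePart] = []
    for i in range(n_exons):
        parts.append(GenePart("exon", cds[bounds[i] : bounds[i + 1]]))
        if i < n_exons - 1:
            ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            if ilen < 8:
                raise ConfigError("intron_len must allow >= 8 nt")
            parts.append(GenePart("intron", "GT" + _random_seq(rng, ilen - 4) + "AG"))
    return parts


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Build a deterministic reference assembly, gene models and proteome."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom_name
    segments: list[Segment] = []
    genes: list[GeneModel] = []
    pos = 0
    pieces: list[str] = []

    def add_intergenic() -> None:
        nonlocal pos
        length = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        seq = _random_seq(rng, length)
        segments.append(Segment("intergenic", seq=seq))
        pieces.append(seq)
        pos += length

    add_intergenic()
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        parts = _make_gene_parts(rng, config)
        exons: list[Interval] = []
        p = pos
        for part in parts:
            if part.kind == "exon":
                exons.append(Interval(chrom, p, p + len(part.seq)))
            p += len(part.seq)
        cds = "".join(part.seq for part in parts if part.kind == "exon")
        protein = translate(cds)[:-1]  # drop terminal stop
        assert "*" not in protein, "internal stop in generated CDS"
        genes.append(GeneModel(gene_id, chrom, "+", exons, protein, cds))
        segments.append(Segment("gene", gene_id=gene_id, parts=parts))
        pieces.append("".join(part.seq for part in parts))
        pos = p
        add_intergenic()

    return ReferenceBundle(
        config=config,
        assembly={chrom: "".join(pieces)},
        genes=genes,
        segments={chrom: segments},
    )
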