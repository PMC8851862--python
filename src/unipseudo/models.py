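"""Core annotation objects shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

from .coords import Interval


@dataclass
class GeneModel:
    """A reference protein-coding gene: exon structure + protein + flags.

    ``exons`` are genomic intervals (0-based half-open) of the CDS pieces in
    transcription order; the spliced CDS includes the terminal stop codon,
    ``protein`` does not include the stop.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    protein: str
    cds: str
    # annotation-support flags
    predicted: bool = False
    intronless_cdna: bool = False
    tsl_level: int = 1
    has_ccds: bool = True
    family: str = ""  # gene-family label ("" = none)

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def n_codons(self) -> int:
        return len(self.protein)

    def attributes(self) -> dict[str, str]:
        return {
            "predicted": "1" if self.predicted else "0",
            "intronless_cdna": "1" if self.intronless_cdna else "0",
            "tsl": str(self.tsl_level),
            "ccds": "1" if self.has_ccds else "0",
            "family": self.family,
        }


@dataclass
class SyntenyBlock:
    """Orthologous interval pair between reference and query assemblies."""

    gene_id: str
    ref: Interval
    query: Interval
    strand: str = "+"


@dataclass
class ReadSupportTrack:
    """Per-base read support, run-length encoded.

    ``runs[chrom]`` is a list of (start, end, depth, support) tuples covering
    the chromosome; support is the number of reads agreeing with the assembly
    base.
    """

    runs: dict[str, list[tuple[int, int, int, int]]] = field(default_factory=dict)

    def at(self, chrom: str, pos: int) -> tuple[int, int] | None:
        for start, end, depth, support in self.runs.get(chrom, ()):
            if start <= pos < end:
                return depth, support
        return None

    def min_fraction(self, chrom: str, start: int, end: int) -> tuple[float, int] | None:
        """Lowest support fraction over [start, end) and the depth there."""
        best: tuple[float, int] | None = None
        for s, e, depth, support in self.runs.get(chrom, ()):
            if s < end and start < e and depth > 0:
                frac = support / depth
                if best is None or frac < best[0]:
                    best = (frac, depth)
        return best

    def length(self, chrom: str) -> int:
        r = self.runs.get(chrom)
        return r[-1][1] if r else 0
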