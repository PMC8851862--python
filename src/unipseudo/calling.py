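"""Convert spliced alignments into disruption lists and locus status calls."""
from __future__ import annotations

from dataclasses import dataclass, field

from .mapping.spliced import SplicedAlignment
from .models import ReadSupportTrack

DISRUPTION_KINDS = ("premature_stop", "frameshift_ins", "frameshift_del")


@dataclass
class Disruption:
    kind: str
    protein_pos: int  # 1-based codon index on the reference protein
    genome_pos: int  # 0-based on the query assembly (plus strand)
    size: int = 0  # nt, frameshifts only
    window_identity: float = 1.0  # identity over 30 bp up- and downstream
    boundary_distance: int = 10**9  # nt to the nearest intron/exon boundary
    read_support: float | None = None  # supporting/total reads, None = unknown
    read_depth: int = 0
    valid: bool = True
    void_reason: str = ""

    @property
    def frame_offset(self) -> int:
        """Signed frame change: insertions positive, deletions negative."""
        if self.kind == "frameshift_ins":
            return self.size
        if self.kind == "frameshift_del":
            return -self.size
        return 0


@dataclass
class PseudogeneCall:
    gene_id: str
    species: str
    alignment: SplicedAlignment
    disruptions: list[Disruption]
    truncated_fraction: float
    status: str = "putative"  # putative | removed:<reason> | retained
    filter_trail: list[tuple[str, str, str]] = field(default_factory=list)

    def log(self, stage: str, rule: str, decision: str) -> None:
        self.filter_trail.append((stage, rule, decision))

    def valid_disruptions(self) -> list[Disruption]:
        return [d for d in self.disruptions if d.valid]


def call_disruptions(
    aln: SplicedAlignment,
    track: ReadSupportTrack | None = None,
    window_codons: int = 10,
) -> list[Disruption]:
    """One record per in-frame premature stop and per frame-breaking indel.

    Consecutive indels within one codon are merged into a single event of net
    size; indel groups whose net offset is a multiple of 3 are dropped (one
    mutational event that does not break the frame).  The reference terminal
    stop is never aligned (the protein excludes it), so it never appears.
    """
    merged: dict[tuple[str, int], list] = {}
    stops = []
    for ev in aln.events:
        if ev.kind == "premature_stop":
            stops.append(ev)
        else:
            merged.setdefault(("fs", ev.protein_pos), []).append(ev)

    out: list[Disruption] = []
    for ev in stops:
        out.append(
            _annotate(
                Disruption("premature_stop", ev.protein_pos, _chrom_pos(aln, ev.genome_pos, 3)),
                aln,
                ev.genome_pos,
                3,
                track,
            )
        )
    for (_, pos), evs in merged.items():
        net = sum(e.size if e.kind == "frameshift_ins" else -e.size for e in evs)
        if net % 3 == 0:
            continue
        size = abs(net) % 3
        kind = "frameshift_ins" if net > 0 else "frameshift_del"
        local = min(e.genome_pos for e in evs)
        out.append(
            _annotate(
                Disruption(kind, pos, _chrom_pos(aln, local, max(1, abs(net))), size=size),
                aln,
                local,
                max(1, abs(net)),
                track,
            )
        )
    out.sort(key=lambda d: d.protein_pos)
    return out


def _chrom_pos(aln: SplicedAlignment, local: int, width: int) -> int:
    a = aln.genome_coord(local)
    b = aln.genome_coord(local + width)
    return min(a, b)


def _annotate(
    d: Disruption,
    aln: SplicedAlignment,
    local: int,
    width: int,
    track: ReadSupportTrack | None,
) -> Disruption:
    d.window_identity = aln.window_identity(d.protein_pos)
    d.boundary_distance = aln.boundary_distance(local)
    if track is not None:
        lo = d.genome_pos
        hi = d.genome_pos + max(1, width)
        res = track.min_fraction(aln.chrom, lo, hi)
        if res is not None:
            d.read_support, d.read_depth = res
    return d


def classify_locus(
    aln: SplicedAlignment,
    disruptions: list[Disruption],
    coverage_floor: float = 0.5,
) -> str:
    """putative_pseudogenic | intact | unalignable."""
    if aln.coverage < coverage_floor:
        return "unalignable"
    return "putative_pseudogenic" if disruptions else "intact"


def truncated_fraction(disruptions: list[Disruption], protein_length: int) -> float:
    """Longest intact N-terminal fraction before the first disruption."""
    if not disruptions:
        return 1.0
    first = min(d.protein_pos for d in disruptions)
    return (first - 1) / protein_length


def make_call(
    gene_id: str,
    species: str,
    aln: SplicedAlignment,
    track: ReadSupportTrack | None = None,
    coverage_floor: float = 0.5,
) -> tuple[str, PseudogeneCall | None]:
    """Classify one aligned locus; returns (status, call-or-None)."""
    disruptions = call_disruptions(aln, track)
    status = classify_locus(aln, disruptions, coverage_floor)
    if status != "putative_pseudogenic":
        return status, None
    call = PseudogeneCall(
        gene_id=gene_id,
        species=species,
        alignment=aln,
        disruptions=disruptions,
        truncated_fraction=truncated_fraction(disruptions, aln.protein_length),
    )
    call.log("calling", "classify_locus", "putative_pseudogenic")
    return status, call
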