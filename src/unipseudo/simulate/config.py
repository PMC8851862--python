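"""Simulation plan: configuration, planned events, and the truth table."""
from __future__ import annotations

from dataclasses import dataclass, field

EVENT_KINDS = frozenset(
    {
        "premature_stop",
        "frameshift_ins",
        "frameshift_del",
        "compensatory_pair",
        "duplicate_copy",
        "retrocopy",
        "family_paralog",
        "assembly_error",
        "relaxed_evolution",
    }
)

#: kinds that disrupt the primary locus ORF for real
DISRUPTIVE_KINDS = frozenset({"premature_stop", "frameshift_ins", "frameshift_del"})
#: kinds that plant an extra copy of the gene elsewhere
COPY_KINDS = frozenset({"duplicate_copy", "retrocopy", "family_paralog"})


class PlanError(ValueError):
    """Raised when an event plan is internally inconsistent."""


class ConfigError(ValueError):
    """Raised when a SimConfig cannot be realized."""


@dataclass(frozen=True)
class PlannedEvent:
    gene_id: str
    kind: str
    codon_position: int | None = None  # 1-based codon on the reference protein
    size: int | None = None  # nt, for frameshifts
    copy_coverage: float | None = None  # fraction of protein, for copies
    k: float | None = None  # selection intensity, for relaxed_evolution

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise PlanError(f"unknown event kind {self.kind!r}")
        if self.kind in ("frameshift_ins", "frameshift_del"):
            if self.size not in (1, 2):
                raise PlanError("frameshift size must be 1 or 2 nt")
        if self.kind in COPY_KINDS:
            cov = 1.0 if self.copy_coverage is None else self.copy_coverage
            if not 0 < cov <= 1:
                raise PlanError("copy_coverage must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int
    exons_per_gene: tuple[int, int] = (1, 4)
    codons_per_gene: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (60, 200)
    intergenic_len: tuple[int, int] = (400, 1200)
    divergence: float = 0.05
    kappa: float = 2.0  # transition/transversion rate bias
    omega_intact: float = 0.2  # dN/dS for CDS of functional genes
    omega_lost: float = 0.8  # dN/dS for CDS of genuinely lost genes
    seed: int = 0
    event_plan: tuple[PlannedEvent, ...] = ()
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        for name in ("exons_per_gene", "codons_per_gene", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"range {name}={lo, hi} empty or non-positive")
        if not 0 <= self.divergence <= 0.3:
            raise ConfigError("divergence must lie in [0, 0.3]")
        if self.exons_per_gene[0] < 1:
            raise ConfigError("genes need at least one exon")


@dataclass
class TruthRecord:
    gene_id: str
    kind: str
    chrom: str = ""
    start: int = -1  # 0-based half-open on the emitted query assembly
    end: int = -1
    codon_position: int | None = None
    size: int | None = None
    detail: str = ""


@dataclass
class TruthTable:
    """Machine-readable ground truth for one simulated query genome."""

    fates: dict[str, str] = field(default_factory=dict)  # gene -> intact|lost|artifact_only
    events: list[TruthRecord] = field(default_factory=list)
    error_sites: list[tuple[str, int, int]] = field(default_factory=list)

    def events_for(self, gene_id: str, kinds: frozenset | None = None) -> list[TruthRecord]:
        return [
            e
            for e in self.events
            if e.gene_id == gene_id and (kinds is None or e.kind in kinds)
        ]

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def to_rows(self) -> list[dict]:
        return [
            {
                "gene_id": e.gene_id,
                "kind": e.kind,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "codon_position": "" if e.codon_position is None else e.codon_position,
                "size": "" if e.size is None else e.size,
                "detail": e.detail,
            }
            for e in self.events
        ]


def validate_plan(config: SimConfig, gene_lengths: dict[str, int]) -> None:
    """Check event plan against realized gene lengths (codons).

    Raises PlanError on unknown genes, out-of-range codon positions, or two
    point events colliding on the same codon of the same gene.
    """
    seen: set[tuple[str, int]] = set()
    for ev in config.event_plan:
        if ev.gene_id not in gene_lengths:
            raise PlanError(f"event references unknown gene {ev.gene_id!r}")
        n_codons = gene_lengths[ev.gene_id]
        positions: list[int] = []
        if ev.kind in DISRUPTIVE_KINDS or ev.kind == "assembly_error":
            if ev.codon_position is None:
                raise PlanError(f"{ev.kind} needs codon_position")
            positions = [ev.codon_position]
        elif ev.kind == "compensatory_pair":
            if ev.codon_position is None:
                raise PlanError("compensatory_pair needs codon_position")
            positions = [ev.codon_position, ev.codon_position + 10]
        for pos in positions:
            # keep point events off the start codon and terminal region
            if not 2 <= pos <= n_codons - 2:
                raise PlanError(
                    f"codon_position {pos} outside [2, {n_codons - 2}] for {ev.gene_id}"
                )
            key = (ev.gene_id, pos)
            if key in seen:
                raise PlanError(f"event collision at codon {pos} of {ev.gene_id}")
            seen.add(key)
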