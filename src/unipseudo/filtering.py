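"""Unitary-status and false-positive filters, applied as a logged cascade.

Stage 1 (unitary status): gene-family exclusion, predicted/intronless
annotation, functional redundancy from copy chains, conserved genomic
position.  Stage 2 (false positives): terminal/boundary/low-identity
disruption voiding, read-support confirmation, annotation support (TSL/CCDS),
and compensatory-frameshift removal.  Every removal carries exactly one
primary reason.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .calling import Disruption, PseudogeneCall
from .coords import Interval
from .mapping.chains import CopyChain
from .models import GeneModel


@dataclass(frozen=True)
class FilterThresholds:
    copy_cov: float = 0.8
    trunc: float = 0.9
    window: int = 30  # nt of context on each side of a disruption
    min_identity: float = 0.4
    boundary_nt: int = 10
    read_support_min: float = 0.8
    read_depth_min: int = 5


@dataclass
class FilterContext:
    genes: dict[str, GeneModel]
    family_exclusion: tuple[str, ...] = (
        "olfactory receptor",
        "zinc finger",
        "vomeronasal receptor",
    )
    copy_chains: dict[str, list[CopyChain]] = field(default_factory=dict)
    synteny_map: dict[str, Interval] = field(default_factory=dict)
    check_reads: bool = True  # read validation is optional per species
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    warnings: list[str] = field(default_factory=list)


@dataclass
class CascadeReport:
    species: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    removal_reasons: dict[str, str] = field(default_factory=dict)  # gene -> reason
    trails: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    STAGES = (
        "candidate_loci",
        "putative_pseudogenic",
        "unitary",
        "false_positives_removed",
        "relaxed_selection",
    )

    def ordered_counts(self) -> list[tuple[str, int]]:
        return [(s, self.counts[s]) for s in self.STAGES if s in self.counts]


def _family_hit(gene: GeneModel, keywords: tuple[str, ...]) -> bool:
    label = gene.family.lower()
    if not label:
        return False
    return any(kw.lower() in label or label in kw.lower() for kw in keywords)


def unitary_status_filter(call: PseudogeneCall, ctx: FilterContext) -> str:
    """Returns 'passed' or 'removed:<reason>' and updates the call."""
    if not call.status.startswith("putative"):
        raise ValueError(f"call {call.gene_id} not in putative state")
    gene = ctx.genes[call.gene_id]
    t = ctx.thresholds

    if _family_hit(gene, ctx.family_exclusion):
        return _remove(call, "unitary", "gene_family")
    call.log("unitary", "gene_family", "pass")

    if gene.predicted or gene.intronless_cdna:
        return _remove(call, "unitary", "predicted_or_intronless")
    call.log("unitary", "predicted_or_intronless", "pass")

    for chain in ctx.copy_chains.get(call.gene_id, []):
        if chain.covered_fraction >= t.copy_cov:
            return _remove(call, "unitary", "redundancy")
    call.log("unitary", "redundancy", "pass")

    syn = ctx.synteny_map.get(call.gene_id)
    if syn is None:
        call.log("unitary", "synteny", "no_synteny_record")
        return _remove(call, "unitary", "non_syntenic")
    aln = call.alignment
    coords = [aln.genome_coord(b) for blk in aln.blocks for b in (blk[2], blk[3])]
    locus = Interval(aln.chrom, min(coords), max(coords))
    if not locus.overlaps(syn):
        return _remove(call, "unitary", "non_syntenic")
    call.log("unitary", "synteny", "pass")
    return "passed"


def false_positive_filter(call: PseudogeneCall, ctx: FilterContext) -> str:
    """Rules a-d in order; returns 'passed' or 'removed:<reason>'."""
    t = ctx.thresholds

    # (a) GeneWise-style alignment artefacts
    if len(call.disruptions) == 1 and call.truncated_fraction > t.trunc:
        _void(call, call.disruptions[0], "terminal")
    for d in call.disruptions:
        if not d.valid:
            continue
        if d.boundary_distance <= t.boundary_nt:
            _void(call, d, "boundary")
        elif d.window_identity < t.min_identity:
            _void(call, d, "low_identity")
    call.log("fp", "a_alignment", f"{len(call.valid_disruptions())} valid")

    # (b) read support
    if ctx.check_reads:
        for d in call.valid_disruptions():
            if d.read_support is None:
                ctx.warnings.append(
                    f"{call.gene_id}: disruption at {d.genome_pos} has unknown "
                    "read support; passing"
                )
                continue
            if d.read_depth >= t.read_depth_min and d.read_support < t.read_support_min:
                _void(call, d, "read_unsupported")
        call.log("fp", "b_reads", f"{len(call.valid_disruptions())} valid")
    else:
        call.log("fp", "b_reads", "skipped")

    valid = call.valid_disruptions()
    if not valid:
        return _remove(call, "fp", "no_valid_disruption")

    # (c) annotation support of the reference gene
    gene = ctx.genes[call.gene_id]
    if gene.tsl_level not in (1, 2) and not gene.has_ccds:
        return _remove(call, "fp", "annotation_support")
    call.log("fp", "c_annotation", "pass")

    # (d) exactly two compensatory frameshifts, nothing else
    if _is_compensatory_only(valid):
        return _remove(call, "fp", "compensatory_frameshifts")
    call.log("fp", "d_compensatory", "pass")
    return "passed"


def _is_compensatory_only(disruptions: list[Disruption]) -> bool:
    if len(disruptions) != 2:
        return False
    a, b = sorted(disruptions, key=lambda d: d.protein_pos)
    if a.kind == "premature_stop" or b.kind == "premature_stop":
        return False
    return (a.frame_offset + b.frame_offset) % 3 == 0


def _remove(call: PseudogeneCall, stage: str, reason: str) -> str:
    call.status = f"removed:{reason}"
    call.log(stage, reason, "removed")
    return call.status


def _void(call: PseudogeneCall, d: Disruption, reason: str) -> None:
    d.valid = False
    d.void_reason = reason
    call.log("fp", f"void_{reason}", f"{d.kind}@{d.protein_pos}")


def apply_filter_cascade(
    calls: list[PseudogeneCall],
    ctx: FilterContext,
    n_candidate_loci: int | None = None,
    species: str = "",
) -> tuple[list[PseudogeneCall], CascadeReport]:
    """Unitary filters then FP filters; per-stage counts never increase.

    The relaxed-selection gate is a separate downstream stage; callers append
    its count to the returned report.
    """
    report = CascadeReport(species=species)
    if n_candidate_loci is not None:
        report.counts["candidate_loci"] = n_candidate_loci
    report.counts["putative_pseudogenic"] = len(calls)

    survivors: list[PseudogeneCall] = []
    for call in calls:
        if unitary_status_filter(call, ctx) == "passed":
            survivors.append(call)
        else:
            report.removal_reasons[call.gene_id] = call.status.split(":", 1)[1]
    report.counts["unitary"] = len(survivors)

    final: list[PseudogeneCall] = []
    for call in survivors:
        if false_positive_filter(call, ctx) == "passed":
            call.status = "retained"
            final.append(call)
        else:
            report.removal_reasons[call.gene_id] = call.status.split(":", 1)[1]
    report.counts["false_positives_removed"] = len(final)

    for call in calls:
        report.trails[call.gene_id] = list(call.filter_trail)
    return final, report
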