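"""End-to-end pipeline: map -> align -> call -> filter -> relax gate.

Every stage logs structured records (stage, gene, action) and writes its
table to the run directory; stage counts are non-increasing down the
cascade.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ..calling import PseudogeneCall, make_call
from ..coords import Interval
from ..filtering import CascadeReport, FilterContext, FilterThresholds, apply_filter_cascade
from ..genetics import STOP_CODONS, revcomp, translate
from ..mapping import (
    AlignParams,
    CandidateLocus,
    GenomeIndex,
    SearchParams,
    SplicedAlignment,
    align_locus,
    chain_hits_into_copies,
    find_candidate_loci,
)
from ..models import GeneModel, ReadSupportTrack
from ..relax import (
    GroupError,
    OrthologGroup,
    RelaxationResult,
    build_codon_alignment,
    estimate_omega,
    mask_alignment,
    relaxation_test,
)
from ..relax.gate import selection_intensity
from . import formats
from .config import PipelineConfig

log = logging.getLogger("unipseudo")

STAGES = ("map", "align", "call", "filter", "relax")


class StageError(RuntimeError):
    def __init__(self, stage: str, record: str, message: str):
        super().__init__(f"stage {stage} failed at {record}: {message}")
        self.stage = stage
        self.record = record


@dataclass
class PipelineData:
    genes: list[GeneModel]
    query_assembly: dict[str, str]
    synteny: dict[str, Interval] = field(default_factory=dict)
    support: ReadSupportTrack | None = None
    control_assembly: dict[str, str] | None = None

    @property
    def gene_index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class PipelineResult:
    loci: dict[str, list[CandidateLocus]] = field(default_factory=dict)
    called: dict[str, CandidateLocus] = field(default_factory=dict)
    copy_chains: dict[str, list] = field(default_factory=dict)
    alignments: dict[str, SplicedAlignment] = field(default_factory=dict)
    statuses: dict[str, str] = field(default_factory=dict)
    calls: list[PseudogeneCall] = field(default_factory=list)
    final: list[PseudogeneCall] = field(default_factory=list)
    report: CascadeReport = field(default_factory=CascadeReport)
    relax: dict[str, RelaxationResult] = field(default_factory=dict)

    def final_gene_ids(self) -> set[str]:
        return {c.gene_id for c in self.final}


def load_data(config: PipelineConfig) -> PipelineData:
    ref_assembly = formats.read_fasta(Path(config.reference_fasta))
    genes = formats.parse_gff3(Path(config.reference_gff3), ref_assembly)
    query = formats.read_fasta(Path(config.query_fasta))
    synteny = formats.read_synteny(Path(config.synteny)) if config.synteny else {}
    support = formats.read_support(Path(config.read_support)) if config.read_support else None
    control = formats.read_fasta(Path(config.control_fasta)) if config.control_fasta else None
    return PipelineData(genes, query, synteny, support, control)


def _search_params(config: PipelineConfig) -> SearchParams:
    return SearchParams(
        evalue_threshold=config.evalue,
        n_decoys=config.n_decoys,
        min_chain_cov=config.min_chain_cov,
        flank=config.flank,
        decoy_seed=config.seed + 1234,
    )


def _log(stage: str, gene: str, action: str, **extra) -> None:
    log.info(json.dumps({"stage": stage, "gene": gene, "action": action, **extra}))


def stage_map(data: PipelineData, config: PipelineConfig, result: PipelineResult) -> None:
    params = _search_params(config)
    index = GenomeIndex(data.query_assembly, k=params.seed_k)
    for gene in data.genes:
        try:
            loci = find_candidate_loci(gene.protein, index, gene.gene_id, params)
        except Exception as exc:
            raise StageError("map", gene.gene_id, str(exc)) from exc
        result.loci[gene.gene_id] = loci
        passing = [l for l in loci if l.passes]
        # an intronless copy can outscore the true locus; prefer the
        # syntenic one when a synteny map is available
        syn = data.synteny.get(gene.gene_id)
        called = None
        if syn is not None:
            called = next((l for l in passing if l.interval.overlaps(syn)), None)
        if called is None:
            called = next(iter(passing), None)
        if called is not None:
            result.called[gene.gene_id] = called
            other_hits = [h for l in loci if l is not called for h in l.hits]
            result.copy_chains[gene.gene_id] = chain_hits_into_copies(
                other_hits, len(gene.protein), min_cov=config.copy_cov,
                evalue_threshold=config.evalue, gene_id=gene.gene_id,
            )
        else:
            result.statuses[gene.gene_id] = "unmapped"
        _log("map", gene.gene_id, "called" if called else "unmapped", n_loci=len(loci))


def stage_align(data: PipelineData, config: PipelineConfig, result: PipelineResult) -> None:
    gene_index = data.gene_index
    for gene_id, locus in result.called.items():
        gene = gene_index[gene_id]
        try:
            aln = align_locus(
                gene.protein, data.query_assembly, locus.interval,
                AlignParams(), gene_id=gene_id,
            )
        except Exception as exc:
            raise StageError("align", gene_id, str(exc)) from exc
        result.alignments[gene_id] = aln
        _log("align", gene_id, "aligned", coverage=round(aln.coverage, 3),
             n_events=len(aln.events))


def stage_call(data: PipelineData, config: PipelineConfig, result: PipelineResult) -> None:
    for gene_id, aln in result.alignments.items():
        status, call = make_call(
            gene_id, config.species, aln, data.support, config.coverage_floor
        )
        result.statuses[gene_id] = status
        if call is not None:
            result.calls.append(call)
        _log("call", gene_id, status)


def stage_filter(data: PipelineData, config: PipelineConfig, result: PipelineResult) -> None:
    ctx = FilterContext(
        genes=data.gene_index,
        family_exclusion=config.family_exclusion,
        copy_chains=result.copy_chains,
        synteny_map=data.synteny,
        check_reads=config.check_reads and data.support is not None,
        thresholds=FilterThresholds(
            copy_cov=config.copy_cov,
            trunc=config.trunc,
            window=config.window,
            min_identity=config.min_identity,
            boundary_nt=config.boundary_nt,
            read_support_min=config.read_support_min,
            read_depth_min=config.read_depth_min,
        ),
    )
    result.final, result.report = apply_filter_cascade(
        result.calls, ctx, n_candidate_loci=len(result.called), species=config.species
    )
    for w in ctx.warnings:
        log.warning(w)
    for stage, count in result.report.ordered_counts():
        _log("filter", "*", stage, count=count)


def _clean_codon_positions(aln: SplicedAlignment, call: PseudogeneCall, segment: str) -> list[int]:
    """Reference codon indices usable for the ortholog-group CDS: aligned,
    full 3-nt, stop-free, and at least one codon away from any disruption."""
    bad: set[int] = set()
    for d in call.disruptions:
        p = d.protein_pos - 1
        bad.update((p - 1, p, p + 1))
    out = []
    for i in range(aln.protein_length):
        g = int(aln.codon_pos[i])
        if g < 0 or i in bad:
            continue
        codon = segment[g : g + 3]
        if len(codon) != 3 or any(b not in "ACGT" for b in codon) or codon in STOP_CODONS:
            continue
        out.append(i)
    return out


def _segment_for(aln: SplicedAlignment, assembly: dict[str, str]) -> str:
    if aln.strand == "+":
        return assembly[aln.chrom][aln.offset : aln.offset + aln.seg_len]
    return revcomp(assembly[aln.chrom][aln.offset - aln.seg_len : aln.offset])


def stage_relax(data: PipelineData, config: PipelineConfig, result: PipelineResult) -> None:
    """Relaxed-selection gate on the calls that survived the filter cascade."""
    if not config.relax_gate:
        result.report.counts["relaxed_selection"] = len(result.final)
        return
    gene_index = data.gene_index
    control_index = None
    control_params = None
    if data.control_assembly is not None:
        control_params = _search_params(config)
        control_index = GenomeIndex(data.control_assembly, k=control_params.seed_k)
    gated: list[PseudogeneCall] = []
    for call in list(result.final):
        gene = gene_index[call.gene_id]
        aln = result.alignments[call.gene_id]
        segment = _segment_for(aln, data.query_assembly)
        positions = _clean_codon_positions(aln, call, segment)
        members: dict[str, dict[int, str]] = {
            config.reference_species: {
                i: gene.cds[3 * i : 3 * i + 3] for i in positions
            },
            config.species: {i: segment[int(aln.codon_pos[i]) : int(aln.codon_pos[i]) + 3] for i in positions},
        }
        if control_index is not None:
            ctrl = _control_codons(gene, control_index, control_params, data, positions)
            if ctrl:
                members[config.control_species] = ctrl
                positions = sorted(set(positions) & set(ctrl))
        cds = {
            sp: "".join(codons[i] for i in positions if i in codons)
            for sp, codons in members.items()
        }
        cds = {sp: s for sp, s in cds.items() if s}
        labels = sorted(cds)
        tree = "(" + ",".join(f"{sp}:0.05" for sp in labels) + ");"
        try:
            group = OrthologGroup(call.gene_id, cds, tree, foreground=config.species)
            masked = mask_alignment(
                build_codon_alignment(group),
                gap_flank_nt=config.gap_flank,
                min_len_nt=config.min_aln,
            )
            if masked.dropped:
                res = RelaxationResult(
                    call.gene_id, None, None, None, None, False, "alignment_too_short"
                )
            else:
                est = estimate_omega(masked.alignment, tree, config.species)
                res = relaxation_test(est, call.gene_id, seed=config.seed)
                if res.k is not None:
                    res.retained = (
                        res.omega_fg > res.omega_bg and res.k < config.k_threshold
                    )
        except GroupError as exc:
            res = RelaxationResult(call.gene_id, None, None, None, None, False, str(exc))
        result.relax[call.gene_id] = res
        if res.retained:
            gated.append(call)
        else:
            call.status = "removed:relaxed_selection"
            call.log("relax", "gate", res.reason or "not_relaxed")
        _log("relax", call.gene_id, "retained" if res.retained else "removed",
             omega_fg=res.omega_fg, omega_bg=res.omega_bg, k=res.k)
    result.final = gated
    result.report.counts["relaxed_selection"] = len(gated)


def _control_codons(gene, control_index, params, data, positions) -> dict[int, str] | None:
    loci = find_candidate_loci(gene.protein, control_index, gene.gene_id, params)
    called = next((l for l in loci if l.passes), None)
    if called is None:
        return None
    aln = align_locus(gene.protein, data.control_assembly, called.interval,
                      AlignParams(), gene_id=gene.gene_id)
    segment = _segment_for(aln, data.control_assembly)
    out = {}
    for i in positions:
        g = int(aln.codon_pos[i])
        if g < 0:
            continue
        codon = segment[g : g + 3]
        if len(codon) == 3 and all(b in "ACGT" for b in codon) and codon not in STOP_CODONS:
            out[i] = codon
    return out


def run_stages(
    data: PipelineData,
    config: PipelineConfig,
    outdir: Path | None = None,
    upto: str = "relax",
) -> PipelineResult:
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    result = PipelineResult()
    limit = STAGES.index(upto)
    runners = (stage_map, stage_align, stage_call, stage_filter, stage_relax)
    for i, runner in enumerate(runners):
        if i > limit:
            break
        runner(data, config, result)
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def run_pipeline(config: PipelineConfig, outdir: Path | None = None, upto: str = "relax") -> PipelineResult:
    return run_stages(load_data(config), config, outdir, upto)


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    formats.write_tsv(
        outdir / "loci.tsv",
        ["gene_id", "chrom", "start", "end", "strand", "evalue", "chain_cov",
         "similarity_pass", "chain_pass", "called"],
        [
            [gid, l.chrom, l.start, l.end, l.strand, f"{l.evalue:.3g}",
             f"{l.chain_cov:.3f}", int(l.evidence.get("similarity_pass", False)),
             int(l.evidence.get("chain_pass", False)),
             int(result.called.get(gid) is l)]
            for gid, loci in sorted(result.loci.items())
            for l in loci
        ],
    )
    formats.write_tsv(
        outdir / "alignments.tsv",
        ["gene_id", "chrom", "strand", "score", "coverage", "n_blocks",
         "n_introns", "n_events"],
        [
            [gid, a.chrom, a.strand, f"{a.score:.1f}", f"{a.coverage:.3f}",
             len(a.blocks), len(a.introns), len(a.events)]
            for gid, a in sorted(result.alignments.items())
        ],
    )
    formats.write_tsv(
        outdir / "disruptions.tsv",
        ["gene_id", "species", "kind", "protein_pos", "chrom", "genome_pos",
         "size", "window_identity", "boundary_distance", "read_support",
         "valid", "void_reason", "status"],
        [
            [c.gene_id, c.species, d.kind, d.protein_pos, c.alignment.chrom,
             d.genome_pos, d.size, f"{d.window_identity:.3f}",
             d.boundary_distance if d.boundary_distance < 10**9 else "",
             "" if d.read_support is None else f"{d.read_support:.3f}",
             int(d.valid), d.void_reason, c.status]
            for c in result.calls
            for d in c.disruptions
        ],
    )
    formats.write_tsv(
        outdir / "cascade_report.tsv",
        ["stage", "count"],
        [[s, c] for s, c in result.report.ordered_counts()],
    )
    formats.write_tsv(
        outdir / "filter_trail.tsv",
        ["gene_id", "stage", "rule", "decision"],
        [
            [gid, stage, rule, decision]
            for gid, trail in sorted(result.report.trails.items())
            for stage, rule, decision in trail
        ],
    )
    formats.write_tsv(
        outdir / "relax.tsv",
        ["gene_id", "omega_fg", "omega_bg", "k", "p_relax", "retained", "reason"],
        [
            [gid,
             "" if r.omega_fg is None else f"{r.omega_fg:.4f}",
             "" if r.omega_bg is None else f"{r.omega_bg:.4f}",
             "" if r.k is None else f"{r.k:.4f}",
             "" if r.p_relax is None else f"{r.p_relax:.4f}",
             int(r.retained), r.reason]
            for gid, r in sorted(result.relax.items())
        ],
    )
    formats.write_tsv(
        outdir / "final_calls.tsv",
        ["gene_id", "species", "n_disruptions", "truncated_fraction", "status"],
        [
            [c.gene_id, c.species, len(c.valid_disruptions()),
             f"{c.truncated_fraction:.3f}", c.status]
            for c in sorted(result.final, key=lambda c: c.gene_id)
        ],
    )


def score_against_truth(final_gene_ids: set[str], fates: dict[str, str]) -> dict:
    """Confusion summary against a simulation truth table."""
    lost = {g for g, f in fates.items() if f == "lost"}
    tp = len(final_gene_ids & lost)
    fp = len(final_gene_ids - lost)
    fn = len(lost - final_gene_ids)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / len(lost) if lost else float("nan"),
        "precision": tp / len(final_gene_ids) if final_gene_ids else float("nan"),
    }
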