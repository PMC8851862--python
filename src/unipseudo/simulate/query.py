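"""Query genome evolution: neutral divergence + planted gene-fate events.

Intact CDS accumulates only synonymous substitutions so that intactness is
preserved; introns and intergenic sequence diverge neutrally with a
transition/transversion bias.  Every planted event is realized and logged in
the TruthTable with coordinates on the emitted query assembly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..coords import Interval
from ..genetics import SYNONYMOUS, STOP_CODONS, translate
from ..models import GeneModel, ReadSupportTrack, SyntenyBlock
from .config import (
    COPY_KINDS,
    DISRUPTIVE_KINDS,
    PlannedEvent,
    SimConfig,
    TruthRecord,
    TruthTable,
    validate_plan,
)
from .reference import ReferenceBundle, Segment, _random_seq

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}


@dataclass
class QueryBundle:
    assembly: dict[str, str]
    truth: TruthTable
    synteny: list[SyntenyBlock]


def _mutate_neutral(rng: np.random.Generator, seq: str, div: float, kappa: float) -> str:
    """i.i.d. substitutions at expected rate ``div`` with ts/tv bias kappa."""
    if div <= 0 or not seq:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < div)
    p_ts = kappa / (kappa + 2.0)
    for i in hits:
        base = out[i]
        if base not in "ACGT":
            continue
        if rng.random() < p_ts:
            out[i] = _TS[base]
        else:
            out[i] = _TV[base][rng.integers(0, 2)]
    return "".join(out)


def _mutate_cds(
    rng: np.random.Generator, codons: list[str], div: float, omega: float
) -> None:
    """Synonymous-biased codon substitutions at roughly per-site rate ``div``.

    Candidate single-nucleotide changes that are non-synonymous are accepted
    with probability ``omega``, otherwise replaced by a synonymous
    alternative when one exists; stop codons are never created, so gene
    intactness is preserved.
    """
    from ..genetics import BASES

    if div <= 0:
        return
    p = min(1.0, 3.0 * div)
    for i in range(1, len(codons)):  # never touch the start codon
        codon = codons[i]
        if codon in STOP_CODONS:
            continue
        if rng.random() >= p:
            continue
        j = int(rng.integers(0, 3))
        b = "ACGT"[rng.integers(0, 4)]
        cand = codon[:j] + b + codon[j + 1 :]
        if b == codon[j] or cand in STOP_CODONS:
            continue
        if translate(cand) == translate(codon) or rng.random() < omega:
            codons[i] = cand
        else:
            alts = SYNONYMOUS.get(codon, [])
            if alts:
                codons[i] = alts[rng.integers(0, len(alts))]


def _mutate_relaxed(
    rng: np.random.Generator, codons: list[str], div: float, omega: float
) -> int:
    """Add non-synonymous substitutions at rate div*omega; returns count."""
    from ..genetics import BASES

    n = 0
    p = min(1.0, 3.0 * div * omega)
    for i in range(1, len(codons) - 1):
        if rng.random() >= p:
            continue
        codon = codons[i]
        choices = []
        for j in range(3):
            for b in BASES:
                if b == codon[j]:
                    continue
                cand = codon[:j] + b + codon[j + 1 :]
                if cand not in STOP_CODONS and translate(cand) != translate(codon):
                    choices.append(cand)
        if choices:
            codons[i] = choices[rng.integers(0, len(choices))]
            n += 1
    return n


def _gene_fate(gene: GeneModel, events: list[PlannedEvent]) -> str:
    apparent = [
        e for e in events if e.kind in DISRUPTIVE_KINDS or e.kind in ("assembly_error", "compensatory_pair")
    ]
    if not apparent:
        return "intact"
    flag_bad = (
        gene.predicted
        or gene.intronless_cdna
        or bool(gene.family)
        or (gene.tsl_level not in (1, 2) and not gene.has_ccds)
    )
    big_copy = any(
        e.kind in COPY_KINDS and (e.copy_coverage is None or e.copy_coverage >= 0.8)
        for e in events
    )
    all_fake = all(e.kind in ("assembly_error", "compensatory_pair") for e in apparent)
    real = [e for e in apparent if e.kind in DISRUPTIVE_KINDS]
    terminal_only = (
        len(real) == len(apparent) == 1
        and real[0].kind == "premature_stop"
        and real[0].codon_position is not None
        and real[0].codon_position > 0.9 * gene.n_codons
    )
    if flag_bad or big_copy or all_fake or terminal_only:
        return "artifact_only"
    return "lost"


def evolve_query(bundle: ReferenceBundle, config: SimConfig) -> QueryBundle:
    """Apply neutral divergence and the event plan; emit truth + synteny."""
    validate_plan(config, bundle.gene_lengths())
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthTable()
    synteny: list[SyntenyBlock] = []
    genes = bundle.gene_index
    plan: dict[str, list[PlannedEvent]] = {}
    for ev in config.event_plan:
        plan.setdefault(ev.gene_id, []).append(ev)

    assembly: dict[str, str] = {}
    copy_queue: list[tuple[PlannedEvent, str]] = []  # (event, copy sequence)

    for chrom, segments in bundle.segments.items():
        out: list[str] = []
        pos = 0
        for seg in segments:
            if seg.kind == "intergenic":
                seq = _mutate_neutral(rng, seg.seq, config.divergence, config.kappa)
                out.append(seq)
                pos += len(seq)
                continue
            gene = genes[seg.gene_id]
            events = plan.get(seg.gene_id, [])
            gene_start = pos
            pos = _emit_gene(
                rng, config, chrom, gene, seg, events, out, pos, truth, copy_queue
            )
            synteny.append(
                SyntenyBlock(
                    gene.gene_id,
                    gene.span,
                    Interval(chrom, gene_start, pos),
                )
            )
            truth.fates[gene.gene_id] = _gene_fate(gene, events)
        # planted copies land after the last segment, spaced by fresh sequence
        for ev, copy_seq in copy_queue:
            spacer = _random_seq(rng, 300)
            out.append(spacer)
            pos += len(spacer)
            out.append(copy_seq)
            truth.events.append(
                TruthRecord(
                    ev.gene_id,
                    ev.kind,
                    chrom,
                    pos,
                    pos + len(copy_seq),
                    detail=f"copy_coverage={ev.copy_coverage if ev.copy_coverage is not None else 1.0}",
                )
            )
            pos += len(copy_seq)
        copy_queue.clear()
        assembly[chrom] = "".join(out)

    for gene in bundle.genes:
        truth.fates.setdefault(gene.gene_id, "intact")
    return QueryBundle(assembly=assembly, truth=truth, synteny=synteny)


def _emit_gene(
    rng: np.random.Generator,
    config: SimConfig,
    chrom: str,
    gene: GeneModel,
    seg: Segment,
    events: list[PlannedEvent],
    out: list[str],
    pos: int,
    truth: TruthTable,
    copy_queue: list,
) -> int:
    # split CDS into codons (incl. terminal stop codon)
    cds = gene.cds
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    lost = any(ev.kind in DISRUPTIVE_KINDS for ev in events)
    omega = config.omega_lost if lost else config.omega_intact
    _mutate_cds(rng, codons, config.divergence, omega)

    point_edits: dict[int, tuple[str, PlannedEvent]] = {}  # codon idx (0-based) -> (op, ev)
    for ev in events:
        if ev.kind == "premature_stop":
            point_edits[ev.codon_position - 1] = ("stop", ev)
        elif ev.kind == "assembly_error":
            point_edits[ev.codon_position - 1] = ("error_stop", ev)
        elif ev.kind == "frameshift_ins":
            point_edits[ev.codon_position - 1] = ("ins", ev)
        elif ev.kind == "frameshift_del":
            point_edits[ev.codon_position - 1] = ("del", ev)
        elif ev.kind == "compensatory_pair":
            size = ev.size or 1
            point_edits[ev.codon_position - 1] = ("ins", ev)
            point_edits[ev.codon_position + 9] = ("del", ev)
        elif ev.kind == "relaxed_evolution":
            omega = 0.2 ** (ev.k if ev.k is not None else 1.0)
            n = _mutate_relaxed(rng, codons, config.divergence, omega)
            truth.events.append(
                TruthRecord(ev.gene_id, ev.kind, chrom, detail=f"k={ev.k},nonsyn={n}")
            )
        elif ev.kind in COPY_KINDS:
            cov = ev.copy_coverage if ev.copy_coverage is not None else 1.0
            n_copy = max(1, int(np.ceil(cov * gene.n_codons)))
            copy_seq = gene.cds[: 3 * n_copy]
            if ev.kind == "family_paralog":
                copy_seq = _mutate_neutral(rng, copy_seq, 0.08, config.kappa)
            copy_queue.append((ev, copy_seq))

    # walk exon parts, emitting codon by codon with edits applied
    pending_pair: dict[str, int] = {}  # compensatory pair: gene -> ins position
    codon_iter = 0  # global codon index across exons
    for part in seg.parts:
        if part.kind == "intron":
            seq = part.seq
            mid = _mutate_neutral(rng, seq[2:-2], config.divergence, config.kappa)
            out.append(seq[:2] + mid + seq[-2:])
            pos += len(seq)
            continue
        n_codons_here = len(part.seq) // 3
        for _ in range(n_codons_here):
            codon = codons[codon_iter]
            edit = point_edits.get(codon_iter)
            if edit is None:
                out.append(codon)
                pos += 3
            else:
                op, ev = edit
                if op in ("stop", "error_stop"):
                    out.append("TAA")
                    truth.events.append(
                        TruthRecord(
                            ev.gene_id,
                            "assembly_error" if op == "error_stop" else "premature_stop",
                            chrom,
                            pos,
                            pos + 3,
                            codon_position=codon_iter + 1,
                        )
                    )
                    if op == "error_stop":
                        truth.error_sites.append((chrom, pos, pos + 3))
                    pos += 3
                elif op == "ins":
                    size = ev.size or 1
                    ins = _random_seq(rng, size)
                    out.append(ins)
                    if ev.kind == "compensatory_pair":
                        pending_pair[ev.gene_id] = pos
                    else:
                        truth.events.append(
                            TruthRecord(
                                ev.gene_id,
                                "frameshift_ins",
                                chrom,
                                pos,
                                pos + size,
                                codon_position=codon_iter + 1,
                                size=size,
                                detail="ins",
                            )
                        )
                    pos += size
                    out.append(codon)
                    pos += 3
                elif op == "del":
                    size = ev.size or 1
                    out.append(codon[size:])
                    if ev.kind == "compensatory_pair":
                        truth.events.append(
                            TruthRecord(
                                ev.gene_id,
                                "compensatory_pair",
                                chrom,
                                pending_pair.pop(ev.gene_id, pos),
                                pos,
                                codon_position=ev.codon_position,
                                size=size,
                                detail="ins+del",
                            )
                        )
                    else:
                        truth.events.append(
                            TruthRecord(
                                ev.gene_id,
                                "frameshift_del",
                                chrom,
                                pos,
                                pos,
                                codon_position=codon_iter + 1,
                                size=size,
                                detail="del",
                            )
                        )
                    pos += 3 - size
            codon_iter += 1
    return pos


def emit_read_support(
    assembly: dict[str, str],
    error_sites: list[tuple[str, int, int]],
    depth: int = 30,
    seed: int = 0,
    error_support: float | None = None,
) -> ReadSupportTrack:
    """Constant-depth support track; planted error sites get low support.

    ``error_support`` (fraction of reads agreeing with the assembly base at
    error sites) is drawn in [0.05, 0.4) per site when not given.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    track = ReadSupportTrack()
    for chrom, seq in assembly.items():
        sites = sorted((s, e) for c, s, e in error_sites if c == chrom)
        runs: list[tuple[int, int, int, int]] = []
        cursor = 0
        for s, e in sites:
            if s > cursor:
                runs.append((cursor, s, depth, depth))
            frac = error_support if error_support is not None else float(rng.uniform(0.05, 0.4))
            runs.append((s, e, depth, int(np.floor(depth * frac))))
            cursor = e
        if cursor < len(seq):
            runs.append((cursor, len(seq), depth, depth))
        track.runs[chrom] = runs
    return track
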