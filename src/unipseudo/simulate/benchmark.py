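"""Standard planted-truth benchmark used by the acceptance tests.

200 genes, 40 planted losses, 40 planted artifact-only confounders at
divergence 0.05; everything derives from one seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..models import ReadSupportTrack
from .config import PlannedEvent, SimConfig
from .query import QueryBundle, emit_read_support, evolve_query
from .reference import ReferenceBundle, generate_reference


@dataclass
class BenchmarkBundle:
    reference: ReferenceBundle
    query: QueryBundle
    support: ReadSupportTrack
    config: SimConfig


def standard_benchmark(
    seed: int = 7,
    n_genes: int = 200,
    n_lost: int = 40,
    n_artifacts: int = 40,
    divergence: float = 0.05,
    depth: int = 30,
) -> BenchmarkBundle:
    base = SimConfig(
        n_genes=n_genes,
        exons_per_gene=(1, 4),
        codons_per_gene=(100, 300),
        intron_len=(60, 150),
        intergenic_len=(400, 900),
        divergence=divergence,
        seed=seed,
    )
    reference = generate_reference(base)
    rng = np.random.default_rng(seed + 99)
    lengths = reference.gene_lengths()
    gene_ids = sorted(lengths)
    chosen = list(rng.choice(gene_ids, size=n_lost + n_artifacts, replace=False))
    lost_ids, artifact_ids = chosen[:n_lost], chosen[n_lost:]

    events: list[PlannedEvent] = []
    gene_index = reference.gene_index

    def _exon_boundaries(gid: str) -> list[int]:
        """codon indices at which an exon ends (cumulative)."""
        out, cum = [], 0
        for ex in gene_index[gid].exons:
            cum += len(ex)
            out.append(cum // 3)
        return out

    def mid_codon(gid: str, clearance: int = 4) -> int:
        """Random codon away from exon boundaries; boundary-adjacent
        disruptions are untrusted by design (the FP filter voids them)."""
        n = lengths[gid]
        bounds = _exon_boundaries(gid)
        for _ in range(200):
            pos = int(rng.integers(max(2, n // 5), max(3, int(0.85 * n))))
            if all(abs(pos - b) > clearance for b in bounds):
                return pos
        return max(2, n // 2)

    # --- genuine losses: stops, frameshifts, and multi-disruption combos ---
    for i, gid in enumerate(lost_ids):
        style = i % 4
        if style == 0:
            events.append(PlannedEvent(gid, "premature_stop", codon_position=mid_codon(gid)))
        elif style == 1:
            events.append(
                PlannedEvent(gid, "frameshift_ins", codon_position=mid_codon(gid), size=1 + i % 2)
            )
        elif style == 2:
            events.append(
                PlannedEvent(gid, "frameshift_del", codon_position=mid_codon(gid), size=1 + i % 2)
            )
        else:  # stop + distant frameshift
            first = mid_codon(gid)
            second = first
            for _ in range(50):
                second = mid_codon(gid)
                if abs(second - first) >= 15:
                    break
            events.append(PlannedEvent(gid, "premature_stop", codon_position=first))
            if abs(second - first) >= 15:
                events.append(
                    PlannedEvent(gid, "frameshift_del", codon_position=second, size=1)
                )

    # --- artifacts: each should be removed by one specific filter ---
    for i, gid in enumerate(artifact_ids):
        style = i % 5
        if style == 0:  # assembly error, low read support
            events.append(PlannedEvent(gid, "assembly_error", codon_position=mid_codon(gid)))
        elif style == 1:  # two compensatory frameshifts
            n = lengths[gid]
            events.append(
                PlannedEvent(
                    gid, "compensatory_pair", codon_position=int(rng.integers(max(2, n // 5), n - 13)),
                    size=1 + i % 2,
                )
            )
        elif style == 2:  # redundant duplicate + a real-looking stop
            events.append(PlannedEvent(gid, "premature_stop", codon_position=mid_codon(gid)))
            events.append(PlannedEvent(gid, "duplicate_copy", copy_coverage=0.9))
        elif style == 3:  # predicted/intronless reference annotation
            events.append(PlannedEvent(gid, "premature_stop", codon_position=mid_codon(gid)))
            g = gene_index[gid]
            if i % 2:
                g.predicted = True
            else:
                g.intronless_cdna = True
        else:  # weak annotation support (TSL>2, no CCDS)
            events.append(PlannedEvent(gid, "premature_stop", codon_position=mid_codon(gid)))
            g = gene_index[gid]
            g.tsl_level = 4
            g.has_ccds = False

    config = replace(base, event_plan=tuple(events))
    query = evolve_query(reference, config)
    support = emit_read_support(
        query.assembly, query.truth.error_sites, depth=depth, seed=seed + 5
    )
    return BenchmarkBundle(reference=reference, query=query, support=support, config=config)
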