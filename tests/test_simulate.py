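from dataclasses import replace

import pytest

from unipseudo.genetics import translate
from unipseudo.simulate import (
    ConfigError,
    PlanError,
    PlannedEvent,
    SimConfig,
    balanced_foreground_tree,
    emit_read_support,
    evolve_query,
    generate_reference,
    simulate_codon_sequences,
)
from unipseudo.simulate.codons import ForegroundError, _neighbor_table


@pytest.fixture(scope="module")
def ref10():
    return generate_reference(SimConfig(n_genes=10, seed=1))


class TestGenerateReference:
    def test_protein_lengths_within_range(self, ref10):
        assert len(ref10.genes) == 10
        for g in ref10.genes:
            assert 100 <= g.n_codons <= 300

    def test_gene_structure_contract(self, ref10):
        for g in ref10.genes:
            assert g.cds.startswith("ATG")
            assert g.cds[-3:] in ("TAA", "TAG", "TGA")
            aa = translate(g.cds)
            assert aa[-1] == "*" and "*" not in aa[:-1]
            assert aa[:-1] == g.protein

    def test_introns_canonical(self, ref10):
        chrom = ref10.assembly["chr1"]
        for g in ref10.genes:
            for a, b in zip(g.exons, g.exons[1:]):
                intron = chrom[a.end : b.start]
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_genes_non_overlapping(self, ref10):
        spans = sorted((g.span.start, g.span.end) for g in ref10.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_exons_spliced_match_assembly(self, ref10):
        chrom = ref10.assembly["chr1"]
        for g in ref10.genes:
            assert "".join(chrom[e.start : e.end] for e in g.exons) == g.cds

    def test_deterministic(self):
        cfg = SimConfig(n_genes=5, seed=42)
        a, b = generate_reference(cfg), generate_reference(cfg)
        assert a.assembly == b.assembly
        assert [g.protein for g in a.genes] == [g.protein for g in b.genes]

    def test_zero_genes(self):
        ref = generate_reference(SimConfig(n_genes=0, seed=1))
        assert ref.genes == [] and ref.proteome() == {}

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=-1)
        with pytest.raises(ConfigError):
            SimConfig(n_genes=1, divergence=0.5)
        with pytest.raises(ConfigError):
            SimConfig(n_genes=1, codons_per_gene=(300, 100))


class TestEvolveQuery:
    def test_identity_at_zero_divergence(self):
        cfg = SimConfig(n_genes=5, seed=3, divergence=0.0)
        ref = generate_reference(cfg)
        q = evolve_query(ref, cfg)
        assert q.assembly == ref.assembly
        assert all(f == "intact" for f in q.truth.fates.values())

    def test_planted_stop_translates_at_position(self):
        cfg = SimConfig(n_genes=5, seed=3, divergence=0.0)
        ref = generate_reference(cfg)
        plan = (PlannedEvent("g0001", "premature_stop", codon_position=50),)
        q = evolve_query(ref, replace(cfg, event_plan=plan))
        rec = q.truth.events[0]
        assert q.assembly["chr1"][rec.start : rec.end] == "TAA"
        # spliced query CDS stops at codon 50
        sb = next(s for s in q.synteny if s.gene_id == "g0001")
        gene = ref.gene_index["g0001"]
        offset = sb.query.start - gene.span.start
        spliced = "".join(
            q.assembly["chr1"][e.start + offset : e.end + offset] for e in gene.exons
        )
        assert translate(spliced)[49] == "*"
        assert q.truth.fates["g0001"] == "lost"

    def test_frameshift_changes_length(self):
        cfg = SimConfig(n_genes=3, seed=5, divergence=0.0)
        ref = generate_reference(cfg)
        plan = (PlannedEvent("g0002", "frameshift_del", codon_position=30, size=2),)
        q = evolve_query(ref, replace(cfg, event_plan=plan))
        sb = next(s for s in q.synteny if s.gene_id == "g0002")
        assert len(sb.query) == len(sb.ref) - 2

    def test_duplicate_copy_present(self):
        cfg = SimConfig(n_genes=3, seed=5, divergence=0.0)
        ref = generate_reference(cfg)
        plan = (PlannedEvent("g0002", "duplicate_copy", copy_coverage=0.85),)
        q = evolve_query(ref, replace(cfg, event_plan=plan))
        rec = next(e for e in q.truth.events if e.kind == "duplicate_copy")
        copy_seq = q.assembly["chr1"][rec.start : rec.end]
        n_codons = ref.gene_index["g0002"].n_codons
        assert len(copy_seq) == 3 * int(-(-0.85 * n_codons // 1))
        assert copy_seq in ref.gene_index["g0002"].cds

    def test_truth_completeness(self):
        cfg = SimConfig(n_genes=10, seed=9, divergence=0.05)
        ref = generate_reference(cfg)
        plan = (
            PlannedEvent("g0001", "premature_stop", codon_position=40),
            PlannedEvent("g0002", "frameshift_ins", codon_position=40, size=1),
            PlannedEvent("g0003", "frameshift_del", codon_position=40, size=2),
            PlannedEvent("g0004", "compensatory_pair", codon_position=40, size=1),
            PlannedEvent("g0005", "assembly_error", codon_position=40),
            PlannedEvent("g0006", "duplicate_copy", copy_coverage=0.9),
            PlannedEvent("g0007", "retrocopy"),
        )
        q = evolve_query(ref, replace(cfg, event_plan=plan))
        for kind in set(e.kind for e in plan):
            planted = sum(1 for e in plan if e.kind == kind)
            assert q.truth.count(kind) == planted, kind
        assert len(q.truth.error_sites) == 1

    def test_event_collision_rejected(self):
        cfg = SimConfig(n_genes=2, seed=1)
        ref = generate_reference(cfg)
        plan = (
            PlannedEvent("g0001", "premature_stop", codon_position=40),
            PlannedEvent("g0001", "frameshift_ins", codon_position=40, size=1),
        )
        with pytest.raises(PlanError):
            evolve_query(ref, replace(cfg, event_plan=plan))

    def test_unknown_gene_rejected(self):
        cfg = SimConfig(n_genes=2, seed=1)
        ref = generate_reference(cfg)
        plan = (PlannedEvent("nope", "premature_stop", codon_position=40),)
        with pytest.raises(PlanError):
            evolve_query(ref, replace(cfg, event_plan=plan))

    def test_intact_genes_stay_translatable(self):
        cfg = SimConfig(n_genes=10, seed=13, divergence=0.1)
        ref = generate_reference(cfg)
        q = evolve_query(ref, cfg)
        for sb in q.synteny:
            gene = ref.gene_index[sb.gene_id]
            offset = sb.query.start - gene.span.start
            spliced = "".join(
                q.assembly["chr1"][e.start + offset : e.end + offset]
                for e in gene.exons
            )
            aa = translate(spliced)
            assert "*" not in aa[:-1], sb.gene_id

    def test_deterministic(self):
        cfg = SimConfig(n_genes=5, seed=21, divergence=0.08)
        ref = generate_reference(cfg)
        assert evolve_query(ref, cfg).assembly == evolve_query(ref, cfg).assembly


class TestReadSupport:
    def test_full_support_without_errors(self):
        track = emit_read_support({"c": "ACGT" * 10}, [], depth=30, seed=0)
        assert track.runs["c"] == [(0, 40, 30, 30)]

    def test_error_site_below_threshold(self):
        track = emit_read_support({"c": "A" * 100}, [("c", 10, 13)], depth=30, seed=0)
        low = [r for r in track.runs["c"] if r[3] < r[2]]
        assert len(low) == 1 and low[0][:2] == (10, 13)
        assert low[0][3] / low[0][2] < 0.8

    def test_track_covers_assembly(self):
        asm = {"a": "A" * 57, "b": "C" * 13}
        track = emit_read_support(asm, [("a", 5, 8)], depth=10, seed=1)
        for chrom, seq in asm.items():
            assert track.length(chrom) == len(seq)
            runs = track.runs[chrom]
            assert runs[0][0] == 0
            for r1, r2 in zip(runs, runs[1:]):
                assert r1[1] == r2[0]

    def test_depth_validation(self):
        with pytest.raises(ValueError):
            emit_read_support({"c": "AC"}, [], depth=0)


class TestCodonSimulation:
    def test_k1_tables_identical(self):
        # k=1 means the foreground process equals the background process
        assert _neighbor_table(2.0, 0.2).keys() == _neighbor_table(2.0, 0.2**1.0).keys()
        t1 = _neighbor_table(2.0, 0.2)
        t2 = _neighbor_table(2.0, 0.2**1.0)
        for codon in t1:
            assert t1[codon][2] == pytest.approx(t2[codon][2])

    def test_foreground_omega_parameterization(self):
        assert 0.2**0.5 == pytest.approx(0.4472, abs=1e-4)

    def test_no_stop_codons_emitted(self):
        tree = balanced_foreground_tree(4)
        seqs = simulate_codon_sequences(tree, 0.3, 0.5, n_codons=200, seed=2)
        for cds in seqs.values():
            aa = translate(cds)
            assert "*" not in aa

    def test_missing_foreground_rejected(self):
        with pytest.raises(ForegroundError):
            simulate_codon_sequences("(a:0.1,b:0.1);", 0.2, 0.5, n_codons=10, seed=0)

    def test_deterministic(self):
        tree = balanced_foreground_tree(4)
        a = simulate_codon_sequences(tree, 0.2, 0.5, n_codons=50, seed=5)
        b = simulate_codon_sequences(tree, 0.2, 0.5, n_codons=50, seed=5)
        assert a == b

    def test_bad_params(self):
        tree = balanced_foreground_tree(4)
        with pytest.raises(ValueError):
            simulate_codon_sequences(tree, 0.0, 0.5, n_codons=10)
        with pytest.raises(ValueError):
            simulate_codon_sequences(tree, 0.2, 0.5, n_codons=0)


def test_benchmark_fates(small_benchmark):
    fates = list(small_benchmark.query.truth.fates.values())
    assert fates.count("lost") == 12
    assert fates.count("artifact_only") == 12
    assert fates.count("intact") == 36
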