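import numpy as np
import pytest

from unipseudo.calling import Disruption, PseudogeneCall
from unipseudo.coords import Interval
from unipseudo.filtering import (
    CascadeReport,
    FilterContext,
    FilterThresholds,
    _is_compensatory_only,
    apply_filter_cascade,
    false_positive_filter,
    unitary_status_filter,
)
from unipseudo.mapping.chains import CopyChain
from unipseudo.mapping.spliced import SplicedAlignment
from unipseudo.models import GeneModel


def _gene(gene_id="g1", **kw):
    defaults = dict(
        chrom="c", strand="+",
        exons=[Interval("c", 100, 400)],
        protein="M" * 100, cds="ATG" * 100 + "TAA",
    )
    defaults.update(kw)
    return GeneModel(gene_id=gene_id, **defaults)


def _aln():
    return SplicedAlignment(
        gene_id="g1", chrom="c", strand="+", offset=100, seg_len=300, score=100.0,
        coverage=1.0, blocks=[(0, 100, 0, 300)], introns=[], events=[],
        codon_pos=np.arange(100) * 3, codon_identical=np.ones(100, dtype=bool),
        protein_length=100,
    )


def _call(disruptions=None, trunc=0.5):
    return PseudogeneCall(
        gene_id="g1", species="sp", alignment=_aln(),
        disruptions=disruptions if disruptions is not None else [
            Disruption("premature_stop", 51, 250)
        ],
        truncated_fraction=trunc,
    )


def _ctx(gene=None, **kw):
    genes = {"g1": gene if gene is not None else _gene()}
    defaults = dict(genes=genes, synteny_map={"g1": Interval("c", 50, 450)})
    defaults.update(kw)
    return FilterContext(**defaults)


class TestUnitaryFilter:
    def test_gene_family_removed(self):
        ctx = _ctx(_gene(family="olfactory receptor 12"))
        assert unitary_status_filter(_call(), ctx) == "removed:gene_family"

    def test_predicted_removed(self):
        assert unitary_status_filter(_call(), _ctx(_gene(predicted=True))) == (
            "removed:predicted_or_intronless"
        )
        assert unitary_status_filter(_call(), _ctx(_gene(intronless_cdna=True))) == (
            "removed:predicted_or_intronless"
        )

    def test_redundancy_at_085(self):
        chains = {"g1": [CopyChain("g1", [(0, 85)], 0.85, redundant=True)]}
        assert unitary_status_filter(_call(), _ctx(copy_chains=chains)) == (
            "removed:redundancy"
        )

    def test_copy_below_threshold_passes(self):
        chains = {"g1": [CopyChain("g1", [(0, 50)], 0.5, redundant=False)]}
        assert unitary_status_filter(_call(), _ctx(copy_chains=chains)) == "passed"

    def test_synteny_match_passes(self):
        assert unitary_status_filter(_call(), _ctx()) == "passed"

    def test_synteny_mismatch_removed(self):
        ctx = _ctx(synteny_map={"g1": Interval("c", 90000, 99000)})
        assert unitary_status_filter(_call(), ctx) == "removed:non_syntenic"

    def test_missing_synteny_removed_with_subreason(self):
        call = _call()
        ctx = _ctx(synteny_map={})
        assert unitary_status_filter(call, ctx) == "removed:non_syntenic"
        assert ("unitary", "synteny", "no_synteny_record") in call.filter_trail

    def test_non_putative_rejected(self):
        call = _call()
        call.status = "retained"
        with pytest.raises(ValueError):
            unitary_status_filter(call, _ctx())


class TestFalsePositiveFilter:
    def test_terminal_truncation_removed(self):
        # single stop at codon 95 of 100 -> truncated_fraction 0.94 > 0.9
        call = _call([Disruption("premature_stop", 95, 380)], trunc=0.94)
        assert false_positive_filter(call, _ctx()) == "removed:no_valid_disruption"
        assert call.disruptions[0].void_reason == "terminal"

    def test_boundary_adjacent_voided(self):
        call = _call([Disruption("premature_stop", 51, 250, boundary_distance=5)])
        assert false_positive_filter(call, _ctx()) == "removed:no_valid_disruption"
        assert call.disruptions[0].void_reason == "boundary"

    def test_low_identity_voided(self):
        call = _call([Disruption("frameshift_ins", 51, 250, size=1, window_identity=0.35)])
        assert false_positive_filter(call, _ctx()) == "removed:no_valid_disruption"
        assert call.disruptions[0].void_reason == "low_identity"

    def test_identity_040_passes(self):
        call = _call([Disruption("premature_stop", 51, 250, window_identity=0.40)])
        assert false_positive_filter(call, _ctx()) == "passed"

    def test_read_unsupported_voided(self):
        call = _call([Disruption("premature_stop", 51, 250, read_support=0.2, read_depth=30)])
        assert false_positive_filter(call, _ctx()) == "removed:no_valid_disruption"
        assert call.disruptions[0].void_reason == "read_unsupported"

    def test_unknown_read_support_passes_with_warning(self):
        ctx = _ctx()
        call = _call([Disruption("premature_stop", 51, 250, read_support=None)])
        assert false_positive_filter(call, ctx) == "passed"
        assert ctx.warnings

    def test_read_check_optional_per_species(self):
        ctx = _ctx(check_reads=False)
        call = _call([Disruption("premature_stop", 51, 250, read_support=0.1, read_depth=30)])
        assert false_positive_filter(call, ctx) == "passed"
        assert ("fp", "b_reads", "skipped") in call.filter_trail

    def test_weak_annotation_removed(self):
        call = _call()
        ctx = _ctx(_gene(tsl_level=4, has_ccds=False))
        assert false_positive_filter(call, ctx) == "removed:annotation_support"

    def test_tsl2_or_ccds_sufficient(self):
        assert false_positive_filter(_call(), _ctx(_gene(tsl_level=2, has_ccds=False))) == "passed"
        assert false_positive_filter(_call(), _ctx(_gene(tsl_level=5, has_ccds=True))) == "passed"

    def test_compensatory_pair_removed(self):
        ds = [
            Disruption("frameshift_ins", 30, 120, size=1),
            Disruption("frameshift_del", 40, 160, size=1),
        ]
        call = _call(ds)
        assert false_positive_filter(call, _ctx()) == "removed:compensatory_frameshifts"

    def test_sizes_summing_to_three_removed(self):
        ds = [
            Disruption("frameshift_ins", 30, 120, size=1),
            Disruption("frameshift_ins", 40, 160, size=2),
        ]
        assert false_positive_filter(_call(ds), _ctx()) == "removed:compensatory_frameshifts"

    def test_stop_between_frameshifts_not_compensatory(self):
        ds = [
            Disruption("frameshift_ins", 30, 120, size=1),
            Disruption("premature_stop", 35, 140),
            Disruption("frameshift_del", 40, 160, size=1),
        ]
        assert false_positive_filter(_call(ds), _ctx()) == "passed"

    def test_two_valid_disruptions_pass(self):
        ds = [
            Disruption("premature_stop", 30, 120),
            Disruption("frameshift_del", 60, 220, size=1),
        ]
        assert false_positive_filter(_call(ds), _ctx()) == "passed"


def test_is_compensatory_only_definition():
    fs = lambda kind, pos, size: Disruption(kind, pos, pos * 3, size=size)
    assert _is_compensatory_only([fs("frameshift_ins", 10, 2), fs("frameshift_del", 20, 2)])
    assert _is_compensatory_only([fs("frameshift_ins", 10, 1), fs("frameshift_ins", 20, 2)])
    assert not _is_compensatory_only([fs("frameshift_ins", 10, 1), fs("frameshift_ins", 20, 1)])
    assert not _is_compensatory_only([fs("frameshift_ins", 10, 1)])


class TestCascade:
    def test_empty_input(self):
        final, report = apply_filter_cascade([], _ctx(), n_candidate_loci=0)
        assert final == []
        assert all(c == 0 for _, c in report.ordered_counts())

    def test_counts_non_increasing(self, small_run):
        counts = [c for _, c in small_run.report.ordered_counts()]
        assert counts == sorted(counts, reverse=True)

    def test_every_removal_has_one_reason(self, small_run):
        removed = {c.gene_id for c in small_run.calls if c.status.startswith("removed")}
        assert removed == set(small_run.report.removal_reasons)
        for reason in small_run.report.removal_reasons.values():
            assert reason and ":" not in reason

    def test_confusion_matrix_clean_on_benchmark(self, small_benchmark, small_run):
        fates = small_benchmark.query.truth.fates
        final = small_run.final_gene_ids()
        lost = {g for g, f in fates.items() if f == "lost"}
        artifacts = {g for g, f in fates.items() if f == "artifact_only"}
        assert final == lost
        assert not final & artifacts

    def test_rules_within_stage_conjunctive(self):
        # a call failing several unitary predicates is removed regardless of
        # which rule fires first; retained set is order-independent
        gene = _gene(predicted=True, family="zinc finger 7")
        ctx = _ctx(gene, synteny_map={})
        call = _call()
        assert unitary_status_filter(call, ctx).startswith("removed:")

    def test_trails_recorded_for_all_calls(self, small_run):
        for call in small_run.calls:
            assert small_run.report.trails[call.gene_id]
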