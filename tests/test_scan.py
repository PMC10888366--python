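"""Lesion detection against constructed alignments and injection truth."""

from collections import Counter

import pytest

from enamelevo.model import (
    AlleleEvidence,
    GeneAlignment,
    GeneModel,
    LesionClass,
    LesionRecord,
)
from enamelevo.scan import (
    EvidenceMismatch,
    ReferenceError_,
    detect_frameshift_indels,
    detect_missing_segments,
    detect_premature_stops,
    detect_splice_lesions,
    detect_terminal_codon_mutations,
    merge_shared,
    scan_gene,
    validate_allelic,
)
from enamelevo.simulate import SimulationConfig, simulate_all

from conftest import record_key

REFS = ("R1", "R2")


def build_aln(query: str, ref: str | None = None, exons=(9, 9)) -> tuple:
    """Two references plus one query over a small 2-exon gene."""
    model = GeneModel.from_exon_lengths("G", list(exons))
    n = model.total_columns
    if ref is None:
        ref = ("ATGAAACCC" + "GTAG" + "GGGAAATAA")[:n]
    seqs = {"R1": ref, "R2": ref, "q": query}
    return GeneAlignment("G", seqs), model


class TestFrameshifts:
    def test_two_bp_deletion_detected(self):
        aln, model = build_aln("ATGAA--CC" + "GTAG" + "GGGAAATAA")
        recs = detect_frameshift_indels(aln, model, REFS)
        assert len(recs) == 1
        r = recs[0]
        assert r.kind is LesionClass.FRAMESHIFT_DELETION
        assert (r.exon, r.start, r.end) == (1, 6, 7)

    def test_in_frame_deletion_ignored(self):
        aln, model = build_aln("ATG---CCC" + "GTAG" + "GGGAAATAA")
        assert detect_frameshift_indels(aln, model, REFS) == []

    def test_insertion_relative_to_references(self):
        # references gapped at two inserted columns inside exon 1
        model = GeneModel("G", exons=((1, 1, 11),), start_codon=(1, 2, 3),
                          stop_codon=(9, 10, 11))
        ref = "ATGAA--CTAA"
        aln = GeneAlignment("G", {"R1": ref, "R2": ref, "q": "ATGAATTCTAA"})
        recs = detect_frameshift_indels(aln, model, REFS)
        assert len(recs) == 1
        r = recs[0]
        assert r.kind is LesionClass.FRAMESHIFT_INSERTION
        assert (r.start, r.end) == (6, 7)

    def test_partially_gapped_references_rejected(self):
        # a column gapped in one reference but not the other is neither a
        # clean reference column nor an insertion: the precondition fails
        model = GeneModel.from_exon_lengths("G", [9, 9])
        seqs = {"R1": "ATGA-ACCC" + "GTAG" + "GGGAAATAA",
                "R2": "ATGAAACCC" + "GTAG" + "GGGAAATAA",
                "q": "ATGAAACCC" + "GTAG" + "GGGAAATAA"}
        aln = GeneAlignment("G", seqs)
        with pytest.raises(ReferenceError_):
            detect_frameshift_indels(aln, model, REFS)

    def test_whole_exon_gap_left_to_deletion_detector(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "---------")
        assert detect_frameshift_indels(aln, model, REFS) == []


class TestStops:
    def test_premature_stop_with_coordinates(self):
        aln, model = build_aln("ATGTAACCC" + "GTAG" + "GGGAAATAA")
        recs = detect_premature_stops(aln, model, REFS)
        assert len(recs) == 1
        assert (recs[0].exon, recs[0].start, recs[0].end) == (1, 4, 6)

    def test_sense_codon_where_relative_has_stop(self):
        # CAG (glutamine) at the position where another taxon has TAG
        aln, model = build_aln("ATGCAGCCC" + "GTAG" + "GGGAAATAA")
        assert detect_premature_stops(aln, model, REFS) == []

    def test_terminal_stop_not_reported(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "GGGAAATAA")
        assert detect_premature_stops(aln, model, REFS) == []

    def test_gapped_codon_skipped(self):
        aln, model = build_aln("ATGTA-CCC" + "GTAG" + "GGGAAATAA")
        assert detect_premature_stops(aln, model, REFS) == []


class TestSplice:
    def test_donor_mutation(self):
        aln, model = build_aln("ATGAAACCC" + "ATAG" + "GGGAAATAA")
        recs = detect_splice_lesions(aln, model, REFS)
        assert len(recs) == 1
        assert (recs[0].kind, recs[0].intron, recs[0].bases) == (
            LesionClass.SPLICE_DONOR, 1, "AT")

    def test_canonical_windows_silent(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "GGGAAATAA")
        assert detect_splice_lesions(aln, model, REFS) == []

    def test_gc_donor_flagged_not_counted(self):
        aln, model = build_aln("ATGAAACCC" + "GCAG" + "GGGAAATAA")
        recs = detect_splice_lesions(aln, model, REFS)
        assert len(recs) == 1
        assert recs[0].noncanonical and recs[0].weight == 0.0

    def test_gapped_window_indeterminate(self):
        aln, model = build_aln("ATGAAACCC" + "-TAG" + "GGGAAATAA")
        assert detect_splice_lesions(aln, model, REFS) == []


class TestTerminalCodons:
    def test_start_codon_mutation(self):
        aln, model = build_aln("GTGAAACCC" + "GTAG" + "GGGAAATAA")
        recs = detect_terminal_codon_mutations(aln, model, REFS)
        assert [r.kind for r in recs] == [LesionClass.START_CODON]

    def test_termination_codon_mutation_with_coordinates(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "GGGAAACAA")
        recs = detect_terminal_codon_mutations(aln, model, REFS)
        assert [r.kind for r in recs] == [LesionClass.TERMINATION_CODON]
        assert (recs[0].start, recs[0].end) == (16, 18)

    def test_intact_terminals_silent(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "GGGAAATAA")
        assert detect_terminal_codon_mutations(aln, model, REFS) == []


class TestMissingSegments:
    def test_exon_deletion_needs_evidence(self):
        aln, model = build_aln("ATGAAACCC" + "GTAG" + "---------")
        assert detect_missing_segments(aln, model, {}) == []
        recs = detect_missing_segments(aln, model, {"q": "NRM"})
        assert len(recs) == 1
        assert (recs[0].kind, recs[0].exon_start, recs[0].exon_end) == (
            LesionClass.EXON_DELETION, 2, 2)

    def test_contiguous_spans_are_single_events(self):
        model = GeneModel.from_exon_lengths("G", [3, 3, 3, 3])
        gap = "-"
        q = gap * 3 + "GTAG" + gap * 3 + "GTAG" + "AAA" + "GTAG" + gap * 3
        ref = "ATG" + "GTAG" + "CCC" + "GTAG" + "AAA" + "GTAG" + "TAA"
        aln = GeneAlignment("G", {"R1": ref, "R2": ref, "q": q})
        recs = detect_missing_segments(aln, model, {"q": "NBR"})
        spans = [(r.exon_start, r.exon_end) for r in recs]
        assert spans == [(1, 2), (4, 4)]

    def test_whole_gene_absent_with_evidence(self):
        model = GeneModel.from_exon_lengths("G", [9])
        aln = GeneAlignment("G", {"R1": "ATGAAATAA", "R2": "ATGAAATAA"},
                            absent=("q",))
        assert detect_missing_segments(aln, model, {}) == []
        recs = detect_missing_segments(aln, model, {"q": "NBR/NRM"})
        assert [r.kind for r in recs] == [LesionClass.GENE_DELETION]


class TestAllelicValidation:
    def rec(self):
        return LesionRecord(gene="ENAM", kind=LesionClass.SPLICE_DONOR,
                            bearer="q", taxa=("q",), intron=4, bases="AT")

    def ev(self, lesion, ancestral):
        return AlleleEvidence(site="ENAM:In4Do",
                              counts={"AT": lesion, "GT": ancestral},
                              lesion_allele="AT", ancestral_allele="GT")

    def test_balanced_reads_give_half_weight(self):
        out = validate_allelic(self.rec(), self.ev(18, 17))
        assert out.allelic and out.weight == 0.5
        assert out.validation == "allelic"
        assert out.bases == "AT/GT"

    def test_homozygous_keeps_full_weight(self):
        out = validate_allelic(self.rec(), self.ev(30, 0))
        assert not out.allelic and out.weight == 1.0
        assert out.validation == "homozygous"

    def test_low_coverage_unverified(self):
        out = validate_allelic(self.rec(), self.ev(5, 4))
        assert out.validation == "unverified"
        assert out.weight == self.rec().weight

    def test_rule_table_brute_force(self):
        for cov in range(1, 40):
            for k in range(cov + 1):
                out = validate_allelic(self.rec(), self.ev(k, cov - k))
                if cov < 10:
                    assert out.validation == "unverified"
                elif k / cov >= 0.4 and (cov - k) / cov >= 0.4:
                    assert out.allelic and out.weight == 0.5
                else:
                    assert not out.allelic and out.weight == 1.0

    def test_wrong_site_rejected(self):
        ev = AlleleEvidence(site="ENAM:In9Do", counts={"AT": 20, "GT": 20},
                            lesion_allele="AT", ancestral_allele="GT")
        with pytest.raises(EvidenceMismatch):
            validate_allelic(self.rec(), ev)


class TestMerge:
    def test_shared_lesion_single_record(self):
        a = LesionRecord(gene="ENAM", kind=LesionClass.FRAMESHIFT_DELETION,
                         bearer="x", taxa=("x",), exon_start=8, exon_end=8,
                         start=3751, end=3752)
        b = a.with_taxa(["y"], bearer="y")
        merged = merge_shared([a, b], clade_table={"XY": ("x", "y")})
        assert len(merged) == 1
        assert merged[0].taxa == ("x", "y")
        assert merged[0].bearer == "XY"

    def test_distinct_locations_stay_separate(self):
        a = LesionRecord(gene="ENAM", kind=LesionClass.FRAMESHIFT_DELETION,
                         bearer="x", taxa=("x",), exon_start=8, exon_end=8,
                         start=10, end=11)
        b = LesionRecord(gene="ENAM", kind=LesionClass.FRAMESHIFT_DELETION,
                         bearer="y", taxa=("y",), exon_start=8, exon_end=8,
                         start=20, end=21)
        assert len(merge_shared([a, b])) == 2


class TestInjectionOracle:
    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_detected_equals_injection_log(self, seed):
        """Every injected lesion, and nothing else, is detected."""
        res = simulate_all(SimulationConfig(seed=seed))
        detected = []
        for gene, aln in res.alignments.items():
            detected.extend(scan_gene(aln, res.models[gene], res.references,
                                      evidence_flags=res.evidence_flags[gene]))
        det = Counter(record_key(r) for r in detected if not r.noncanonical)
        inj = Counter(record_key(r) for r in res.injection_log)
        assert det == inj

    def test_references_never_flagged(self):
        res = simulate_all(SimulationConfig(seed=31))
        for gene, aln in res.alignments.items():
            for rec in scan_gene(aln, res.models[gene], res.references,
                                 evidence_flags=res.evidence_flags[gene]):
                assert not set(rec.taxa) & set(res.references)

    def test_total_weight_identity(self):
        """Weighted total = events - 0.5 x allelic events."""
        res = simulate_all(SimulationConfig(seed=13, het_fraction=0.5))
        recs = res.injection_log
        total = sum(r.weight for r in recs)
        assert total == pytest.approx(len(recs) - 0.5 * sum(r.allelic for r in recs))
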