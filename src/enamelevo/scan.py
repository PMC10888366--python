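"""Detection and classification of gene-inactivating mutations.

The screen compares each query taxon against a designated set of intact
reference taxa (by default the non-cetacean outgroups).  The reference
reading frame is defined by the alignment columns where at least one
reference is ungapped; columns gapped in *all* references are insertions
relative to the ancestral gene.

Six lesion classes are detected: frameshift indels (length mod 3 != 0),
premature stop codons, start/termination-codon mutations, splice donor
(GT) and acceptor (AG) disruptions, and exon/whole-gene deletions (the
latter only when an explicit evidence flag marks absence as a deletion
rather than missing data).  Heterozygous lesions validated against read
evidence are down-weighted to 0.5 following a 10x-coverage / 40%-per-
allele rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Mapping

from .model import (
    AlleleEvidence,
    GAP,
    GeneAlignment,
    GeneModel,
    LesionClass,
    LesionRecord,
)

__all__ = [
    "detect_frameshift_indels",
    "detect_premature_stops",
    "detect_splice_lesions",
    "detect_terminal_codon_mutations",
    "detect_missing_segments",
    "validate_allelic",
    "merge_shared",
    "scan_gene",
    "ReferenceError_",
    "EvidenceMismatch",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class ReferenceError_(ValueError):
    """A designated reference taxon violates the intact-exon precondition."""


class EvidenceMismatch(ValueError):
    pass


def _queries(aln: GeneAlignment, references: Iterable[str]) -> list[str]:
    refs = set(references)
    present_refs = refs & set(aln.sequences)
    if not present_refs:
        raise ReferenceError_(f"{aln.gene}: no reference taxon present in alignment")
    return [t for t in aln.sequences if t not in refs]


def _insertion_columns(aln: GeneAlignment, model: GeneModel,
                       references: Iterable[str]) -> set[int]:
    """Exon columns gapped in every reference (insertions vs the ancestor)."""
    refs = [t for t in references if t in aln.sequences]
    ins: set[int] = set()
    for col in model.cds_columns():
        states = [aln.sequences[t][col - 1] for t in refs]
        if all(s == GAP for s in states):
            ins.add(col)
        elif any(s == GAP for s in states):
            raise ReferenceError_(
                f"{aln.gene}: reference gap at exon column {col} "
                "(references must have intact exons)"
            )
    return ins


def detect_frameshift_indels(aln: GeneAlignment, model: GeneModel,
                             references: Iterable[str]) -> list[LesionRecord]:
    """Frameshift insertions/deletions per query taxon.

    A lesion is a maximal within-exon run of query gaps over reference
    columns (deletion) or of query bases over reference-gap columns
    (insertion) whose length is not a multiple of 3.  Runs covering a
    whole exon are left to the exon-deletion detector.
    """
    ins_cols = _insertion_columns(aln, model, references)
    records: list[LesionRecord] = []
    for taxon in _queries(aln, references):
        seq = aln.sequences[taxon]
        for exon_idx, s, e in model.exons:
            runs: list[tuple[str, int, int]] = []  # (type, first col, last col)
            for col in range(s, e + 1):
                base = seq[col - 1]
                if col in ins_cols:
                    kind = "I" if base != GAP else None
                else:
                    kind = "D" if base == GAP else None
                if kind and runs and runs[-1][0] == kind and runs[-1][2] == col - 1:
                    runs[-1] = (kind, runs[-1][1], col)
                elif kind:
                    runs.append((kind, col, col))
            for kind, c0, c1 in runs:
                length = c1 - c0 + 1
                if kind == "D" and (c0, c1) == (s, e):
                    continue  # whole exon absent: candidate exon deletion
                if length % 3 == 0:
                    continue
                records.append(LesionRecord(
                    gene=aln.gene,
                    kind=(LesionClass.FRAMESHIFT_INSERTION if kind == "I"
                          else LesionClass.FRAMESHIFT_DELETION),
                    bearer=taxon, taxa=(taxon,),
                    exon_start=exon_idx, exon_end=exon_idx,
                    start=model.cds_of_column(c0), end=model.cds_of_column(c1),
                ))
    return records


def _reference_codons(model: GeneModel, ins_cols: set[int]) -> list[tuple[int, ...]]:
    """Triplets of non-insertion exon columns — the ancestral reading frame."""
    cols = [c for c in model.cds_columns() if c not in ins_cols]
    return [tuple(cols[i : i + 3]) for i in range(0, len(cols) - len(cols) % 3, 3)]


def detect_premature_stops(aln: GeneAlignment, model: GeneModel,
                           references: Iterable[str]) -> list[LesionRecord]:
    """In-frame TAA/TAG/TGA strictly before the annotated terminal stop.

    Codons are read in the reference frame (insertion columns skipped);
    codons containing alignment gaps in the query are skipped.  The scan
    runs on the raw alignment, so stops downstream of a frameshift are
    still reported.
    """
    ins_cols = _insertion_columns(aln, model, references)
    codons = _reference_codons(model, ins_cols)
    stop_cols = set(model.stop_codon or ())
    records = []
    for taxon in _queries(aln, references):
        seq = aln.sequences[taxon]
        for triplet in codons:
            if stop_cols & set(triplet):
                continue  # annotated termination codon
            codon = "".join(seq[c - 1] for c in triplet)
            if GAP in codon:
                continue
            if codon in STOP_CODONS:
                records.append(LesionRecord(
                    gene=aln.gene, kind=LesionClass.PREMATURE_STOP,
                    bearer=taxon, taxa=(taxon,),
                    exon_start=model.exon_of_column(triplet[0]),
                    exon_end=model.exon_of_column(triplet[0]),
                    start=model.cds_of_column(triplet[0]),
                    end=model.cds_of_column(triplet[2]),
                ))
    return records


def detect_splice_lesions(aln: GeneAlignment, model: GeneModel,
                          references: Iterable[str]) -> list[LesionRecord]:
    """Non-canonical splice windows: donor != GT, acceptor != AG.

    A GC donor is returned flagged ``noncanonical`` (weight 0, excluded
    from counts) since GC-AG introns can still be spliced.  Windows with
    gaps are indeterminate and yield nothing.
    """
    records = []
    for taxon in _queries(aln, references):
        seq = aln.sequences[taxon]
        for intron_idx, donor, acceptor in model.introns:
            for cols, canonical, kind in (
                (donor, "GT", LesionClass.SPLICE_DONOR),
                (acceptor, "AG", LesionClass.SPLICE_ACCEPTOR),
            ):
                obs = seq[cols[0] - 1] + seq[cols[1] - 1]
                if GAP in obs or obs == canonical:
                    continue
                noncanonical = kind is LesionClass.SPLICE_DONOR and obs == "GC"
                records.append(LesionRecord(
                    gene=aln.gene, kind=kind, bearer=taxon, taxa=(taxon,),
                    intron=intron_idx, bases=obs, noncanonical=noncanonical,
                    note="non-canonical donor" if noncanonical else None,
                ))
    return records


def detect_terminal_codon_mutations(aln: GeneAlignment, model: GeneModel,
                                    references: Iterable[str]) -> list[LesionRecord]:
    """Start-codon (non-ATG) and termination-codon (non-stop) mutations."""
    records = []
    for taxon in _queries(aln, references):
        seq = aln.sequences[taxon]
        if model.start_codon:
            codon = "".join(seq[c - 1] for c in model.start_codon)
            if GAP not in codon and codon != "ATG":
                exon = model.exon_of_column(model.start_codon[0])
                records.append(LesionRecord(
                    gene=aln.gene, kind=LesionClass.START_CODON,
                    bearer=taxon, taxa=(taxon,),
                    exon_start=exon, exon_end=exon,
                ))
        if model.stop_codon:
            codon = "".join(seq[c - 1] for c in model.stop_codon)
            if GAP not in codon and codon not in STOP_CODONS:
                exon = model.exon_of_column(model.stop_codon[0])
                records.append(LesionRecord(
                    gene=aln.gene, kind=LesionClass.TERMINATION_CODON,
                    bearer=taxon, taxa=(taxon,),
                    exon_start=exon, exon_end=exon,
                    start=model.cds_of_column(model.stop_codon[0]),
                    end=model.cds_of_column(model.stop_codon[2]),
                ))
    return records


def detect_missing_segments(aln: GeneAlignment, model: GeneModel,
                            evidence_flags: Mapping[str, str] | None = None
                            ) -> list[LesionRecord]:
    """Evidence-backed exon/gene deletions.

    ``evidence_flags`` maps taxon -> evidence tag ("NBR", "NRM" or
    "NBR/NRM").  Absence without a flag is missing data, not a lesion.
    In-frame whole-exon deletions still count.
    """
    flags = dict(evidence_flags or {})
    records = []
    for taxon in aln.absent:
        tag = flags.get(taxon)
        if tag:
            records.append(LesionRecord(
                gene=aln.gene, kind=LesionClass.GENE_DELETION,
                bearer=taxon, taxa=(taxon,), evidence=tag,
            ))
    for taxon, seq in aln.sequences.items():
        tag = flags.get(taxon)
        if not tag:
            continue
        gone = [
            i for i, s, e in model.exons
            if all(seq[c - 1] == GAP for c in range(s, e + 1))
        ]
        if len(gone) == model.n_exons:
            records.append(LesionRecord(
                gene=aln.gene, kind=LesionClass.GENE_DELETION,
                bearer=taxon, taxa=(taxon,), evidence=tag,
            ))
            continue
        # contiguous exon-index spans, one event each
        span: list[int] = []
        for i in gone + [None]:
            if span and (i is None or i != span[-1] + 1):
                records.append(LesionRecord(
                    gene=aln.gene, kind=LesionClass.EXON_DELETION,
                    bearer=taxon, taxa=(taxon,),
                    exon_start=span[0], exon_end=span[-1], evidence=tag,
                ))
                span = []
            if i is not None:
                span.append(i)
    return records


def validate_allelic(record: LesionRecord, evidence: AlleleEvidence) -> LesionRecord:
    """Apply the heterozygosity rule: >=10x coverage and both alleles at
    >=40% of reads -> allelic, weight 0.5; clear lesion-allele majority ->
    homozygous, weight 1; coverage <10 -> unverified, weight unchanged."""
    expected = evidence_site(record)
    if evidence.site != expected:
        raise EvidenceMismatch(
            f"evidence for site {evidence.site!r}, record is {expected!r}"
        )
    if evidence.coverage < 10:
        return replace(record, validation="unverified")
    f_lesion = evidence.fraction(evidence.lesion_allele)
    f_anc = evidence.fraction(evidence.ancestral_allele)
    if f_lesion >= 0.4 and f_anc >= 0.4:
        bases = record.bases
        if record.kind in (LesionClass.SPLICE_DONOR, LesionClass.SPLICE_ACCEPTOR):
            bases = f"{evidence.lesion_allele}/{evidence.ancestral_allele}"
        return replace(record, allelic=True, validation="allelic", bases=bases)
    return replace(record, allelic=False, validation="homozygous")


def evidence_site(record: LesionRecord) -> str:
    """Canonical site identifier used to match read evidence to a lesion."""
    if record.intron is not None:
        return f"{record.gene}:In{record.intron}{record.kind.value}"
    return f"{record.gene}:E{record.exon_start}:{record.start}"


def merge_shared(records: list[LesionRecord],
                 clade_table: Mapping[str, tuple[str, ...]] | None = None
                 ) -> list[LesionRecord]:
    """Merge per-taxon records of the same lesion (exact location match)
    into one shared event; label with a clade name when the taxon set is
    exactly a named clade."""
    by_key: dict[tuple, list[LesionRecord]] = defaultdict(list)
    order: list[tuple] = []
    for r in records:
        k = r.location_key()
        if k not in by_key:
            order.append(k)
        by_key[k].append(r)
    inverse = {}
    for name, members in (clade_table or {}).items():
        inverse[frozenset(members)] = name
    merged = []
    for k in order:
        group = by_key[k]
        taxa = tuple(sorted({t for r in group for t in (r.taxa or (r.bearer,))}))
        bearer = inverse.get(frozenset(taxa), "+".join(taxa) if len(taxa) > 1 else taxa[0])
        rep = group[0]
        merged.append(replace(rep, taxa=taxa, bearer=bearer,
                              allelic=any(r.allelic for r in group)))
    return merged


def scan_gene(aln: GeneAlignment, model: GeneModel, references: Iterable[str],
              evidence_flags: Mapping[str, str] | None = None,
              clade_table: Mapping[str, tuple[str, ...]] | None = None
              ) -> list[LesionRecord]:
    """Run all detectors on one gene and merge shared lesions."""
    records = []
    records += detect_frameshift_indels(aln, model, references)
    records += detect_premature_stops(aln, model, references)
    records += detect_splice_lesions(aln, model, references)
    records += detect_terminal_codon_mutations(aln, model, references)
    records += detect_missing_segments(aln, model, evidence_flags)
    return merge_shared(records, clade_table)
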