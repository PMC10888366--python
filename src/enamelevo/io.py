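"""Readers and writers for the pipeline's plain-text formats.

FASTA alignments go through Bio.SeqIO; tables are TSV via pandas with a
deterministic column order.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    EnamelScoreTable,
    GAP,
    GeneAlignment,
    GeneModel,
    LesionClass,
    LesionRecord,
)
from .notation import format_lesion_notation, parse_lesion_notation
from .timetree import TimeTree

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_timetree",
    "read_gene_models",
    "write_gene_models",
    "lesions_to_frame",
    "frame_to_lesions",
    "write_lesion_tsv",
    "read_lesion_tsv",
    "read_enamel_scores",
    "write_enamel_scores",
    "load_taxon_table",
    "load_clade_table",
    "load_lesion_catalog",
    "load_enamel_table",
    "load_species_tree",
]

_LESION_COLUMNS = [
    "bearer", "taxa", "gene", "class", "exon_start", "exon_end",
    "intron", "start", "end", "bases", "evidence", "note",
    "allelic", "noncanonical", "weight",
]


class AlignmentError(ValueError):
    pass


def read_alignment(path, model: GeneModel | None = None,
                   expected_taxa=None) -> GeneAlignment:
    """Read a gene alignment FASTA; all sequences must have equal length.

    Taxa in ``expected_taxa`` missing from the file are recorded on the
    returned alignment as ``absent`` (candidate exon/gene deletions or
    missing data — the distinction needs an evidence flag).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences")
    seqs = {r.id: str(r.seq).upper() for r in records}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    n = lengths.pop()
    gene = model.gene_name if model else Path(path).stem
    if model is not None and model.total_columns > n:
        raise AlignmentError(
            f"{path}: gene model spans column {model.total_columns} "
            f"but alignment has {n} columns"
        )
    absent = tuple(sorted(set(expected_taxa or ()) - set(seqs)))
    return GeneAlignment(gene=gene, sequences=seqs, absent=absent)


def write_alignment(aln: GeneAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in aln.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_timetree(path, tip_ages: dict[str, float] | None = None) -> TimeTree:
    return TimeTree.from_path(path, tip_ages=tip_ages)


# -- gene models ------------------------------------------------------


def write_gene_models(models: dict[str, GeneModel], path) -> None:
    rows = []
    for gene in sorted(models):
        m = models[gene]
        for i, s, e in m.exons:
            rows.append((gene, "exon", i, s, e))
        for i, (d1, d2), (a1, a2) in m.introns:
            rows.append((gene, "donor", i, d1, d2))
            rows.append((gene, "acceptor", i, a1, a2))
        if m.start_codon:
            rows.append((gene, "start_codon", 0, m.start_codon[0], m.start_codon[2]))
        if m.stop_codon:
            rows.append((gene, "stop_codon", 0, m.stop_codon[0], m.stop_codon[2]))
    pd.DataFrame(rows, columns=["gene", "feature", "index", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_models(path) -> dict[str, GeneModel]:
    df = pd.read_csv(path, sep="\t")
    models: dict[str, GeneModel] = {}
    for gene, sub in df.groupby("gene", sort=True):
        rows = sub.to_dict("records")
        exons = tuple(sorted(
            (int(r["index"]), int(r["start"]), int(r["end"]))
            for r in rows if r["feature"] == "exon"
        ))
        donors = {
            int(r["index"]): (int(r["start"]), int(r["end"]))
            for r in rows if r["feature"] == "donor"
        }
        acceptors = {
            int(r["index"]): (int(r["start"]), int(r["end"]))
            for r in rows if r["feature"] == "acceptor"
        }
        introns = tuple((i, donors[i], acceptors[i]) for i in sorted(donors))
        def _codon(feature):
            row = sub[sub.feature == feature]
            if row.empty:
                return None
            s, e = int(row.iloc[0].start), int(row.iloc[0].end)
            return (s, s + 1, e)
        models[str(gene)] = GeneModel(
            gene_name=str(gene), exons=exons, introns=introns,
            start_codon=_codon("start_codon"), stop_codon=_codon("stop_codon"),
        )
    return models


# -- lesion tables ----------------------------------------------------


def lesions_to_frame(records: list[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "bearer": r.bearer,
            "taxa": ";".join(r.taxa),
            "gene": r.gene,
            "class": r.kind.name,
            "exon_start": r.exon_start,
            "exon_end": r.exon_end,
            "intron": r.intron,
            "start": r.start,
            "end": r.end,
            "bases": r.bases,
            "evidence": r.evidence,
            "note": r.note,
            "allelic": r.allelic,
            "noncanonical": r.noncanonical,
            "weight": r.weight,
        })
    return pd.DataFrame(rows, columns=_LESION_COLUMNS)


def frame_to_lesions(df: pd.DataFrame) -> list[LesionRecord]:
    def _int(v):
        return None if pd.isna(v) else int(v)

    def _str(v):
        return None if pd.isna(v) or v == "" else str(v)

    out = []
    for row in df.to_dict("records"):
        out.append(LesionRecord(
            gene=str(row["gene"]),
            kind=LesionClass[str(row["class"])],
            bearer=_str(row["bearer"]) or "",
            taxa=tuple(str(row["taxa"]).split(";")) if _str(row["taxa"]) else (),
            exon_start=_int(row["exon_start"]), exon_end=_int(row["exon_end"]),
            intron=_int(row["intron"]), start=_int(row["start"]), end=_int(row["end"]),
            bases=_str(row["bases"]), evidence=_str(row["evidence"]),
            note=_str(row["note"]),
            allelic=bool(row["allelic"]), noncanonical=bool(row["noncanonical"]),
        ))
    return out


def write_lesion_tsv(records: list[LesionRecord], path) -> None:
    lesions_to_frame(records).to_csv(path, sep="\t", index=False)


def read_lesion_tsv(path) -> list[LesionRecord]:
    return frame_to_lesions(pd.read_csv(path, sep="\t"))


# -- enamel scores ----------------------------------------------------


def read_enamel_scores(path) -> EnamelScoreTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return EnamelScoreTable.from_strings(dict(zip(df.taxon, df.score)))


def write_enamel_scores(table: EnamelScoreTable, path) -> None:
    rows = sorted(table.as_strings().items())
    pd.DataFrame(rows, columns=["taxon", "score"]).to_csv(path, sep="\t", index=False)


# -- shipped reference tables -----------------------------------------


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("enamelevo") / "data" / name)


def load_taxon_table() -> pd.DataFrame:
    """Sampled taxa with group (Odontoceti/Mysticeti/Outgroup) and family."""
    return pd.read_csv(_data_path("taxa.tsv"), sep="\t")


def load_clade_table() -> dict[str, tuple[str, ...]]:
    """Named clades (families, genera, higher groups) -> member taxa."""
    df = pd.read_csv(_data_path("clades.tsv"), sep="\t")
    return {
        str(r.clade): tuple(str(r.members).split(";")) for r in df.itertuples()
    }


def load_lesion_catalog(expand_clades: bool = True) -> list[LesionRecord]:
    """The shipped inactivating-mutation catalog, one record per event."""
    df = pd.read_csv(_data_path("lesion_catalog.tsv"), sep="\t")
    clades = load_clade_table()
    records: list[LesionRecord] = []
    for r in df.itertuples():
        bearer = str(r.bearer)
        recs = parse_lesion_notation(str(r.notation), bearer=bearer)
        if expand_clades:
            members = clades.get(bearer, (bearer,))
            recs = [rec.with_taxa(members) for rec in recs]
        records.extend(recs)
    return records


def load_lesion_catalog_raw() -> pd.DataFrame:
    return pd.read_csv(_data_path("lesion_catalog.tsv"), sep="\t")


def load_enamel_table() -> EnamelScoreTable:
    return read_enamel_scores(_data_path("enamel_scores.tsv"))


def load_species_tree(n_taxa: int = 93) -> TimeTree:
    if n_taxa not in (37, 93):
        raise ValueError("shipped trees have 37 or 93 taxa")
    return TimeTree.from_path(_data_path(f"species_tree_{n_taxa}.nwk"))
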