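"""Codec for the compact lesion-catalog notation.

A catalog cell looks like::

    *ACP4*: E1-3, 11: NBR/NRM; *AMELX*: E2: 47I; In2Do: GG

Gene sections are introduced by ``*GENE*:``.  Entries within a section are
separated by ``;`` (the parser also tolerates commas, as printed in some
catalog rows).  Entry forms:

``E2: 47I`` / ``E8: 3751-3752D``      frameshift insertion / deletion
``E2: 73-75S``                        premature stop codon
``E5: 767-769TCM``                    termination-codon mutation
``E2: SCM``                           start-codon mutation
``In2Do: AT`` / ``In8Ac: GG``         splice donor / acceptor lesion
``In4Do: AT/GT (allelic variation)``  heterozygous lesion (weight 0.5)
``E3: NBR`` / ``E1-3, 11: NBR/NRM``   exon deletion(s); each
                                      comma-separated span is one event
``E8-9: NRM (no stop)``               exon deletion annotated "no stop"
``WGD (NBR/NRM)``                     whole-gene deletion

NBR = no BLAST results, NRM = no reads mapped (deletion evidence tags).
"""

from __future__ import annotations

import re
from dataclasses import replace

from .model import LesionClass, LesionRecord

__all__ = ["parse_lesion_notation", "format_lesion_notation", "LesionNotationError"]


class LesionNotationError(ValueError):
    pass


_GENE = re.compile(r"\*([A-Za-z0-9]+)\*\s*:")
_WGD = re.compile(r"WGD\s*\((NBR/NRM|NBR|NRM)\)")
_EXON_DEL = re.compile(
    r"E(\d+)(?:-(\d+))?((?:\s*,\s*\d+(?:-\d+)?)*)\s*:\s*(NBR/NRM|NBR|NRM)"
    r"(\s*\(no stop\))?"
)
_SCM = re.compile(r"E(\d+)\s*:\s*SCM")
_COORD = re.compile(r"E(\d+)\s*:\s*(\d+)(?:-(\d+))?(TCM|I|D|S)\b")
_COORD_CONT = re.compile(r"(\d+)(?:-(\d+))?(TCM|I|D|S)\b")
_SPLICE = re.compile(r"In(\d+)(Do|Ac)\s*:\s*([ACGT]{2}(?:/[ACGT]{2})?)")
_ALLELIC = re.compile(r"\(allelic variation\)")
_SEP = re.compile(r"[;,\s]+")

_INDEL = {
    "I": LesionClass.FRAMESHIFT_INSERTION,
    "D": LesionClass.FRAMESHIFT_DELETION,
    "S": LesionClass.PREMATURE_STOP,
    "TCM": LesionClass.TERMINATION_CODON,
}
_SPLICE_KIND = {"Do": LesionClass.SPLICE_DONOR, "Ac": LesionClass.SPLICE_ACCEPTOR}


def parse_lesion_notation(text: str, bearer: str = "") -> list[LesionRecord]:
    """Parse one catalog cell into individual lesion events.

    A multi-span exon-deletion entry ("E1-3, 11: NBR/NRM") yields one
    event per span.  An "(allelic variation)" flag applies to the
    immediately preceding event.
    """
    records: list[LesionRecord] = []
    gene: str | None = None
    pos = 0
    n = len(text)
    while pos < n:
        m = _SEP.match(text, pos)
        if m:
            pos = m.end()
            if pos >= n:
                break
        for pattern, handler in (
            (_GENE, "gene"),
            (_EXON_DEL, "exon_del"),
            (_SCM, "scm"),
            (_COORD, "coord"),
            (_SPLICE, "splice"),
            (_WGD, "wgd"),
            (_ALLELIC, "allelic"),
            (_COORD_CONT, "coord_cont"),
        ):
            m = pattern.match(text, pos)
            if m:
                break
        else:
            token = text[pos : pos + 25].split(";")[0]
            raise LesionNotationError(f"unrecognized token at {pos!r}: {token!r}")
        pos = m.end()
        if handler == "gene":
            gene = m.group(1)
            continue
        if handler == "allelic":
            if not records:
                raise LesionNotationError("allelic flag with no preceding lesion")
            records[-1] = replace(records[-1], allelic=True)
            continue
        if gene is None:
            raise LesionNotationError(f"lesion entry before any *GENE*: marker: {m.group(0)!r}")
        if handler == "wgd":
            records.append(
                LesionRecord(gene=gene, kind=LesionClass.GENE_DELETION, bearer=bearer,
                             evidence=m.group(1))
            )
        elif handler == "exon_del":
            spans = [(int(m.group(1)), int(m.group(2) or m.group(1)))]
            for extra in re.finditer(r"(\d+)(?:-(\d+))?", m.group(3) or ""):
                spans.append((int(extra.group(1)), int(extra.group(2) or extra.group(1))))
            note = "no stop" if m.group(5) else None
            for a, b in spans:
                records.append(
                    LesionRecord(gene=gene, kind=LesionClass.EXON_DELETION, bearer=bearer,
                                 exon_start=a, exon_end=b, evidence=m.group(4), note=note)
                )
        elif handler == "scm":
            exon = int(m.group(1))
            records.append(
                LesionRecord(gene=gene, kind=LesionClass.START_CODON, bearer=bearer,
                             exon_start=exon, exon_end=exon)
            )
        elif handler in ("coord", "coord_cont"):
            if handler == "coord":
                exon = int(m.group(1))
                start, end, code = m.group(2), m.group(3), m.group(4)
            else:
                if not records or records[-1].exon_start is None or records[-1].kind not in (
                    LesionClass.FRAMESHIFT_INSERTION,
                    LesionClass.FRAMESHIFT_DELETION,
                    LesionClass.PREMATURE_STOP,
                    LesionClass.TERMINATION_CODON,
                ):
                    raise LesionNotationError(
                        f"bare coordinate {m.group(0)!r} without a preceding exon entry"
                    )
                exon = records[-1].exon_start
                start, end, code = m.group(1), m.group(2), m.group(3)
            s = int(start)
            e = int(end) if end else s
            records.append(
                LesionRecord(gene=gene, kind=_INDEL[code], bearer=bearer,
                             exon_start=exon, exon_end=exon, start=s, end=e)
            )
        elif handler == "splice":
            records.append(
                LesionRecord(gene=gene, kind=_SPLICE_KIND[m.group(2)], bearer=bearer,
                             intron=int(m.group(1)), bases=m.group(3))
            )
    return records


def _format_entry(rec: LesionRecord) -> str:
    k = rec.kind
    if k is LesionClass.GENE_DELETION:
        body = f"WGD ({rec.evidence or 'NBR/NRM'})"
    elif k is LesionClass.EXON_DELETION:
        span = f"E{rec.exon_start}" + (
            f"-{rec.exon_end}" if rec.exon_end and rec.exon_end != rec.exon_start else ""
        )
        body = f"{span}: {rec.evidence or 'NBR/NRM'}"
        if rec.note:
            body += f" ({rec.note})"
    elif k is LesionClass.START_CODON:
        body = f"E{rec.exon_start}: SCM"
    elif k in (LesionClass.SPLICE_DONOR, LesionClass.SPLICE_ACCEPTOR):
        body = f"In{rec.intron}{k.value}: {rec.bases}"
    else:
        coord = str(rec.start) if rec.end in (None, rec.start) else f"{rec.start}-{rec.end}"
        body = f"E{rec.exon_start}: {coord}{k.value}"
    if rec.allelic:
        body += " (allelic variation)"
    return body


def format_lesion_notation(records: list[LesionRecord]) -> str:
    """Canonical catalog text for a record list (inverse of the parser).

    Consecutive exon-deletion events of the same gene and evidence tag are
    re-merged into one multi-span entry ("E1-3, 11: NBR/NRM").
    """
    if not records:
        return ""
    sections: list[tuple[str, list[str]]] = []
    i = 0
    while i < len(records):
        rec = records[i]
        # fold runs of exon deletions sharing gene/evidence/note into one entry
        if rec.kind is LesionClass.EXON_DELETION:
            run = [rec]
            while (
                i + 1 < len(records)
                and records[i + 1].kind is LesionClass.EXON_DELETION
                and records[i + 1].gene == rec.gene
                and records[i + 1].evidence == rec.evidence
                and records[i + 1].note == rec.note
                and not records[i + 1].allelic
                and not rec.allelic
            ):
                i += 1
                run.append(records[i])
            spans = []
            for r in run:
                spans.append(
                    f"{r.exon_start}" + (
                        f"-{r.exon_end}" if r.exon_end and r.exon_end != r.exon_start else ""
                    )
                )
            body = f"E{', '.join(spans)}: {rec.evidence or 'NBR/NRM'}"
            if rec.note:
                body += f" ({rec.note})"
            entry = body
        else:
            entry = _format_entry(rec)
        if sections and sections[-1][0] == rec.gene:
            sections[-1][1].append(entry)
        else:
            sections.append((rec.gene, [entry]))
        i += 1
    return "; ".join(f"*{gene}*: " + "; ".join(entries) for gene, entries in sections)
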