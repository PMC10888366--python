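"""Domain types shared by all analysis stages.

Coordinate conventions
----------------------
Gene alignments are column matrices holding the aligned coding sequence
(CDS) of every sampled taxon, with the two splice-relevant dinucleotides
of each intron interleaved between consecutive exons:

    exon1 | donor1(2) acceptor1(2) | exon2 | donor2(2) acceptor2(2) | ...

Alignment columns are 1-based inclusive.  CDS coordinates are 1-based
ranks among *exon* columns only (intron windows excluded), which is the
coordinate system used by the lesion-notation catalog (e.g. "E8:
3751-3752D" points at CDS alignment positions 3751-3752 inside exon 8).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LesionClass",
    "LesionRecord",
    "GeneModel",
    "GeneAlignment",
    "EnamelScoreTable",
    "AlleleEvidence",
    "BranchRow",
    "GENE_ORDER",
]

#: Fixed concatenation order for the seven enamel-specific genes.
GENE_ORDER = ("ACP4", "AMBN", "AMELX", "AMTN", "ENAM", "KLK4", "MMP20")

GAP = "-"


class LesionClass(enum.Enum):
    """The six screened classes of gene-inactivating mutations.

    Codes follow the catalog notation: I/D frameshift indels, S premature
    stop, SCM/TCM start/termination-codon mutations, Do/Ac splice-site
    lesions, exon and whole-gene deletions.
    """

    FRAMESHIFT_INSERTION = "I"
    FRAMESHIFT_DELETION = "D"
    PREMATURE_STOP = "S"
    START_CODON = "SCM"
    TERMINATION_CODON = "TCM"
    SPLICE_DONOR = "Do"
    SPLICE_ACCEPTOR = "Ac"
    EXON_DELETION = "XD"
    GENE_DELETION = "WGD"


@dataclass(frozen=True)
class LesionRecord:
    """One inactivating-mutation event.

    ``bearer`` is the display label (a taxon or a clade name); ``taxa``
    lists the individual taxa carrying the lesion when known.  ``weight``
    is 0.5 for allelic (heterozygous) lesions, 0 for flagged non-canonical
    observations that are excluded from counts, and 1 otherwise.
    """

    gene: str
    kind: LesionClass
    bearer: str = ""
    taxa: tuple[str, ...] = ()
    exon_start: int | None = None
    exon_end: int | None = None
    intron: int | None = None
    start: int | None = None
    end: int | None = None
    bases: str | None = None
    evidence: str | None = None
    note: str | None = None
    allelic: bool = False
    noncanonical: bool = False
    validation: str | None = None

    @property
    def weight(self) -> float:
        if self.noncanonical:
            return 0.0
        return 0.5 if self.allelic else 1.0

    @property
    def exon(self) -> int | None:
        return self.exon_start

    def location_key(self) -> tuple:
        """Identity of the lesion irrespective of who carries it."""
        return (
            self.gene,
            self.kind,
            self.exon_start,
            self.exon_end,
            self.intron,
            self.start,
            self.end,
        )

    def with_taxa(self, taxa: Iterable[str], bearer: str | None = None) -> "LesionRecord":
        taxa = tuple(sorted(set(taxa)))
        return replace(self, taxa=taxa, bearer=bearer if bearer is not None else self.bearer)


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron architecture of one gene in alignment space.

    ``exons`` are ``(index, start, end)`` triples in 1-based inclusive
    alignment columns; ``introns`` are ``(index, donor_cols, acceptor_cols)``
    where each window is a pair of alignment columns (first two / last two
    intron bases).  ``start_codon`` and ``stop_codon`` are triples of
    alignment columns.
    """

    gene_name: str
    exons: tuple[tuple[int, int, int], ...]
    introns: tuple[tuple[int, tuple[int, int], tuple[int, int]], ...] = ()
    start_codon: tuple[int, int, int] | None = None
    stop_codon: tuple[int, int, int] | None = None

    def __post_init__(self):
        prev_end = 0
        for idx, (i, s, e) in enumerate(self.exons, start=1):
            if i != idx:
                raise ValueError(f"exon indices must be 1..n in order, got {i} at {idx}")
            if s > e:
                raise ValueError(f"exon {i}: start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"exon {i} overlaps or precedes exon {i - 1}")
            prev_end = e

    @property
    def in_frame(self) -> bool:
        """True when the total exon span is divisible by 3 (intact reference)."""
        return self.cds_length % 3 == 0

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def cds_columns(self) -> list[int]:
        """Alignment columns of the CDS, in exon order."""
        cols: list[int] = []
        for _, s, e in self.exons:
            cols.extend(range(s, e + 1))
        return cols

    def exon_of_column(self, col: int) -> int | None:
        for i, s, e in self.exons:
            if s <= col <= e:
                return i
        return None

    def cds_of_column(self, col: int) -> int:
        """1-based CDS coordinate of an exon alignment column."""
        pos = 0
        for _, s, e in self.exons:
            if col > e:
                pos += e - s + 1
            elif col >= s:
                return pos + (col - s + 1)
            else:
                break
        raise ValueError(f"column {col} is not an exon column of {self.gene_name}")

    def column_of_cds(self, pos: int) -> int:
        if pos < 1 or pos > self.cds_length:
            raise ValueError(f"CDS position {pos} out of range for {self.gene_name}")
        remaining = pos
        for _, s, e in self.exons:
            span = e - s + 1
            if remaining <= span:
                return s + remaining - 1
            remaining -= span
        raise AssertionError("unreachable")

    def exon_of_cds(self, pos: int) -> int:
        return self.exon_of_column(self.column_of_cds(pos))

    @property
    def total_columns(self) -> int:
        last = self.exons[-1][2]
        for _, d, a in self.introns:
            last = max(last, d[1], a[1])
        if self.stop_codon:
            last = max(last, self.stop_codon[2])
        return last

    @classmethod
    def from_exon_lengths(cls, gene_name: str, exon_lengths: Sequence[int]) -> "GeneModel":
        """Build a model with interleaved 4-column intron windows.

        Layout per intron: donor dinucleotide then acceptor dinucleotide
        (the only intron bases the screen inspects).
        """
        if sum(exon_lengths) % 3 != 0:
            raise ValueError("total exon length must be divisible by 3")
        exons = []
        introns = []
        col = 1
        for i, ln in enumerate(exon_lengths, start=1):
            exons.append((i, col, col + ln - 1))
            col += ln
            if i < len(exon_lengths):
                introns.append((i, (col, col + 1), (col + 2, col + 3)))
                col += 4
        start = (exons[0][1], exons[0][1] + 1, exons[0][1] + 2)
        stop = (exons[-1][2] - 2, exons[-1][2] - 1, exons[-1][2])
        return cls(gene_name, tuple(exons), tuple(introns), start, stop)


@dataclass
class GeneAlignment:
    """Taxon-keyed aligned sequences for one gene, plus absent taxa."""

    gene: str
    sequences: dict[str, str]
    absent: tuple[str, ...] = ()

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: aligned sequences have unequal lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, col: int) -> dict[str, str]:
        """1-based alignment column."""
        return {t: s[col - 1] for t, s in self.sequences.items()}


class EnamelScoreTable:
    """Taxon -> ordered enamel-complexity score set (1..5).

    Polymorphic taxa carry two adjacent categories (e.g. ``2/3``); the
    derived value is the arithmetic mean of the set.
    """

    def __init__(self, scores: Mapping[str, Iterable[int]]):
        self._scores: dict[str, frozenset[int]] = {}
        for taxon, states in scores.items():
            sset = frozenset(int(s) for s in states)
            if not sset or not sset <= {1, 2, 3, 4, 5}:
                raise ValueError(f"{taxon}: scores must be within 1..5, got {set(states)}")
            if len(sset) == 2 and max(sset) - min(sset) != 1:
                raise ValueError(f"{taxon}: polymorphic scores must be adjacent, got {set(sset)}")
            if len(sset) > 2:
                raise ValueError(f"{taxon}: at most two categories allowed")
            self._scores[taxon] = sset

    @classmethod
    def from_strings(cls, raw: Mapping[str, str]) -> "EnamelScoreTable":
        parsed = {t: [int(x) for x in str(v).split("/")] for t, v in raw.items()}
        return cls(parsed)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._scores

    def __iter__(self):
        return iter(self._scores)

    def __len__(self):
        return len(self._scores)

    def states(self, taxon: str) -> frozenset[int]:
        return self._scores[taxon]

    def value(self, taxon: str) -> float:
        s = self._scores[taxon]
        return sum(s) / len(s)

    def as_strings(self) -> dict[str, str]:
        return {
            t: "/".join(str(x) for x in sorted(s)) for t, s in self._scores.items()
        }

    def items(self):
        return self._scores.items()


@dataclass(frozen=True)
class AlleleEvidence:
    """Read support for the two alleles at a candidate lesion site."""

    site: str
    counts: Mapping[str, int]
    lesion_allele: str
    ancestral_allele: str

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("allele counts must be non-negative")

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def fraction(self, allele: str) -> float:
        cov = self.coverage
        return self.counts.get(allele, 0) / cov if cov else math.nan


@dataclass
class BranchRow:
    """One row of the merged per-branch table."""

    branch: str
    duration: float = math.nan
    lesion_event_count: int = 0
    lesion_weight_sum: float = 0.0
    mutations_per_myr: float = math.nan
    enamel_branch_score: float = math.nan
    dn: float = math.nan
    ds: float = math.nan
    omega: float = math.nan
    substitution_count: float = math.nan
    retained: bool = False
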