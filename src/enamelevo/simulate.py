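"""Synthetic data with the statistical structure the analysis assumes.

The generator produces everything the pipeline consumes, with exact
truth logs for oracle comparisons:

* codon alignments evolved by Gillespie (event-level) simulation under a
  Goldman-Yang-style rate matrix with branch-specific omega, so true
  per-branch synonymous/nonsynonymous event counts exist;
* gene-inactivating lesions of all six classes injected afterwards as
  edits on the descendants of scheduled branches, so detection and
  selection estimation are testable independently;
* allele read counts for designated heterozygous lesions;
* tip enamel-complexity scores monotonically (decreasingly) coupled to
  the branch omega regime, with categorical noise and occasional
  adjacent-pair polymorphism.

Defaults emulate a small odontocete-like study: a 14-taxon ingroup plus
2 intact outgroup references on a 50-MYR timetree, seven gene partitions
totalling 210 codons, kappa = 4, purifying (omega = 0.05) versus relaxed
(omega = 0.8) branch regimes, and a relaxed clade covering roughly half
the ingroup.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import codon as C
from .model import (
    AlleleEvidence,
    EnamelScoreTable,
    GAP,
    GeneAlignment,
    GeneModel,
    LesionClass,
    LesionRecord,
)
from .timetree import TimeTree

__all__ = [
    "SimulationConfig",
    "simulate_timetree",
    "simulate_codon_alignment",
    "inject_lesions",
    "simulate_allele_evidence",
    "simulate_enamel_scores",
    "simulate_all",
    "SimulationResult",
]

DEFAULT_GENES = ("ACP4", "AMBN", "AMELX", "AMTN", "ENAM", "KLK4", "MMP20")


@dataclass
class SimulationConfig:
    seed: int
    n_ingroup: int = 14
    n_references: int = 2
    root_age: float = 50.0          # MYR
    crown_age: float = 36.0         # MYR, ingroup radiation
    subs_per_codon_per_myr: float = 0.012
    kappa: float = 4.0
    omega_purifying: float = 0.05
    omega_relaxed: float = 0.8
    relaxed_fraction: float = 0.5   # share of ingroup tips in the relaxed clade
    gene_codons: tuple[int, ...] = (30, 30, 30, 30, 30, 30, 30)
    genes: tuple[str, ...] = DEFAULT_GENES
    exons_per_gene: int = 3
    lesions_per_relaxed_tip: float = 1.5
    het_fraction: float = 0.25
    mean_coverage: float = 30.0
    score_noise: float = 0.15       # P(shift score by +-1)
    polymorphic_prob: float = 0.10
    gc_bias: float = 0.55           # simple compositional skew

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.gene_codons) != len(self.genes):
            raise ValueError("gene_codons must match genes")


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: TimeTree
    regimes: dict[str, str]                     # branch -> "purifying"|"relaxed"
    omegas: dict[str, float]
    alignments: dict[str, GeneAlignment]
    models: dict[str, GeneModel]
    references: tuple[str, ...]
    injection_log: list[LesionRecord]
    evidence_flags: dict[str, dict[str, str]]   # gene -> taxon -> tag
    allele_evidence: dict[str, AlleleEvidence]  # site -> evidence
    enamel: EnamelScoreTable
    true_events: dict[str, tuple[int, int]]     # branch -> (syn, nonsyn)
    tip_sequences: dict[str, np.ndarray]


def simulate_timetree(config: SimulationConfig, rng: np.random.Generator) -> TimeTree:
    """Yule ingroup topology with node ages; outgroups attach at the root."""
    n = config.n_ingroup
    names = [f"T{i + 1:02d}" for i in range(n)]
    # Yule coalescent-style: start with tips, join random pairs at
    # increasing ages drawn uniformly then sorted and scaled to crown age
    ages = np.sort(rng.uniform(0.05, 1.0, size=n - 1)) * config.crown_age
    nodes = [(name, 0.0) for name in names]  # (newick, age)
    for a in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (si, ai), (sj, aj) = nodes[i], nodes[j]
        merged = (f"({si}:{a - ai:.9f},{sj}:{a - aj:.9f})", float(a))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    crown, crown_age = nodes[0]
    stem = config.root_age - crown_age
    refs = [f"REF{i + 1}" for i in range(config.n_references)]
    if len(refs) == 1:
        out = f"{refs[0]}:{config.root_age:.9f}"
    else:
        split = config.root_age * 0.6
        tips = ",".join(f"{r}:{split:.9f}" for r in refs)
        # pectinate references under one clade
        out = f"({refs[0]}:{split:.9f},{refs[1]}:{split:.9f}):{config.root_age - split:.9f}"
    newick = f"({out},{crown}:{stem:.9f});"
    return TimeTree.from_newick(newick)


def assign_regimes(tree: TimeTree, config: SimulationConfig,
                   rng: np.random.Generator) -> dict[str, str]:
    """Mark one ingroup clade (about ``relaxed_fraction`` of ingroup tips)
    and all branches inside it, including its stem, as relaxed."""
    ingroup = [t for t in tree.taxa if not t.startswith("REF")]
    target = max(2, int(round(config.relaxed_fraction * len(ingroup))))
    best, best_diff = None, None
    for branch in tree.branches():
        leaves = tree.leaf_set(branch)
        if any(t.startswith("REF") for t in leaves):
            continue
        if len(leaves) == len(ingroup):
            continue
        diff = abs(len(leaves) - target)
        if best is None or diff < best_diff:
            best, best_diff = branch, diff
    relaxed_root = best
    relaxed_leaves = tree.leaf_set(relaxed_root)
    regimes = {}
    for branch in tree.branches():
        inside = tree.leaf_set(branch) <= relaxed_leaves
        regimes[branch] = "relaxed" if inside else "purifying"
    return regimes


def _stationary_pi(config: SimulationConfig) -> np.ndarray:
    g = config.gc_bias / 2
    a = (1 - config.gc_bias) / 2
    fnt = np.array([a, g, g, a])  # A C G T
    at = np.array([[C.NT.index(c[p]) for p in range(3)] for c in C.SENSE_CODONS])
    pi = fnt[at[:, 0]] * fnt[at[:, 1]] * fnt[at[:, 2]]
    return pi / pi.sum()


def simulate_codon_alignment(config: SimulationConfig,
                             tree: TimeTree | None = None,
                             regimes: dict[str, str] | None = None,
                             rng: np.random.Generator | None = None):
    """Evolve codon sequences along the tree (Gillespie, per branch).

    Returns (tip codon matrices by taxon, per-branch true (syn, nonsyn)
    event counts, tree, regimes, node sequences).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tree = tree if tree is not None else simulate_timetree(config, rng)
    regimes = regimes if regimes is not None else assign_regimes(tree, config, rng)
    omega_of = {
        "purifying": config.omega_purifying,
        "relaxed": config.omega_relaxed,
    }
    pi = _stationary_pi(config)
    qs = {
        regime: C.rate_matrix(config.kappa, w, pi)
        for regime, w in omega_of.items()
    }
    syn_pair = np.zeros((61, 61), dtype=bool)
    for i, ci in enumerate(C.SENSE_CODONS):
        for j, cj in enumerate(C.SENSE_CODONS):
            syn_pair[i, j] = C.AMINO_ACID[ci] == C.AMINO_ACID[cj]

    L = sum(config.gene_codons)
    root_seq = rng.choice(61, size=L, p=pi)
    node_seq: dict[str, np.ndarray] = {tree.label(tree.root): root_seq}
    true_events: dict[str, tuple[int, int]] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.root:
            continue
        branch = tree.label(node)
        parent = tree.label(node.parent_node)
        seq = node_seq[parent].copy()
        q = qs[regimes[branch]]
        t_total = tree.duration(branch) * config.subs_per_codon_per_myr
        syn = nonsyn = 0
        elapsed = 0.0
        rates = -q[seq, seq]  # exit rate per site
        total = rates.sum()
        while total > 0:
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t_total:
                break
            site = rng.choice(L, p=rates / total)
            row = q[seq[site]].copy()
            row[seq[site]] = 0.0
            new = rng.choice(61, p=row / row.sum())
            if syn_pair[seq[site], new]:
                syn += 1
            else:
                nonsyn += 1
            seq[site] = new
            total -= rates[site]
            rates[site] = -q[new, new]
            total += rates[site]
        node_seq[branch] = seq
        true_events[branch] = (syn, nonsyn)
    tips = {t: node_seq[t] for t in tree.taxa}
    return tips, true_events, tree, regimes, node_seq


def _build_gene_structures(config: SimulationConfig, tips: dict[str, np.ndarray]
                           ) -> tuple[dict[str, GeneAlignment], dict[str, GeneModel]]:
    """Slice the codon matrix into genes and add canonical splice windows."""
    alignments, models = {}, {}
    offset = 0
    for gene, n_cod in zip(config.genes, config.gene_codons):
        n_nt = n_cod * 3
        k = config.exons_per_gene
        # exon lengths: near-equal thirds, multiple-of-1 columns
        cuts = [round(n_nt * i / k) for i in range(k + 1)]
        exon_lengths = [cuts[i + 1] - cuts[i] for i in range(k)]
        model = GeneModel.from_exon_lengths(gene, exon_lengths)
        seqs = {}
        for taxon, codons in tips.items():
            nt = "".join(C.SENSE_CODONS[c] for c in codons[offset:offset + n_cod])
            parts = []
            pos = 0
            for i, ln in enumerate(exon_lengths):
                parts.append(nt[pos:pos + ln])
                pos += ln
                if i < k - 1:
                    parts.append("GTAG")  # canonical donor + acceptor
            seqs[taxon] = "".join(parts)
        # make the annotated start/stop codons real
        for taxon in seqs:
            s = list(seqs[taxon])
            sc, ec = model.start_codon, model.stop_codon
            s[sc[0] - 1:sc[2]] = "ATG"
            s[ec[0] - 1:ec[2]] = "TAA"
            seqs[taxon] = "".join(s)
        alignments[gene] = GeneAlignment(gene=gene, sequences=seqs)
        models[gene] = model
        offset += n_cod
    return alignments, models


def default_schedule(tree: TimeTree, regimes: dict[str, str],
                     config: SimulationConfig, rng: np.random.Generator
                     ) -> list[dict]:
    """A lesion schedule touching all six classes on relaxed branches."""
    relaxed = [b for b, r in regimes.items() if r == "relaxed"]
    classes = ["frameshift_deletion", "frameshift_insertion", "premature_stop",
               "splice_donor", "splice_acceptor", "start_codon",
               "termination_codon", "exon_deletion", "gene_deletion"]
    n_tips_relaxed = sum(1 for b in relaxed if b in tree.taxa)
    n_lesions = max(len(classes), int(round(config.lesions_per_relaxed_tip
                                            * n_tips_relaxed)))
    schedule = []
    genes = list(config.genes)
    for i in range(n_lesions):
        cls = classes[i] if i < len(classes) else str(rng.choice(classes))
        branch = str(rng.choice(relaxed))
        gene = genes[int(rng.integers(len(genes)))]
        schedule.append({"branch": branch, "gene": gene, "class": cls})
    return schedule


_KIND = {
    "frameshift_deletion": LesionClass.FRAMESHIFT_DELETION,
    "frameshift_insertion": LesionClass.FRAMESHIFT_INSERTION,
    "premature_stop": LesionClass.PREMATURE_STOP,
    "splice_donor": LesionClass.SPLICE_DONOR,
    "splice_acceptor": LesionClass.SPLICE_ACCEPTOR,
    "start_codon": LesionClass.START_CODON,
    "termination_codon": LesionClass.TERMINATION_CODON,
    "exon_deletion": LesionClass.EXON_DELETION,
    "gene_deletion": LesionClass.GENE_DELETION,
}


def inject_lesions(alignments: dict[str, GeneAlignment],
                   models: dict[str, GeneModel],
                   tree: TimeTree, schedule: list[dict],
                   references: tuple[str, ...],
                   rng: np.random.Generator):
    """Apply scheduled lesions to all descendants of each branch.

    Returns (alignments, models, injection log, evidence flags).  The
    log records the expected detector output: class, location in the
    final alignment's CDS coordinates, and the bearer taxa.  Placements
    that would collide with an earlier edit (and so change what the
    detector reports) are skipped; whole-exon and whole-gene deletions
    emit evidence flags.  Once a gene carries a whole-gene deletion no
    further lesion is scheduled in it.
    """
    seqs_by_gene = {g: dict(a.sequences) for g, a in alignments.items()}
    absent_by_gene = {g: set(a.absent) for g, a in alignments.items()}
    models = dict(models)
    flags: dict[str, dict[str, str]] = {g: {} for g in alignments}
    used_cols: set[tuple[str, int]] = set()   # (gene, column) touched by edits
    used_keys: set[tuple] = set()
    wgd_genes: set[str] = set()
    ins_cols: dict[str, set[int]] = {g: set() for g in alignments}  # inserted columns
    pending: list[dict] = []  # records with column coordinates, finalized later

    def cols_free(gene, c_lo, c_hi):
        return not any((gene, c) in used_cols for c in range(c_lo, c_hi + 1))

    def reserve(gene, c_lo, c_hi):
        for c in range(c_lo, c_hi + 1):
            used_cols.add((gene, c))

    for entry in schedule:
        gene = entry["gene"]
        kind = _KIND[entry["class"]]
        branch = entry["branch"]
        bearers = tuple(sorted(tree.leaf_set(branch)))
        if set(bearers) & set(references):
            raise ValueError(f"schedule targets a reference taxon via branch {branch}")
        if gene in wgd_genes:
            continue
        model = models[gene]
        seqs = seqs_by_gene[gene]
        bearers_here = tuple(t for t in bearers if t in seqs)
        if not bearers_here:
            continue
        rec = {"gene": gene, "kind": kind, "taxa": bearers_here}

        if kind is LesionClass.GENE_DELETION:
            if any((gene, c) in used_cols for c in range(1, model.total_columns + 1)):
                continue  # keep earlier point lesions observable
            for t in bearers_here:
                del seqs[t]
                flags[gene][t] = "NRM"
            absent_by_gene[gene] |= set(bearers_here)
            wgd_genes.add(gene)
            rec["evidence"] = "NRM"
        elif kind is LesionClass.EXON_DELETION:
            exon = int(rng.integers(1, model.n_exons + 1))
            _, s, e = model.exons[exon - 1]
            if ("xd", gene, exon) in used_keys or not cols_free(gene, s, e):
                continue
            used_keys.add(("xd", gene, exon))
            reserve(gene, s, e)
            for t in bearers_here:
                sq = list(seqs[t])
                for c in range(s, e + 1):
                    sq[c - 1] = GAP
                seqs[t] = "".join(sq)
                flags[gene][t] = "NRM"
            rec.update(exon_start=exon, exon_end=exon, evidence="NRM")
        elif kind in (LesionClass.SPLICE_DONOR, LesionClass.SPLICE_ACCEPTOR):
            if not model.introns:
                continue
            intron = int(rng.integers(1, len(model.introns) + 1))
            key = ("sp", gene, intron, kind.value)
            if key in used_keys:
                continue
            used_keys.add(key)
            _, donor, acceptor = model.introns[intron - 1]
            cols = donor if kind is LesionClass.SPLICE_DONOR else acceptor
            reserve(gene, cols[0], cols[1])
            bases = "AT" if kind is LesionClass.SPLICE_DONOR else "GG"
            for t in bearers_here:
                sq = list(seqs[t])
                sq[cols[0] - 1], sq[cols[1] - 1] = bases[0], bases[1]
                seqs[t] = "".join(sq)
            rec.update(intron=intron, bases=bases)
        elif kind is LesionClass.START_CODON:
            if ("scm", gene) in used_keys or model.start_codon is None:
                continue
            sc = model.start_codon
            if not cols_free(gene, sc[0], sc[2]):
                continue
            used_keys.add(("scm", gene))
            reserve(gene, sc[0], sc[2])
            for t in bearers_here:
                sq = list(seqs[t])
                sq[sc[0] - 1] = "G"  # ATG -> GTG
                seqs[t] = "".join(sq)
            rec.update(exon_start=model.exon_of_column(sc[0]),
                       exon_end=model.exon_of_column(sc[0]))
        elif kind is LesionClass.TERMINATION_CODON:
            if ("tcm", gene) in used_keys or model.stop_codon is None:
                continue
            ec = model.stop_codon
            if not cols_free(gene, ec[0], ec[2]):
                continue
            used_keys.add(("tcm", gene))
            reserve(gene, ec[0], ec[2])
            for t in bearers_here:
                sq = list(seqs[t])
                sq[ec[0] - 1:ec[2]] = "CAA"
                seqs[t] = "".join(sq)
            rec.update(exon_start=model.exon_of_column(ec[0]),
                       exon_end=model.exon_of_column(ec[0]),
                       col_start=ec[0], col_end=ec[2])
        elif kind is LesionClass.PREMATURE_STOP:
            # a stop must sit on a reference-frame codon: triplets of
            # exon columns with injected insertion columns excluded
            ref_cols = [c for c in model.cds_columns() if c not in ins_cols[gene]]
            n_codons = len(ref_cols) // 3
            cols = None
            for _ in range(60):
                ci = int(rng.integers(2, n_codons - 1))
                cand = ref_cols[3 * ci: 3 * ci + 3]
                if all(cols_free(gene, c, c) for c in cand):
                    cols = cand
                    break
            if cols is None:
                continue
            for c in cols:
                reserve(gene, c, c)
            for t in bearers_here:
                sq = list(seqs[t])
                sq[cols[0] - 1], sq[cols[1] - 1], sq[cols[2] - 1] = "T", "A", "G"
                seqs[t] = "".join(sq)
            rec.update(exon_start=model.exon_of_column(cols[0]),
                       exon_end=model.exon_of_column(cols[0]),
                       col_start=cols[0], col_end=cols[2])
        else:  # frameshift indel
            length = int(rng.choice([1, 2, 4, 5]))
            exon = int(rng.integers(1, model.n_exons + 1))
            _, s, e = model.exons[exon - 1]
            if e - s + 1 < length + 10:
                continue
            c0 = None
            for _ in range(60):
                cand = int(rng.integers(s + 4, e - length - 3))
                # 1-column margin so adjacent runs cannot fuse
                if cols_free(gene, cand - 1, cand + length):
                    c0 = cand
                    break
            if c0 is None:
                continue
            reserve(gene, c0 - 1, c0 + length)
            if kind is LesionClass.FRAMESHIFT_DELETION:
                for t in bearers_here:
                    sq = list(seqs[t])
                    for c in range(c0, c0 + length):
                        sq[c - 1] = GAP
                    seqs[t] = "".join(sq)
                rec.update(exon_start=exon, exon_end=exon,
                           col_start=c0, col_end=c0 + length - 1)
            else:
                # insert new columns after c0: bearers get bases, others gaps
                bases = "".join(str(b) for b in rng.choice(list("ACGT"), size=length))
                for t in list(seqs):
                    fill = bases if t in bearers_here else GAP * length
                    seqs[t] = seqs[t][:c0] + fill + seqs[t][c0:]
                models[gene] = model = _shift_model(model, c0, length)
                shifted = set()
                for g, c in used_cols:
                    shifted.add((g, c + length) if g == gene and c > c0 else (g, c))
                used_cols.clear()
                used_cols.update(shifted)
                ins_cols[gene] = {c + length if c > c0 else c for c in ins_cols[gene]}
                ins_cols[gene].update(range(c0 + 1, c0 + length + 1))
                reserve(gene, c0 + 1, c0 + length)
                for p in pending:
                    if p["gene"] == gene:
                        for k in ("col_start", "col_end"):
                            if k in p and p[k] > c0:
                                p[k] += length
                rec.update(exon_start=exon, exon_end=exon,
                           col_start=c0 + 1, col_end=c0 + length)
        pending.append(rec)

    log: list[LesionRecord] = []
    for p in pending:
        gene = p["gene"]
        model = models[gene]
        start = end = None
        if "col_start" in p:
            start = model.cds_of_column(p["col_start"])
            end = model.cds_of_column(p["col_end"])
        taxa = p["taxa"]
        log.append(LesionRecord(
            gene=gene, kind=p["kind"], bearer="+".join(taxa) if len(taxa) > 1 else taxa[0],
            taxa=taxa, exon_start=p.get("exon_start"), exon_end=p.get("exon_end"),
            intron=p.get("intron"), start=start, end=end,
            bases=p.get("bases"), evidence=p.get("evidence"),
        ))
    out_aln = {
        g: GeneAlignment(g, seqs_by_gene[g], tuple(sorted(absent_by_gene[g])))
        for g in alignments
    }
    return out_aln, models, log, flags


def _shift_model(model: GeneModel, after_col: int, length: int) -> GeneModel:
    """Rebuild a gene model after inserting ``length`` columns after
    ``after_col`` (the insertion lands inside an exon)."""

    def sh(c):
        return c + length if c > after_col else c

    exons = []
    for i, s, e in model.exons:
        if s <= after_col < e:
            exons.append((i, s, e + length))
        else:
            exons.append((i, sh(s), sh(e)))
    introns = tuple(
        (i, (sh(d[0]), sh(d[1])), (sh(a[0]), sh(a[1])))
        for i, d, a in model.introns
    )
    start = tuple(sh(c) for c in model.start_codon) if model.start_codon else None
    stop = tuple(sh(c) for c in model.stop_codon) if model.stop_codon else None
    return GeneModel(model.gene_name, tuple(exons), introns, start, stop)


def simulate_allele_evidence(log: list[LesionRecord], het_fraction: float,
                             mean_coverage: float, rng: np.random.Generator
                             ) -> tuple[list[LesionRecord], dict[str, AlleleEvidence]]:
    """Draw read support per lesion; a ``het_fraction`` of lesions are
    heterozygous with mean allele balance 0.5 (both alleles guaranteed to
    satisfy the 40% rule so the weighting is decidable)."""
    from .scan import evidence_site

    if not 0 <= het_fraction <= 1:
        raise ValueError("het fraction must be in [0, 1]")
    evidence: dict[str, AlleleEvidence] = {}
    updated = []
    for rec in log:
        if rec.kind in (LesionClass.GENE_DELETION, LesionClass.EXON_DELETION):
            updated.append(rec)
            continue
        if rec.kind is LesionClass.SPLICE_DONOR:
            lesion_allele, ancestral_allele = rec.bases, "GT"
        elif rec.kind is LesionClass.SPLICE_ACCEPTOR:
            lesion_allele, ancestral_allele = rec.bases, "AG"
        else:
            lesion_allele, ancestral_allele = "alt", "ref"
        cov = max(10, int(rng.poisson(mean_coverage)))
        site = evidence_site(rec)
        if rng.random() < het_fraction:
            lo = math.ceil(0.4 * cov)
            k = int(rng.binomial(cov, 0.5))
            k = min(max(k, lo), cov - lo)
            counts = {lesion_allele: k, ancestral_allele: cov - k}
            new_bases = (f"{lesion_allele}/{ancestral_allele}"
                         if rec.intron is not None else rec.bases)
            rec = dataclasses.replace(rec, allelic=True, bases=new_bases)
        else:
            counts = {lesion_allele: cov, ancestral_allele: 0}
        evidence[site] = AlleleEvidence(site=site, counts=counts,
                                        lesion_allele=lesion_allele,
                                        ancestral_allele=ancestral_allele)
        updated.append(rec)
    return updated, evidence


def simulate_enamel_scores(tree: TimeTree, regimes: dict[str, str],
                           config: SimulationConfig, rng: np.random.Generator
                           ) -> EnamelScoreTable:
    """Tip scores via a monotone decreasing omega -> score link.

    Purifying tips center on category 5, relaxed tips on category 2;
    noise shifts a tip by one category with probability ``score_noise``
    and adjacent-pair polymorphism occurs with ``polymorphic_prob``.
    """
    link = {"purifying": 5, "relaxed": 2}
    scores: dict[str, list[int]] = {}
    for taxon in tree.taxa:
        base = link[regimes[taxon]]
        if rng.random() < config.score_noise:
            base += int(rng.choice([-1, 1]))
        base = int(np.clip(base, 1, 5))
        if rng.random() < config.polymorphic_prob:
            other = base + 1 if base < 5 else base - 1
            scores[taxon] = sorted({base, other})
        else:
            scores[taxon] = [base]
    return EnamelScoreTable(scores)


def simulate_all(config: SimulationConfig,
                 schedule: list[dict] | None = None) -> SimulationResult:
    """Run the full generator: tree, sequences, lesions, evidence, scores."""
    rng = np.random.default_rng(config.seed)
    tips, true_events, tree, regimes, node_seq = simulate_codon_alignment(config, rng=rng)
    alignments, models = _build_gene_structures(config, tips)
    references = tuple(t for t in tree.taxa if t.startswith("REF"))
    if schedule is None:
        schedule = default_schedule(tree, regimes, config, rng)
    alignments, models, log, flags = inject_lesions(
        alignments, models, tree, schedule, references, rng
    )
    log, allele_ev = simulate_allele_evidence(
        log, config.het_fraction, config.mean_coverage, rng
    )
    enamel = simulate_enamel_scores(tree, regimes, config, rng)
    omegas = {
        b: (config.omega_relaxed if regimes[b] == "relaxed" else config.omega_purifying)
        for b in tree.branches()
    }
    return SimulationResult(
        config=config, tree=tree, regimes=regimes, omegas=omegas,
        alignments=alignments, models=models, references=references,
        injection_log=log, evidence_flags=flags, allele_evidence=allele_ev,
        enamel=enamel, true_events=true_events, tip_sequences=tips,
    )
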