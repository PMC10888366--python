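# enamelevo

Toothed whales (Odontoceti) span the full range of enamel phenotypes,
from thick prismatic enamel with Hunter-Schreger bands in river dolphins
to prismless or absent enamel in sperm whales, beaked whales, porpoises,
and the narwhal. When enamel stops mattering to feeding, the genes that
build it — *ACP4*, *AMBN*, *AMELX*, *AMTN*, *ENAM*, *KLK4*, *MMP20* —
decay: frameshift indels, premature stop codons, splice-site mutations,
start/stop-codon mutations, and exon or whole-gene deletions accumulate.

`enamelevo` is a Python library for quantifying that decay and relating
it to phenotype. It is written for molecular evolutionists who have
per-gene coding alignments, a timetree, and ordinal phenotype scores,
and who want branch-level measures of relaxed selection:

1. **Lesion scanning** — detect and classify the six classes of
   gene-inactivating mutations in annotated coding alignments relative
   to intact reference taxa, merge lesions shared across species, and
   down-weight heterozygous lesions to 0.5 when read evidence shows both
   alleles at ≥ 40% of reads with ≥ 10× coverage.
2. **Parsimony mapping** — place each lesion's origin on the species
   tree (ACCTRAN or DELTRAN, treating inactivation as irreversible),
   classify origins as synapomorphic or autapomorphic, and convert
   per-branch weighted lesion counts into mutations per million years.
3. **Ordered ancestral reconstruction** — Sankoff dynamic programming
   for the Werth enamel-complexity score (1 = no enamel … 5 = prismatic
   enamel with Hunter-Schreger bands) as an ordered (Wagner) character
   with cost |i − j|, full MPR state sets, and branch scores equal to
   the mean of the branch's endpoint values.
4. **Selection analysis** — per-branch dN/dS (ω) on the concatenated
   genes under a free-ratio Goldman–Yang-style codon model
   (`q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]`, CF1/CF2 codon
   frequencies, premature stops recoded to missing, frameshift
   insertions stripped), fitted by Felsenstein pruning with bounded
   coordinate ascent; a modified Nei–Gojobori counting estimator over
   reconstructed ancestral codons serves as a fast cross-check.
5. **Branch statistics** — Spearman rank correlation (tied ranks,
   two-tailed t approximation), OLS regression with an optional
   log-transformed predictor, and Anderson–Darling residual-normality
   tests, all at the branch level after dropping branches with fewer
   than five substitutions.
6. **Synthetic data** — a seeded generator that evolves codon sequences
   by event-level (Gillespie) simulation under branch-specific ω,
   injects lesions of all six classes with an exact truth log, draws
   allele read counts, and couples tip enamel scores to the selection
   regime, so every stage of the pipeline is testable end to end.

The package ships machine-readable reference tables: the lesion catalog
for 63 odontocetes in compact notation (e.g. `*ENAM*: E8: 3751-3752D`),
the taxon/family table, enamel-complexity scores for 37 taxa, and
93- and 37-taxon species trees (family-level topology; placeholder
ultrametric ages, since the counting analyses need topology only).

## Worked example

Tallies of the shipped lesion catalog (`python examples/01_lesion_catalog.py`):

```
total inactivating-mutation events : 48
weighted total (allelic = 0.5)     : 44.5
events in high-enamel families     : 2
events in low-enamel families      : 46 (11 synapomorphic, 35 autapomorphic)
beaked whales with >= 1 lesion     : 12 of 19
```

48 lesion events map onto the tree; only two fall in the oceanic/river
dolphin families with prismatic enamel (a heterozygous *ENAM* splice
mutation in the killer whale and an in-frame *AMTN* exon-3 deletion in
*Platanista*), while 46 fall in the five families with degenerate
enamel, eleven of them shared by whole clades such as Kogiidae or
Monodontidae — gene decay concentrates exactly where enamel is simplest.

An end-to-end synthetic run (`python examples/05_correlation_pipeline.py`):

```
lesion rate vs enamel score:
  Spearman rho = -0.591  (p = 5.91e-04)
dN/dS vs enamel score (24 branches with >= 5 substitutions):
  Spearman rho = -0.854  (p = 1.10e-07)
  OLS slope    = -3.014  r2 = 0.76
```

Both molecular measures of relaxed selection correlate negatively with
branch enamel complexity, recovering the coupling planted by the
generator.

The same stages are scriptable from a shell:

```sh
enamelevo synth --seed 5 --out run1
enamelevo scan run1
enamelevo map run1 --method deltran
enamelevo selection run1 --estimator ml --freq-model cf1
enamelevo stats run1
```

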