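# Methods

This note documents the models and conventions implemented in
`enamelevo`, the defaults of the synthetic-data generator, and the
numerical choices that matter when reproducing or extending an analysis.

## Lesion detection

All detectors compare query taxa against a designated set of intact
**reference taxa** (by default the non-cetacean outgroups, whose enamel
genes are under purifying selection). The ancestral reading frame is
defined by the alignment columns in which at least one reference is
ungapped; columns gapped in *all* references are insertions relative to
the ancestral gene. A column gapped in some but not all references
violates the intact-reference precondition and is an error rather than
a call.

- **Frameshift indels.** Within each exon, a maximal run of query gaps
  over reference columns (deletion) or of query bases over insertion
  columns (insertion) is one event if its length is not a multiple of
  three. In-frame indels are not lesions. A run spanning a whole exon is
  left to the deletion detector. Compound indels are reported run by
  run even when two nearby events jointly restore the frame — the
  catalog convention is one row per physical event.
- **Premature stops.** Codons are read in the reference frame
  (insertion columns skipped), so the scan runs on the alignment
  *before* any frameshift stripping and stops downstream of a
  frameshift are still reported. Codons containing gaps are skipped;
  the annotated terminal stop is excluded.
- **Splice sites.** The first two bases of an intron must be `GT` and
  the last two `AG`. Any other dinucleotide is a lesion, except a `GC`
  donor, which is returned flagged as non-canonical (weight 0, excluded
  from counts) because GC–AG introns can still be spliced. Windows with
  gaps are indeterminate, not lesions.
- **Start/termination codons.** Non-`ATG` start and non-stop
  termination codons are lesions; gapped codons are indeterminate.
- **Exon and gene deletions.** Absence alone is missing data. Only an
  explicit per-taxon evidence flag (`NBR` no BLAST results, `NRM` no
  reads mapped) turns a fully absent exon span or gene into a deletion
  event; each contiguous absent exon span is one event, and in-frame
  whole-exon deletions still count.
- **Heterozygosity.** A lesion with read evidence is down-weighted to
  0.5 when coverage is at least 10× and both the lesion and ancestral
  alleles each hold at least 40% of reads; with a clear lesion-allele
  majority it keeps weight 1; below 10× it is reported unverified with
  its weight unchanged.

Lesions with identical gene, class, and location (exact column match)
across taxa are merged into one shared event whose bearers are the
taxon set; a named clade label is attached when the set matches the
clade table exactly.

## Parsimony on the tree

**Lesion characters are irreversible.** An inactivated gene is assumed
unable to regain function, so an origin may only sit on a branch whose
subtree contains no taxon observed intact. Within each maximal
absent-free subtree containing bearers, DELTRAN places the origin on
the bearers' stem (delayed, tipward) and ACCTRAN on the subtree's
topmost branch (accelerated, rootward); both imply the same number of
origins. Taxa without data are wildcards. Origins are never placed on
the root branch; if a clean subtree reaches the root, the origin is
pushed into the root's children that contain bearers. An origin is
synapomorphic when its branch subtends two or more sampled bearers.
When the catalog is mapped, non-bearer sampled taxa are marked absent
(they were screened and found intact), which is why ACCTRAN and DELTRAN
give identical mappings for the shipped catalog.

**Enamel complexity is an ordered character** on states 1–5 with linear
(Wagner) cost |i − j|, solved exactly by Sankoff dynamic programming
(cost vectors down, outside vectors up), which handles polytomies and
polymorphic tips. MPR state sets are exact; an equivocal node is valued
at the mean of its MPR set (the set is a contiguous interval for an
ordered character), and a scored polymorphic tip keeps its observed
pair and is valued at its mean (so a `2/3` tip contributes 2.5). The
unique ACCTRAN/DELTRAN resolutions are produced top-down: at each node
the state is chosen from the set of conditionally optimal states given
the parent's resolved state — DELTRAN takes the state closest to the
parent (delaying change), ACCTRAN the farthest (accelerating it);
remaining ties resolve to the higher state, reflecting ancestrally
complex enamel. Each branch's score is the mean of its two endpoint
values: 3 → 3 = 3, 4 → 2 = 3, 1 → 1/2 = 1.25.

**Mutations/MYR** divides the summed lesion weights on a branch by the
branch duration in millions of years; lesion-free branches score 0.

## Codon model and dN/dS

The substitution model is Goldman–Yang-style on the 61 sense codons:
single-nucleotide changes only, `q_ij = π_j · κ^[ts] · ω^[nonsyn]`, with
per-branch rate matrices normalized to one expected substitution per
codon per unit branch length. Codon frequencies come from the data —
CF1 pools nucleotide frequencies across codon positions, CF2 keeps them
position-specific — with stop codons excluded and the vector
renormalized. Before fitting, intron windows are dropped, columns
gapped in all references (frameshift insertions) are deleted, terminal
stop codons are removed, every remaining stop codon becomes missing
data, and the genes are concatenated in a fixed order
(ACP4, AMBN, AMELX, AMTN, ENAM, KLK4, MMP20), padding taxa that lack a
gene with missing codons. Missing/ambiguous codons enter the pruning
recursion as indicator partials over all compatible states.

**Free-ratio fit.** The tree is evaluated unrooted (a bifurcating root
has its two incident edges merged; the merged branch is reported under
the deeper root child's label). κ starts at a pairwise
transition/transversion counting estimate and is refined by scalar ML
updates between sweeps; branch lengths and per-branch ω alternate
branch-by-branch with bounded scalar optimization (t ∈ [1e-7, 25],
ω ∈ [1e-4, 999], the clamp marking inexact extremes). Partial-likelihood
caches are refreshed once per sweep, so each sweep is a Gauss–Seidel
pass against slightly stale partials; the sweep-end likelihood check
keeps the ascent honest and the best iterate is returned. Convergence
is declared when a sweep improves the log-likelihood by less than 1e-6,
with a 200-sweep cap. The single deterministic start (ω = 0.2
everywhere; branch lengths from a Jukes–Cantor-corrected mean pairwise
distance spread over the expected path length) makes fits reproducible;
like any coordinate ascent this finds a local optimum and is not
guaranteed to replicate other implementations' optima to the last
digit — the counting estimator provides an independent consistency
check. Per branch, dN and dS follow the flux decomposition of the
normalized rate matrix (so dN/dS equals the branch's ω exactly) and the
substitution count is `N·dN + S·dS = L·t`. A branch is flagged inexact
when its expected synonymous or nonsynonymous substitutions fall below
0.5 or its ω sits at a clamp bound; branches with fewer than five
substitutions are dropped from correlation analyses.

**Counting estimator.** Ancestral codons come either from marginal
(empirical Bayes) reconstruction under the fitted model (ties broken
toward the more frequent codon) or from unit-cost parsimony (Sankoff,
ties toward the parent state) when no fit is available. Per branch,
differences between parent and child codons are averaged over minimal
mutational pathways that avoid stop codons (Nei–Gojobori pathway
counting) and site counts are κ-weighted mutational opportunities
averaged over the two endpoint sequences, so N + S = 3 × codons
compared. Pathway counting ignores multiple hits, so it is only
consistent with the ML estimator at moderate divergence; the
consistency check in the test suite therefore runs at roughly half a
substitution per codon root-to-tip, while deeper analyses should trust
the ML route.

## Statistics

Branches, not taxa, are the statistical unit; tables join on the
child-node label. Spearman's rho uses average ranks for ties and a
two-tailed t approximation with n − 2 degrees of freedom (the common
statistical-package default at these sample sizes; exact permutation is
not attempted). OLS regression treats the molecular variable as the
predictor and the enamel branch score as the response, returning the
two-tailed slope test and residuals; under the log-transformed variant
non-positive predictor values are excluded and counted, since log 0 is
undefined (lesion rates, which are mostly zero, are never
log-transformed). Residual normality uses the Anderson–Darling case-3
statistic (mean and variance estimated), computed stepwise from the
sorted standardized sample, with the small-sample correction
A\* = A²(1 + 0.75/n + 2.25/n²) and the standard piecewise significance
approximation.

## Synthetic data

The generator's defaults describe a small odontocete-like study: a
14-taxon ingroup radiating over the last 36 MYR plus two intact
outgroup references, root age 50 MYR, κ = 4, a modest GC skew
(GC = 0.55), 0.012 substitutions per codon per MYR (≈ 0.6 per codon
root-to-tip), seven gene partitions of 30 codons each with three exons
and canonical splice windows, and two selection regimes — ω = 0.05
background purifying selection versus ω = 0.8 relaxed selection on one
clade covering about half the ingroup, mirroring the contrast between
enamel-bearing dolphins and the degenerate-enamel families. Sequences
evolve by event-level Gillespie simulation so every branch has an exact
log of realized synonymous and nonsynonymous events. Lesions are
injected afterwards as edits on all descendants of scheduled branches
(default: about 1.5 per relaxed terminal, covering all six classes);
placements that would collide with an earlier edit — and thereby change
what a detector reports — are skipped, so the injection log is exactly
the expected scan output. A quarter of point lesions are heterozygous,
with coverage ~ Poisson(30) (floored at 10×) and balanced allele counts
clipped to the 40% rule so the weighting is decidable. Tip enamel
scores follow a monotone decreasing link from regime to category
(purifying → 5, relaxed → 2) with a ±1 shift with probability 0.15 and
an adjacent polymorphic pair with probability 0.10.

What the generator does *not* emulate: alignment error, sequencing or
assembly artifacts, within-gene rate heterogeneity, indel evolution
outside the injected lesions, gene-tree discordance, and correlated
phenotypic evolution beyond the single regime link. Passing end-to-end
tests therefore demonstrates the pipeline's internal correctness under
its own model assumptions, not robustness to real-data misalignment or
annotation error.

Simulation-based calibration in the test suite is read against the
simulation's own spread: per-branch ω is a ratio estimate whose mean
over branches carries finite-sample (Jensen-type) upward skew of a few
percent at these branch lengths — the true realized event ratios show
the same skew — so the neutral calibration asks that the 95% interval
of replicate means bracket ω = 1, not that every mean hit 1.0 exactly.

## Shipped reference data

The lesion catalog, taxonomy, and enamel-score tables are transcribed
into TSV with underscored binomials; the catalog's genus-label typo is
corrected and the wild yak is consistently *Bos mutus*. The 93- and
37-taxon species trees encode the accepted family-level topology
(Physeteroidea basal among odontocetes, then Ziphiidae, Platanistidae,
Lipotidae, Inioidea, and Delphinoidea = Delphinidae + (Monodontidae +
Phocoenidae)) with arbitrary pectinate arrangements inside families
(genera kept monophyletic) and placeholder ultrametric ages. The
catalog tallies need topology only; rate-per-MYR analyses on real data
require a calibrated timetree supplied by the user.

## Known limitations

- The free-ratio optimizer is a coordinate ascent with a single start;
  multimodal likelihood surfaces (very short or clamped branches) can
  leave individual ω at local optima, which is why inexact flags and
  the ≥ 5-substitution filter exist.
- Pathway counting saturates on long branches (dS first), inflating the
  counting ω there.
- The lesion scanner assumes the gene model annotates the alignment
  correctly; it does not re-align or detect annotation errors.
- Clade-labeled catalog rows expand through the shipped clade table;
  lesions shared by taxon sets that are not named clades keep a
  `+`-joined bearer label.
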