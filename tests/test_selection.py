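"""Codon-model machinery: recoding, frequencies, the free-ratio fit, and
the counting cross-check."""

import math

import numpy as np
import pytest

from enamelevo import codon as C
from enamelevo.model import GeneAlignment, GeneModel
from enamelevo.selection import (
    CodonAlignment,
    codon_frequencies,
    counting_dnds,
    filter_branches,
    fit_free_ratio,
    marginal_ancestral,
    parsimony_ancestral,
    recode_for_selection,
)
from enamelevo.selection import _Pruner  # noqa: internal, exercised directly
from enamelevo.simulate import SimulationConfig, simulate_codon_alignment
from enamelevo.timetree import TimeTree

REFS = ("R1", "R2")


def _sim_alignment(seed, n_ingroup=6, codons=300, w_pur=1.0, w_rel=1.0,
                   rate=0.012):
    cfg = SimulationConfig(seed=seed, n_ingroup=n_ingroup, n_references=2,
                           gene_codons=(codons,), genes=("G1",),
                           omega_purifying=w_pur, omega_relaxed=w_rel,
                           subs_per_codon_per_myr=rate)
    tips, true_events, tree, regimes, _ = simulate_codon_alignment(cfg)
    taxa = sorted(tips)
    aln = CodonAlignment(taxa=taxa, matrix=np.stack([tips[t] for t in taxa]))
    return aln, tree, regimes, true_events


class TestRateMatrix:
    def test_rows_sum_to_zero_and_detailed_balance(self):
        pi = np.random.default_rng(0).dirichlet(np.ones(61))
        q = C.rate_matrix(kappa=3.0, omega=0.4, pi=pi)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_flux_ratio_recovers_omega(self):
        """dN/dS from the flux decomposition equals the omega parameter."""
        pi = np.random.default_rng(1).dirichlet(np.ones(61))
        rs1, rn1 = C.flux_fractions(2.5, 1.0, pi)
        for w in (0.05, 0.3, 1.0, 2.0):
            rs, rn = C.flux_fractions(2.5, w, pi)
            assert (rn / rs) / (rn1 / rs1) == pytest.approx(w)

    def test_site_counts_sum_to_three(self):
        for codon in ("ATG", "GGG", "TTA", "CGA"):
            s, n = C.site_counts(codon, kappa=2.0)
            assert s + n == pytest.approx(3.0)

    def test_pathway_counting_single_step(self):
        # GGT -> GGC is synonymous (glycine)
        assert C.shortest_paths_counts("GGT", "GGC") == (1.0, 0.0)
        # ATG -> GTG is nonsynonymous (M -> V)
        assert C.shortest_paths_counts("ATG", "GTG") == (0.0, 1.0)


class TestRecode:
    def make_gene(self, query, ref="ATGAAACCCTAA"):
        model = GeneModel.from_exon_lengths("G1", [12])
        aln = GeneAlignment("G1", {"R1": ref, "R2": ref, "q": query})
        return {"G1": (aln, model)}

    def test_stop_recoded_to_missing(self):
        caln = recode_for_selection(self.make_gene("ATGTAACCCTAA"), REFS)
        row = caln.row("q")
        assert row[1] == -1           # internal TAA -> missing
        assert row[0] == C.CODON_INDEX["ATG"]
        # terminal stop columns are dropped entirely
        assert caln.n_codons == 3

    def test_insertion_columns_removed(self):
        model = GeneModel("G1", exons=((1, 1, 14),), start_codon=(1, 2, 3),
                          stop_codon=(12, 13, 14))
        ref = "ATGAAA--CCCTAA"
        aln = GeneAlignment("G1", {"R1": ref, "R2": ref, "q": "ATGAAATTCCCTAA"})
        caln = recode_for_selection({"G1": (aln, model)}, REFS)
        assert caln.n_codons == 3
        assert caln.row("q")[2] == C.CODON_INDEX["CCC"]

    def test_concatenation_length_and_padding(self):
        genes = {}
        for name, n_exon_cod in (("A", 4), ("B", 5)):
            model = GeneModel.from_exon_lengths(name, [n_exon_cod * 3])
            ref = ("ATG" + "AAA" * (n_exon_cod - 2) + "TAA")
            seqs = {"R1": ref, "R2": ref}
            if name == "A":
                seqs["q"] = ref
            genes[name] = (GeneAlignment(name, seqs, absent=() if name == "A"
                                         else ("q",)), model)
        caln = recode_for_selection(genes, REFS, gene_order=("A", "B"),
                                    taxa=["R1", "R2", "q"])
        assert caln.n_codons == (4 - 1) + (5 - 1)
        assert caln.gene_bounds == {"A": (0, 3), "B": (3, 7)}
        assert (caln.row("q")[3:] == -1).all()   # missing gene padded


class TestFrequencies:
    def test_uniform_composition_gives_uniform_codons(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 61, size=(4, 6000)).astype(np.int16)
        # integer-uniform codon usage is not nucleotide-uniform; build from
        # uniform nucleotides instead
        nts = rng.integers(0, 4, size=(4, 18000))
        codons = []
        for row in nts:
            cs = []
            for k in range(0, len(row) - 2, 3):
                codon = "".join("ACGT"[b] for b in row[k:k + 3])
                cs.append(C.CODON_INDEX.get(codon, -1))
            codons.append(cs)
        aln = CodonAlignment(taxa=list("abcd"), matrix=np.array(codons))
        cf1 = codon_frequencies(aln, "CF1")
        cf2 = codon_frequencies(aln, "CF2")
        assert np.allclose(cf1, 1 / 61, atol=0.004)
        assert np.allclose(cf1, cf2, atol=0.01)

    def test_g_rich_third_positions_separate_cf2(self):
        codons = [c for c in C.SENSE_CODONS if c.endswith("G")]
        idx = [C.CODON_INDEX[c] for c in codons]
        rng = np.random.default_rng(3)
        mat = rng.choice(idx, size=(4, 2000)).astype(np.int16)
        aln = CodonAlignment(taxa=list("abcd"), matrix=mat)
        cf1 = codon_frequencies(aln, "CF1")
        cf2 = codon_frequencies(aln, "CF2")
        third_g = [i for i, c in enumerate(C.SENSE_CODONS) if c[2] == "G"]
        assert cf2[third_g].sum() > cf1[third_g].sum()
        assert cf2[third_g].sum() == pytest.approx(1.0)

    def test_single_codon_alignment(self):
        mat = np.full((3, 50), C.CODON_INDEX["ATG"], dtype=np.int16)
        aln = CodonAlignment(taxa=list("abc"), matrix=mat)
        # position-specific frequencies concentrate all mass on ATG
        cf2 = codon_frequencies(aln, "CF2")
        assert cf2.argmax() == C.CODON_INDEX["ATG"]
        assert cf2[C.CODON_INDEX["ATG"]] == pytest.approx(1.0, abs=1e-6)
        # pooled frequencies still rank ATG maximal (tied with other
        # codons drawn from the same three nucleotides)
        cf1 = codon_frequencies(aln, "CF1")
        assert cf1[C.CODON_INDEX["ATG"]] == pytest.approx(cf1.max())
        assert cf1.sum() == pytest.approx(1.0)

    def test_cf_vectors_normalized_on_simulation(self):
        aln, _, _, _ = _sim_alignment(5, codons=120)
        for model in ("CF1", "CF2"):
            pi = codon_frequencies(aln, model)
            assert pi.sum() == pytest.approx(1.0)
            assert (pi > 0).all()


class TestLikelihood:
    def test_invariant_to_rooting(self):
        """Same unrooted tree, two rooted inputs, equal likelihood."""
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 61, size=(4, 80)).astype(np.int16)
        aln = CodonAlignment(taxa=list("abcd"), matrix=mat)
        pi = codon_frequencies(aln, "CF1")
        t1 = TimeTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = TimeTree.from_newick("(((a:1,b:1):2,c:3):1,d:4);")
        vals = []
        for tree in (t1, t2):
            eng = _Pruner(aln, tree, pi)
            t = {e: 0.07 for e in eng.edges}
            w = {e: 0.5 for e in eng.edges}
            vals.append(eng.lnl(2.0, t, w))
        assert vals[0] == pytest.approx(vals[1], abs=1e-8)

    def test_one_ratio_never_beats_free_ratio(self):
        aln, tree, _, _ = _sim_alignment(9, codons=150, w_pur=0.1, w_rel=0.9)
        free = fit_free_ratio(aln, tree, max_sweeps=30)
        one = fit_free_ratio(aln, tree, one_ratio=True, max_sweeps=30)
        assert one.lnl <= free.lnl + 1e-6

    def test_identical_sequences_give_inexact_zero_branches(self):
        mat = np.tile(np.arange(40, dtype=np.int16) % 61, (3, 1))
        aln = CodonAlignment(taxa=list("abc"), matrix=mat)
        tree = TimeTree.from_newick("((a:1,b:1):1,c:2);")
        fit = fit_free_ratio(aln, tree, max_sweeps=8)
        for est in fit.estimates.values():
            assert est.substitution_count < 1.0
            assert est.inexact


class TestRecovery:
    def test_regime_rank_separation(self):
        """Relaxed (w=0.8) branches outrank purifying (w=0.05) ones."""
        aln, tree, regimes, _ = _sim_alignment(101, codons=400,
                                               w_pur=0.05, w_rel=0.8)
        fit = fit_free_ratio(aln, tree)
        keep = filter_branches(fit.estimates, 5)
        ests = [(fit.estimates[b].omega, regimes[b]) for b in keep
                if b in regimes]
        relaxed = [w for w, r in ests if r == "relaxed"]
        purifying = [w for w, r in ests if r == "purifying"]
        assert min(relaxed) > max(purifying)

    def test_counting_agrees_with_ml(self):
        """At moderate divergence (little saturation) the pathway-counting
        and ML per-branch omegas rank branches the same way."""
        from scipy.stats import spearmanr
        aln, tree, _, _ = _sim_alignment(103, n_ingroup=8, codons=500,
                                         w_pur=0.05, w_rel=0.8, rate=0.006)
        fit = fit_free_ratio(aln, tree)
        anc = marginal_ancestral(aln, tree, fit)
        cnt = counting_dnds(aln, tree, anc, kappa=fit.kappa)
        keep = [b for b in filter_branches(fit.estimates, 5)
                if np.isfinite(cnt[b].omega)]
        rho = spearmanr([fit.estimates[b].omega for b in keep],
                        [cnt[b].omega for b in keep]).statistic
        assert rho > 0.9

    def test_counting_site_counts_sum(self):
        aln, tree, _, _ = _sim_alignment(7, codons=100)
        anc = parsimony_ancestral(aln, tree)
        ests = counting_dnds(aln, tree, anc, kappa=2.0)
        for est in ests.values():
            assert est.n_sites + est.s_sites == pytest.approx(3 * aln.n_codons)

    def test_counting_hand_case(self):
        """3 codons, one synonymous + one nonsynonymous change on the same
        terminal branch, verified against hand-applied pathway counting."""
        codons = ["ATG", "GGT", "CTT"]
        variant = ["ATG", "GGC", "CAT"]  # GGT->GGC syn; CTT->CAT L->H nonsyn
        idx = lambda cs: [C.CODON_INDEX[c] for c in cs]
        mat = np.array([idx(codons), idx(codons), idx(variant)], dtype=np.int16)
        aln = CodonAlignment(taxa=["a", "b", "q"], matrix=mat)
        tree = TimeTree.from_newick("((a:1,b:1):1,q:2);")
        anc = parsimony_ancestral(aln, tree)
        ests = counting_dnds(aln, tree, anc, kappa=1.0)
        q = ests["q"]
        # CTT -> CAT differs at one position: exactly 1 nonsyn step
        # GGT -> GGC: 1 syn step
        assert q.substitution_count == pytest.approx(2.0)
        assert q.ds > 0 and q.dn > 0
        # site counts: mean of the endpoint sequences' opportunities
        s_total = (sum(C.site_counts(c, 1.0)[0] for c in codons)
                   + sum(C.site_counts(c, 1.0)[0] for c in variant)) / 2
        assert q.s_sites == pytest.approx(s_total)
        assert q.dn == pytest.approx(1.0 / q.n_sites)
        assert q.ds == pytest.approx(1.0 / q.s_sites)
        assert q.omega == pytest.approx(q.s_sites / q.n_sites)

    def test_pure_synonymous_branch(self):
        codons = ["GGT", "AAA", "CCC"]
        variant = ["GGC", "AAA", "CCC"]
        idx = lambda cs: [C.CODON_INDEX[c] for c in cs]
        mat = np.array([idx(codons), idx(codons), idx(variant)], dtype=np.int16)
        aln = CodonAlignment(taxa=["a", "b", "q"], matrix=mat)
        tree = TimeTree.from_newick("((a:1,b:1):1,q:2);")
        ests = counting_dnds(aln, tree, parsimony_ancestral(aln, tree), kappa=1.0)
        assert ests["q"].ds > 0
        assert ests["q"].dn == 0
        assert ests["q"].inexact


class TestFilter:
    def test_threshold(self):
        from enamelevo.selection import BranchEstimate
        mk = lambda b, s: BranchEstimate(branch=b, t=0.1, omega=0.5, dn=0.1,
                                         ds=0.2, n_sites=10, s_sites=5,
                                         substitution_count=s, inexact=False)
        ests = {"a": mk("a", 4.2), "b": mk("b", 5.0), "c": mk("c", 80.0)}
        assert filter_branches(ests, 5) == ["b", "c"]
        assert filter_branches(ests, 0) == ["a", "b", "c"]
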