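"""Codon-state machinery for the selection analyses.

State space: the 61 sense codons of the universal genetic code (stops
are recoded to missing upstream).  The substitution process follows a
Goldman-Yang-style parameterization: single-nucleotide changes only,
target-codon frequency pi_j, a transition/transversion ratio kappa, and
a nonsynonymous multiplier omega.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS", "STOP_CODONS", "CODON_INDEX", "AMINO_ACID", "NT",
    "is_transition", "rate_matrix", "flux_fractions", "shortest_paths_counts",
    "site_counts",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # universal code

NT = "ACGT"
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _single_nt_pairs():
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) == 1:
                yield i, j, diffs[0]


_PAIRS = list(_single_nt_pairs())
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([is_transition(*p[2]) for p in _PAIRS])
_PAIR_SYN = np.array([
    AMINO_ACID[SENSE_CODONS[p[0]]] == AMINO_ACID[SENSE_CODONS[p[1]]] for p in _PAIRS
])


def rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                normalize: bool = True) -> np.ndarray:
    """61x61 instantaneous rate matrix Q.

    q_ij = pi_j * (kappa if transition) * (omega if nonsynonymous) for
    single-nucleotide changes, 0 otherwise; rows sum to 0.  When
    ``normalize`` the matrix is scaled so the expected rate at
    stationarity is one substitution per codon per unit branch length.
    """
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    w = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    q[_PAIR_I, _PAIR_J] = w
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        scale = -(pi * np.diag(q)).sum()
        if scale > 0:
            q /= scale
    return q


def flux_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractions of the substitution flux."""
    w = pi[_PAIR_I] * pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0)
    syn = w[_PAIR_SYN].sum()
    nonsyn = omega * w[~_PAIR_SYN].sum()
    tot = syn + nonsyn
    return float(syn / tot), float(nonsyn / tot)


def site_counts(codon: str, kappa: float) -> tuple[float, float]:
    """Kappa-weighted (synonymous, nonsynonymous) site counts of one codon.

    Each of the nine single-nucleotide neighbors is weighted kappa
    (transition) or 1 (transversion); paths into stop codons count as
    nonsynonymous opportunity removed from the total, mirroring the
    mutational-opportunity convention.  Counts sum to 3.
    """
    syn_w = tot_w = 0.0
    for pos in range(3):
        for nt in NT:
            if nt == codon[pos]:
                continue
            target = codon[:pos] + nt + codon[pos + 1:]
            w = kappa if is_transition(codon[pos], nt) else 1.0
            tot_w += w
            if target in AMINO_ACID and AMINO_ACID[target] == AMINO_ACID[codon]:
                syn_w += w
    s = 3.0 * syn_w / tot_w
    return s, 3.0 - s


def shortest_paths_counts(a: str, b: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) step counts over all minimal
    mutational pathways between two sense codons, skipping pathways that
    pass through stop codons (Nei-Gojobori pathway counting)."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt not in AMINO_ACID:
                ok = False
                break
            if AMINO_ACID[nxt] == AMINO_ACID[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            n_paths += 1
            syn_tot += syn
            nonsyn_tot += nonsyn
    if n_paths == 0:
        # all pathways blocked by stops: split evenly as a degenerate fallback
        return len(diffs) / 2, len(diffs) / 2
    return syn_tot / n_paths, nonsyn_tot / n_paths
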