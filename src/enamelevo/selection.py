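"""Per-branch dN/dS estimation on the concatenated codon alignment.

Two estimators share one alignment representation:

* ``fit_free_ratio`` — maximum likelihood under a Goldman-Yang-style
  codon model with a free omega per branch, evaluated on the unrooted
  tree by Felsenstein pruning and optimized by bounded coordinate ascent
  (branch lengths and per-branch omega alternated until the
  log-likelihood stalls).
* ``counting_dnds`` — modified Nei-Gojobori pathway counting between
  reconstructed ancestral codons, with kappa-weighted site counts; a
  fast, independent cross-check of the ML fit.

Branch lengths are expected substitutions per codon; per-branch dN and
dS follow the usual decomposition of the substitution flux, so
``substitution_count = N*dN + S*dS = n_codons * t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import codon as C
from .model import GAP, GENE_ORDER, GeneAlignment, GeneModel
from .scan import _insertion_columns
from .timetree import TimeTree

__all__ = [
    "CodonAlignment",
    "recode_for_selection",
    "codon_frequencies",
    "BranchEstimate",
    "SelectionFit",
    "fit_free_ratio",
    "marginal_ancestral",
    "parsimony_ancestral",
    "counting_dnds",
    "filter_branches",
]

MISSING = -1
OMEGA_MIN, OMEGA_MAX = 1e-4, 999.0
T_MIN, T_MAX = 1e-7, 25.0


@dataclass
class CodonAlignment:
    """Integer codon matrix: rows taxa, columns codons; -1 = missing."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_codons) int16
    gene_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int16)
        if self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix rows must match taxa")

    @property
    def n_codons(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]


def _codon_index(codon: str) -> int:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return MISSING
    if codon in C.STOP_CODONS:
        return MISSING  # premature stops recoded as missing data
    return C.CODON_INDEX[codon]


def recode_for_selection(genes: dict[str, tuple[GeneAlignment, GeneModel]],
                         references,
                         gene_order=GENE_ORDER,
                         taxa: list[str] | None = None) -> CodonAlignment:
    """Build the concatenated, selection-ready codon alignment.

    Per gene: intron windows are discarded, frameshift-insertion columns
    (gapped in all references) are deleted for every taxon, the annotated
    terminal stop codon is dropped, and every remaining stop codon is
    recoded to missing.  Genes are concatenated in a fixed order; taxa
    lacking a gene are padded with missing codons.
    """
    order = [g for g in gene_order if g in genes]
    extra = sorted(set(genes) - set(order))
    order += extra
    if taxa is None:
        taxa = sorted({t for g in order for t in genes[g][0].sequences})
    blocks = []
    bounds = {}
    pos = 0
    for gene in order:
        aln, model = genes[gene]
        ins = _insertion_columns(aln, model, references)
        stop_cols = set(model.stop_codon or ())
        cols = [c for c in model.cds_columns() if c not in ins and c not in stop_cols]
        if len(cols) % 3:
            raise ValueError(
                f"{gene}: {len(cols)} reference coding columns, not a codon multiple"
            )
        n_cod = len(cols) // 3
        block = np.full((len(taxa), n_cod), MISSING, dtype=np.int16)
        for ti, taxon in enumerate(taxa):
            seq = aln.sequences.get(taxon)
            if seq is None:
                continue
            for k in range(n_cod):
                codon = "".join(seq[cols[3 * k + j] - 1] for j in range(3))
                block[ti, k] = _codon_index(codon)
        blocks.append(block)
        bounds[gene] = (pos, pos + n_cod)
        pos += n_cod
    matrix = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(taxa), 0), int)
    return CodonAlignment(taxa=list(taxa), matrix=matrix, gene_bounds=bounds)


# -- codon frequencies --------------------------------------------------

_NT_AT = np.array([[C.NT.index(c[p]) for p in range(3)] for c in C.SENSE_CODONS])


def codon_frequencies(aln: CodonAlignment, model: str = "CF1") -> np.ndarray:
    """Equilibrium codon frequencies from observed nucleotide composition.

    CF1 pools nucleotide frequencies across the three codon positions;
    CF2 keeps them position-specific.  Stop codons are excluded and the
    61-vector renormalized.
    """
    model = model.upper()
    if model not in ("CF1", "CF2"):
        raise ValueError(f"frequency model must be CF1 or CF2, not {model!r}")
    obs = aln.matrix[aln.matrix >= 0]
    if obs.size == 0:
        return np.full(61, 1.0 / 61)
    fpos = np.zeros((3, 4))
    for p in range(3):
        fpos[p] = np.bincount(_NT_AT[obs, p], minlength=4)
    fpos /= fpos.sum(axis=1, keepdims=True)
    if model == "CF1":
        pooled = fpos.mean(axis=0)
        fpos = np.tile(pooled, (3, 1))
    pi = fpos[0, _NT_AT[:, 0]] * fpos[1, _NT_AT[:, 1]] * fpos[2, _NT_AT[:, 2]]
    pi = np.clip(pi, 1e-12, None)
    return pi / pi.sum()


# -- tree plumbing ------------------------------------------------------


def _unrooted_edges(tree: TimeTree):
    """Adjacency of the unrooted tree plus a pruning root.

    If the input root is a bifurcation its two incident edges are merged
    (reported under the label of the second root child); the pruning
    root is the first internal node found.
    """
    adj: dict[str, set[str]] = {}

    def link(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    merged_under = None
    root = tree.root
    kids = root.child_nodes()
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        link(tree.label(node.parent_node), tree.label(node))
    if len(kids) == 2:
        a, b = (tree.label(k) for k in kids)
        rl = tree.label(root)
        adj[a].discard(rl)
        adj[b].discard(rl)
        del adj[rl]
        link(a, b)
        merged_under = b
    tips = set(tree.taxa)
    proot = next(lbl for lbl in adj if lbl not in tips)
    # direct edges away from proot
    parent: dict[str, str] = {}
    order = [proot]
    seen = {proot}
    queue = [proot]
    while queue:
        u = queue.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
                queue.append(v)
    children = {u: [] for u in order}
    for v, u in parent.items():
        children[u].append(v)
    for u in children:
        children[u].sort()
    return proot, parent, children, order, merged_under


# -- results ------------------------------------------------------------


@dataclass
class BranchEstimate:
    branch: str
    t: float
    omega: float
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    substitution_count: float
    inexact: bool


@dataclass
class SelectionFit:
    estimates: dict[str, BranchEstimate]
    lnl: float
    kappa: float
    pi: np.ndarray
    freq_model: str
    converged: bool
    sweeps: int
    merged_root_branch: str | None = None

    def omega_of(self) -> dict[str, float]:
        return {b: e.omega for b, e in self.estimates.items()}


# -- likelihood machinery -----------------------------------------------


class _Pruner:
    """Pattern-compressed pruning engine over the 61 sense codons."""

    def __init__(self, aln: CodonAlignment, tree: TimeTree, pi: np.ndarray):
        self.pi = pi
        (self.root, self.parent, self.children,
         self.order, self.merged) = _unrooted_edges(tree)
        self.edges = [v for v in self.order if v != self.root]
        cols = np.ascontiguousarray(aln.matrix.T)
        patterns, self.weights = np.unique(cols, axis=0, return_counts=True)
        self.n_pat = patterns.shape[0]
        self.tipL: dict[str, np.ndarray] = {}
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        for label in self.order:
            if label in taxon_row:
                states = patterns[:, taxon_row[label]]
                L = np.zeros((self.n_pat, 61))
                known = states >= 0
                L[~known, :] = 1.0
                L[np.flatnonzero(known), states[known]] = 1.0
                self.tipL[label] = L
        self.pi_sqrt = np.sqrt(pi)
        self._eig_cache: dict[tuple, tuple] = {}

    def _eig(self, kappa, omega):
        key = (round(kappa, 12), round(omega, 12))
        hit = self._eig_cache.get(key)
        if hit is None:
            q = C.rate_matrix(kappa, omega, self.pi)
            b = (q * self.pi_sqrt[:, None]) / self.pi_sqrt[None, :]
            b = (b + b.T) / 2  # enforce symmetry against round-off
            hit = np.linalg.eigh(b)
            if len(self._eig_cache) > 512:
                self._eig_cache.clear()
            self._eig_cache[key] = hit
        return hit

    def prob_matrix(self, kappa, omega, t):
        lam, v = self._eig(kappa, omega)
        p = (v * np.exp(lam * t)) @ v.T
        p = (p / self.pi_sqrt[:, None]) * self.pi_sqrt[None, :]
        return np.clip(p, 0.0, None)

    def down_partials(self, kappa, t, omega):
        """Postorder conditional likelihoods with per-pattern log scaling."""
        down: dict[str, np.ndarray] = {}
        scale: dict[str, np.ndarray] = {}
        for label in reversed(self.order):
            kids = self.children[label]
            if not kids:
                down[label] = self.tipL[label]
                scale[label] = np.zeros(self.n_pat)
                continue
            acc = self.tipL.get(label)
            acc = np.ones((self.n_pat, 61)) if acc is None else acc.copy()
            sc = np.zeros(self.n_pat)
            for c in kids:
                p = self.prob_matrix(kappa, omega[c], t[c])
                acc *= down[c] @ p.T
                sc += scale[c]
            m = acc.max(axis=1)
            m[m == 0] = 1.0
            acc /= m[:, None]
            sc = sc + np.log(m)
            down[label] = acc
            scale[label] = sc
        return down, scale

    def lnl(self, kappa, t, omega, down=None, scale=None):
        if down is None:
            down, scale = self.down_partials(kappa, t, omega)
        site = down[self.root] @ self.pi
        return float(np.dot(self.weights, np.log(site) + scale[self.root]))

    def outside(self, kappa, t, omega, down, scale):
        """Per-edge outside vectors O_e (at the parent endpoint), with
        the same scaling discipline as the down pass.  Also returns the
        node-side vectors R_v = O_e P(t_e) used for marginal posteriors
        (R_v * down_v is proportional to the state posterior at v)."""
        out: dict[str, np.ndarray] = {}
        oscale: dict[str, np.ndarray] = {}
        R = {self.root: np.tile(self.pi, (self.n_pat, 1))}
        Rs = {self.root: np.zeros(self.n_pat)}
        for label in self.order:
            kids = self.children[label]
            if not kids:
                continue
            contrib = {}
            for c in kids:
                p = self.prob_matrix(kappa, omega[c], t[c])
                contrib[c] = (down[c] @ p.T, p)
            base_tip = self.tipL.get(label)
            for c in kids:
                o = R[label].copy()
                osc = Rs[label].copy()
                if base_tip is not None:
                    o = o * base_tip
                for c2 in kids:
                    if c2 is c:
                        continue
                    o = o * contrib[c2][0]
                    osc += scale[c2]
                m = o.max(axis=1)
                m[m == 0] = 1.0
                o /= m[:, None]
                osc = osc + np.log(m)
                out[c] = o
                oscale[c] = osc
                R[c] = o @ contrib[c][1]
                Rs[c] = osc
        return out, oscale, R


def _estimate_kappa(aln: CodonAlignment) -> float:
    """Pairwise transition/transversion count ratio, scaled by the 1:2
    opportunity ratio — a deliberately rough initializer."""
    mat = aln.matrix
    nt = _NT_AT[np.clip(mat, 0, None)]  # (taxa, codons, 3)
    nt = np.where(mat[..., None] >= 0, nt, -1).reshape(mat.shape[0], -1)
    ts = tv = 0
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nt[i], nt[j]
            ok = (a >= 0) & (b >= 0) & (a != b)
            pur_a = (a == 0) | (a == 2)
            pur_b = (b == 0) | (b == 2)
            ts += int(np.sum(ok & (pur_a == pur_b)))
            tv += int(np.sum(ok & (pur_a != pur_b)))
    if tv == 0:
        return 2.0
    return max(0.1, 2.0 * ts / tv)


def _init_branch_length(aln: CodonAlignment, n_edges: int) -> float:
    mat = aln.matrix
    nt = _NT_AT[np.clip(mat, 0, None)].reshape(mat.shape[0], -1)
    miss = (mat < 0)[:, :, None].repeat(3, axis=2).reshape(mat.shape[0], -1)
    dists = []
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            tot = int(ok.sum())
            if tot == 0:
                continue
            p = float(np.sum((nt[i] != nt[j]) & ok)) / tot
            p = min(p, 0.70)
            d = -0.75 * math.log(1 - 4 * p / 3)
            dists.append(d)
    if not dists:
        return 0.05
    mean_codon = 3.0 * float(np.mean(dists))
    # a root-to-tip path crosses roughly half the edges of a pectinate
    # pass and log2(n) of a balanced one; split the difference
    per_edge = mean_codon / max(2.0, n_edges / 2.0)
    return float(np.clip(per_edge, 1e-4, 2.0))


def fit_free_ratio(aln: CodonAlignment, tree: TimeTree,
                   freq_model: str = "CF1", kappa: float | None = None,
                   one_ratio: bool = False, init_omega: float = 0.2,
                   max_sweeps: int = 200, tol: float = 1e-6,
                   optimize_kappa: bool = True) -> SelectionFit:
    """Maximum-likelihood branch lengths and per-branch omega.

    Kappa starts at a pairwise counting estimate (or the value given)
    and is refined by scalar ML updates between sweeps unless
    ``optimize_kappa`` is off; branch lengths and omegas are alternated
    branch-by-branch with bounded scalar optimization until the
    log-likelihood improves by less than ``tol`` or ``max_sweeps`` is
    hit.  Partial-likelihood caches are refreshed once per sweep, so a
    sweep is a Gauss-Seidel pass against slightly stale partials; the
    sweep-end likelihood check keeps the ascent honest.  With
    ``one_ratio`` a single omega is shared by all branches.
    """
    if len(aln.taxa) < 3:
        raise ValueError("free-ratio fit needs at least 3 taxa")
    pi = codon_frequencies(aln, freq_model)
    engine = _Pruner(aln, tree, pi)
    if kappa is None:
        kappa = _estimate_kappa(aln)
    t0 = _init_branch_length(aln, len(engine.edges))
    t = {e: t0 for e in engine.edges}
    omega = {e: init_omega for e in engine.edges}

    def edge_obj(out, osc, dn, dsc):
        def f(tt, ww):
            p = engine.prob_matrix(kappa, ww, tt)
            site = np.maximum(((out @ p) * dn).sum(axis=1), 1e-300)
            return float(np.dot(engine.weights, np.log(site) + osc + dsc))
        return f

    lnl = engine.lnl(kappa, t, omega)
    sweeps = 0
    converged = False
    best = (lnl, dict(t), dict(omega), kappa)
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        down, scale = engine.down_partials(kappa, t, omega)
        out, oscale, _ = engine.outside(kappa, t, omega, down, scale)
        for e in engine.edges:
            f = edge_obj(out[e], oscale[e], down[e], scale[e])
            res = minimize_scalar(lambda x: -f(x, omega[e]), bounds=(T_MIN, T_MAX),
                                  method="bounded", options={"xatol": 1e-6})
            t[e] = float(res.x)
            if not one_ratio:
                res = minimize_scalar(lambda x: -f(t[e], math.exp(x)),
                                      bounds=(math.log(OMEGA_MIN), math.log(OMEGA_MAX)),
                                      method="bounded", options={"xatol": 1e-4})
                omega[e] = float(math.exp(res.x))
        if one_ratio:
            def g(logw):
                w = {e: math.exp(logw) for e in engine.edges}
                return -engine.lnl(kappa, t, w)
            res = minimize_scalar(g, bounds=(math.log(OMEGA_MIN), math.log(OMEGA_MAX)),
                                  method="bounded", options={"xatol": 1e-4})
            shared = float(math.exp(res.x))
            omega = {e: shared for e in engine.edges}
        if optimize_kappa:
            res = minimize_scalar(
                lambda x: -engine.lnl(math.exp(x), t, omega),
                bounds=(math.log(0.1), math.log(60.0)),
                method="bounded", options={"xatol": 1e-3},
            )
            kappa = float(math.exp(res.x))
        new = engine.lnl(kappa, t, omega)
        if new > best[0]:
            best = (new, dict(t), dict(omega), kappa)
        if new - lnl < tol:
            converged = new - lnl > -tol or converged
            break
        lnl = new
    lnl, t, omega, kappa = best

    rho_s1, rho_n1 = C.flux_fractions(kappa, 1.0, pi)
    L = aln.n_codons
    s_sites = 3.0 * L * rho_s1
    n_sites = 3.0 * L * rho_n1
    estimates = {}
    for e in engine.edges:
        rs, rn = C.flux_fractions(kappa, omega[e], pi)
        syn_subs = t[e] * rs * L
        nonsyn_subs = t[e] * rn * L
        ds = syn_subs / s_sites * 1.0 if s_sites else 0.0
        dn = nonsyn_subs / n_sites * 1.0 if n_sites else 0.0
        subs = L * t[e]
        inexact = (
            syn_subs < 0.5 or nonsyn_subs < 0.5
            or omega[e] <= OMEGA_MIN * 1.01 or omega[e] >= OMEGA_MAX * 0.99
        )
        estimates[e] = BranchEstimate(
            branch=e, t=t[e], omega=omega[e], dn=dn, ds=ds,
            n_sites=n_sites, s_sites=s_sites,
            substitution_count=subs, inexact=inexact,
        )
    return SelectionFit(estimates=estimates, lnl=lnl, kappa=kappa, pi=pi,
                        freq_model=freq_model.upper(), converged=converged,
                        sweeps=sweeps, merged_root_branch=engine.merged)


# -- ancestral codons ----------------------------------------------------


def marginal_ancestral(aln: CodonAlignment, tree: TimeTree, fit: SelectionFit
                       ) -> dict[str, np.ndarray]:
    """Marginal (empirical Bayes) codon states per node under the fitted
    model; ties broken toward the more frequent codon.  Tips keep their
    observed states (missing stays missing)."""
    engine = _Pruner(aln, tree, fit.pi)
    t = {e: fit.estimates[e].t for e in engine.edges}
    omega = {e: fit.estimates[e].omega for e in engine.edges}
    down, scale = engine.down_partials(fit.kappa, t, omega)
    _, _, node_out = engine.outside(fit.kappa, t, omega, down, scale)
    cols = np.ascontiguousarray(aln.matrix.T)
    patterns, inverse = np.unique(cols, axis=0, return_inverse=True)
    states: dict[str, np.ndarray] = {}
    order_pi = fit.pi  # tie-break weight
    for label in engine.order:
        if label == engine.root:
            post = down[label] * engine.pi[None, :]
        elif label in engine.children and engine.children[label]:
            post = down[label] * node_out[label]
        else:
            row = aln.matrix[aln.taxa.index(label)]
            states[label] = row.copy()
            continue
        post = post + 1e-15 * order_pi[None, :]
        best = np.argmax(post, axis=1).astype(np.int16)
        states[label] = best[inverse]
    return states


def parsimony_ancestral(aln: CodonAlignment, tree: TimeTree) -> dict[str, np.ndarray]:
    """Unit-cost (Fitch-style) parsimony ancestral codons via Sankoff
    dynamic programming on the unrooted tree; missing tips are wildcards.

    A cheap alternative to the marginal reconstruction for the counting
    estimator.  Ties are broken toward the parent's state, then the
    lowest codon index.
    """
    root, parent, children, order, _ = _unrooted_edges(tree)
    cols = np.ascontiguousarray(aln.matrix.T)
    patterns, inverse = np.unique(cols, axis=0, return_inverse=True)
    n_pat = patterns.shape[0]
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    big = np.int32(10 ** 6)
    cost: dict[str, np.ndarray] = {}
    for label in reversed(order):
        kids = children.get(label, [])
        if label in taxon_row:
            states = patterns[:, taxon_row[label]]
            c = np.zeros((n_pat, 61), dtype=np.int32)
            obs = states >= 0
            c[obs, :] = big
            c[np.flatnonzero(obs), states[obs]] = 0
        else:
            c = np.zeros((n_pat, 61), dtype=np.int32)
        for k in kids:
            ck = cost[k]
            # unit-cost transition: stay (ck) or switch (min + 1)
            c = c + np.minimum(ck, ck.min(axis=1, keepdims=True) + 1)
        cost[label] = c

    chosen: dict[str, np.ndarray] = {}
    rows = np.arange(n_pat)
    for label in order:
        c = cost[label]
        if label == root:
            pick = np.argmin(c, axis=1).astype(np.int16)
        else:
            p = chosen[parent[label]]
            switch = c.min(axis=1) + 1
            stay = c[rows, p]
            pick = np.where(stay <= switch, p,
                            np.argmin(c, axis=1)).astype(np.int16)
        chosen[label] = pick
    out: dict[str, np.ndarray] = {}
    for label in order:
        if label in taxon_row:
            out[label] = aln.matrix[taxon_row[label]].copy()
        else:
            out[label] = chosen[label][inverse]
    return out


_PATH_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def _path_counts(i: int, j: int) -> tuple[float, float]:
    key = (min(i, j), max(i, j))
    hit = _PATH_CACHE.get(key)
    if hit is None:
        hit = C.shortest_paths_counts(C.SENSE_CODONS[key[0]], C.SENSE_CODONS[key[1]])
        _PATH_CACHE[key] = hit
    return hit


def counting_dnds(aln: CodonAlignment, tree: TimeTree,
                  ancestral: dict[str, np.ndarray], kappa: float = 2.0
                  ) -> dict[str, BranchEstimate]:
    """Modified Nei-Gojobori counting between parent and child codons.

    Site counts are kappa-weighted mutational opportunities averaged
    over the branch's two endpoint sequences; differences are averaged
    over minimal mutational pathways.  N + S = 3 x (codons compared).
    """
    root, parent, children, order, merged = _unrooted_edges(tree)
    site_s = np.array([C.site_counts(c, kappa)[0] for c in C.SENSE_CODONS])
    out = {}
    for label in order:
        if label == root:
            continue
        a = ancestral[parent[label]]
        b = ancestral[label]
        ok = (a >= 0) & (b >= 0)
        s_sites = float((site_s[a[ok]].sum() + site_s[b[ok]].sum()) / 2)
        n_sites = 3.0 * int(ok.sum()) - s_sites
        sd = nd = 0.0
        diff = ok & (a != b)
        for i, j in zip(a[diff], b[diff]):
            s, n = _path_counts(int(i), int(j))
            sd += s
            nd += n
        ds = sd / s_sites if s_sites > 0 else math.nan
        dn = nd / n_sites if n_sites > 0 else math.nan
        if sd == 0.0 or nd == 0.0:
            omega = math.nan if sd == 0.0 else 0.0
            inexact = True
        else:
            omega = dn / ds
            inexact = False
        out[label] = BranchEstimate(
            branch=label, t=(sd + nd) / max(1, int(ok.sum())), omega=omega,
            dn=dn, ds=ds, n_sites=n_sites, s_sites=s_sites,
            substitution_count=sd + nd, inexact=inexact,
        )
    return out


def filter_branches(estimates: dict[str, BranchEstimate],
                    min_subs: float = 5.0) -> list[str]:
    """Branches retained for correlation analyses: substitution count of
    at least ``min_subs`` (the short-branch guard against inexact
    dN/dS)."""
    return sorted(b for b, e in estimates.items()
                  if e.substitution_count >= min_subs)
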