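"""Branch-level statistics: lesion rates, count summaries, and the
correlation/regression battery.

Branches (not taxa) are the statistical unit; tables are keyed by the
canonical branch id (child-node label).  Spearman's rho uses average
ranks for ties and a two-tailed t-approximation for the p-value; the
Anderson-Darling normality test uses the case-3 statistic (mean and
variance estimated) with the standard small-sample correction and
published significance approximation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import LesionRecord
from .parsimony import OriginAssignment, classify_origin, map_lesion
from .timetree import TimeTree

__all__ = [
    "mutations_per_myr",
    "map_all_lesions",
    "count_summary",
    "CountSummary",
    "spearman",
    "ols_regress",
    "anderson_darling",
    "RegressionResult",
]

#: Families with prismatic / HSB enamel (Werth categories 4-5).
HIGH_ENAMEL_FAMILIES = ("Delphinidae", "Iniidae", "Pontoporiidae", "Platanistidae")
#: Families with degenerative enamel phenotypes (Werth categories 1-3).
LOW_ENAMEL_FAMILIES = ("Monodontidae", "Phocoenidae", "Ziphiidae",
                       "Kogiidae", "Physeteridae")


def map_all_lesions(records: list[LesionRecord], tree: TimeTree,
                    method: str = "DELTRAN"
                    ) -> list[tuple[LesionRecord, OriginAssignment]]:
    """Map every catalog record onto the tree; one origin per record.

    A record's bearers are its expanded taxon set.  Every other sampled
    taxon was screened and observed without the lesion, so non-bearers
    are marked absent; with monophyletic bearers this puts the origin on
    their stem branch under ACCTRAN and DELTRAN alike.
    """
    out = []
    tree_taxa = set(tree.taxa)
    for rec in records:
        taxa = [t for t in (rec.taxa or (rec.bearer,)) if t in tree_taxa]
        if not taxa:
            raise ValueError(f"record bearers not on tree: {rec.taxa or rec.bearer}")
        presence = {t: "present" for t in taxa}
        presence.update({t: "absent" for t in tree_taxa - set(taxa)})
        origins = map_lesion(tree, presence, method=method)
        if len(origins) != 1:
            raise ValueError(
                f"{rec.gene} lesion of {rec.bearer}: bearers not monophyletic "
                f"({len(origins)} origins)"
            )
        out.append((rec, origins[0]))
    return out


def mutations_per_myr(origins: Mapping[str, list[LesionRecord]],
                      tree: TimeTree) -> dict[str, float]:
    """Weighted lesion count per branch divided by branch duration (MYR).

    Every branch of the tree is reported; branches with no lesion get 0.
    """
    rates = {}
    for branch in tree.branches():
        recs = origins.get(branch, [])
        w = sum(r.weight for r in recs)
        dur = tree.duration(branch)
        if dur <= 0 and w > 0:
            raise ValueError(f"zero-duration branch {branch} carries a lesion")
        rates[branch] = w / dur if dur > 0 else 0.0
    return rates


@dataclass
class CountSummary:
    total_events: int
    weighted_total: float
    per_gene: dict[str, int]
    synapomorphic: int
    autapomorphic: int
    per_family_events: dict[str, int]
    taxa_with_lesion: dict[str, int]     # family -> number of taxa with >=1 lesion
    family_sizes: dict[str, int]
    high_enamel_events: int
    low_enamel_events: int
    low_enamel_synapomorphic: int
    low_enamel_autapomorphic: int

    def as_dict(self) -> dict:
        return {
            "total_events": self.total_events,
            "weighted_total": self.weighted_total,
            "per_gene": dict(sorted(self.per_gene.items())),
            "synapomorphic": self.synapomorphic,
            "autapomorphic": self.autapomorphic,
            "per_family_events": dict(sorted(self.per_family_events.items())),
            "taxa_with_lesion": dict(sorted(self.taxa_with_lesion.items())),
            "family_sizes": dict(sorted(self.family_sizes.items())),
            "high_enamel_events": self.high_enamel_events,
            "low_enamel_events": self.low_enamel_events,
            "low_enamel_synapomorphic": self.low_enamel_synapomorphic,
            "low_enamel_autapomorphic": self.low_enamel_autapomorphic,
        }


def count_summary(records: list[LesionRecord], tree: TimeTree,
                  taxon_table: pd.DataFrame, method: str = "DELTRAN"
                  ) -> CountSummary:
    """Headline tallies of the lesion catalog after parsimony mapping."""
    family_of = dict(zip(taxon_table.taxon, taxon_table.family))
    mapped = map_all_lesions(records, tree, method=method)
    per_gene = Counter(rec.gene for rec, _ in mapped)
    syn = sum(1 for _, o in mapped if classify_origin(o, tree) == "synapomorphic")
    per_family = Counter()
    low_syn = low_auto = 0
    taxa_hit: dict[str, set] = {}
    for rec, origin in mapped:
        fams = {family_of[t] for t in origin.bearers if t in family_of}
        for f in fams:
            per_family[f] += 1
        for t in origin.bearers:
            f = family_of.get(t)
            if f:
                taxa_hit.setdefault(f, set()).add(t)
        if fams & set(LOW_ENAMEL_FAMILIES):
            if classify_origin(origin, tree) == "synapomorphic":
                low_syn += 1
            else:
                low_auto += 1
    high = sum(per_family.get(f, 0) for f in HIGH_ENAMEL_FAMILIES)
    low = low_syn + low_auto
    fam_sizes = taxon_table.groupby("family").size().to_dict()
    return CountSummary(
        total_events=len(mapped),
        weighted_total=sum(rec.weight for rec, _ in mapped),
        per_gene=dict(per_gene),
        synapomorphic=syn,
        autapomorphic=len(mapped) - syn,
        per_family_events=dict(per_family),
        taxa_with_lesion={f: len(s) for f, s in taxa_hit.items()},
        family_sizes={str(k): int(v) for k, v in fam_sizes.items()},
        high_enamel_events=high,
        low_enamel_events=low,
        low_enamel_synapomorphic=low_syn,
        low_enamel_autapomorphic=low_auto,
    )


# -- correlation & regression -------------------------------------------


def spearman(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed t-approximation p.

    Ties get average ranks.  Constant input has no defined rank
    correlation and raises.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    residuals: np.ndarray
    n: int
    excluded: int = 0


def ols_regress(x: Iterable[float], y: Iterable[float],
                log_x: bool = False) -> RegressionResult:
    """Least-squares fit of y on x with a two-tailed slope test.

    With ``log_x`` the predictor is log-transformed and non-positive
    values are excluded (their count is reported) — the log of zero is
    not defined, so zero-rate or zero-omega branches drop out.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    excluded = 0
    if log_x:
        keep = x > 0
        excluded = int((~keep).sum())
        x, y = np.log(x[keep]), y[keep]
    if x.size < 3:
        raise ValueError("need n >= 3 after exclusions")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    fit = sps.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2), p=float(fit.pvalue),
        residuals=residuals, n=int(x.size), excluded=excluded,
    )


def anderson_darling(residuals: Iterable[float]) -> tuple[float, float]:
    """Anderson-Darling normality test (mean/variance estimated).

    Returns the uncorrected A-squared statistic and a p-value from the
    small-sample-corrected statistic A* = A2 (1 + 0.75/n + 2.25/n2)
    using the standard piecewise significance approximation.
    """
    x = np.sort(np.asarray(list(residuals), dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("Anderson-Darling needs n >= 8")
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    cdf = np.clip(cdf, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1]))))
    a = a2 * (1 + 0.75 / n + 2.25 / n ** 2)
    if a >= 0.6:
        p = math.exp(1.2937 - 5.709 * a + 0.0186 * a ** 2)
    elif a >= 0.34:
        p = math.exp(0.9177 - 4.279 * a - 1.38 * a ** 2)
    elif a >= 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a - 59.938 * a ** 2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a - 223.73 * a ** 2)
    return a2, float(min(max(p, 0.0), 1.0))
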