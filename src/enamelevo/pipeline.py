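"""File-based orchestration of the analysis stages.

Every stage reads and writes plain-text artifacts inside one run
directory, so a full analysis is reproducible from a config and a seed:

    make_synthetic -> run_scan -> run_map -> run_selection -> run_stats

``run_all`` chains the stages and writes ``report.json`` with a config
hash and per-stage record counts.  ``fixture_report`` computes the
headline catalog tallies from the shipped reference tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .model import AlleleEvidence, EnamelScoreTable, LesionRecord
from .notation import format_lesion_notation
from .parsimony import branch_scores, classify_origin, sankoff_ordered
from .scan import evidence_site, scan_gene, validate_allelic
from .selection import (
    CodonAlignment,
    counting_dnds,
    filter_branches,
    fit_free_ratio,
    marginal_ancestral,
    parsimony_ancestral,
    recode_for_selection,
)
from .simulate import SimulationConfig, simulate_all
from .stats import (
    anderson_darling,
    count_summary,
    map_all_lesions,
    mutations_per_myr,
    ols_regress,
    spearman,
)
from .timetree import TimeTree

__all__ = [
    "make_synthetic", "run_scan", "run_map", "run_selection", "run_stats",
    "run_all", "fixture_report", "load_run_config",
]


def _config_from(obj) -> SimulationConfig:
    if isinstance(obj, SimulationConfig):
        return obj
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            obj = json.load(fh)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    clean = {k: v for k, v in obj.items() if k in known}
    for key in ("gene_codons", "genes"):
        if key in clean and isinstance(clean[key], list):
            clean[key] = tuple(clean[key])
    return SimulationConfig(**clean)


def load_run_config(run_dir) -> SimulationConfig:
    return _config_from(Path(run_dir) / "config.json")


def make_synthetic(config, out_dir) -> Path:
    """Generate a complete synthetic input set under ``out_dir``."""
    config = _config_from(config)
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    res = simulate_all(config)
    for gene, aln in res.alignments.items():
        eio.write_alignment(aln, out / f"{gene}.fasta")
    eio.write_gene_models(res.models, out / "gene_models.tsv")
    res.tree.write(out / "tree.nwk")
    eio.write_enamel_scores(res.enamel, out / "enamel_scores.tsv")
    (out / "references.txt").write_text("\n".join(res.references) + "\n")
    rows = [
        {"gene": g, "taxon": t, "evidence": tag}
        for g, m in sorted(res.evidence_flags.items()) for t, tag in sorted(m.items())
    ]
    pd.DataFrame(rows, columns=["gene", "taxon", "evidence"]).to_csv(
        out / "evidence_flags.tsv", sep="\t", index=False)
    ev_rows = [
        {"site": site, "lesion_allele": e.lesion_allele,
         "ancestral_allele": e.ancestral_allele,
         "lesion_count": e.counts[e.lesion_allele],
         "ancestral_count": e.counts[e.ancestral_allele]}
        for site, e in sorted(res.allele_evidence.items())
    ]
    pd.DataFrame(ev_rows, columns=["site", "lesion_allele", "ancestral_allele",
                                   "lesion_count", "ancestral_count"]).to_csv(
        out / "allele_evidence.tsv", sep="\t", index=False)
    eio.write_lesion_tsv(res.injection_log, out / "truth" / "injection_log.tsv")
    pd.DataFrame(sorted(res.regimes.items()), columns=["branch", "regime"]).to_csv(
        out / "truth" / "regimes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(b, s, n) for b, (s, n) in sorted(res.true_events.items())],
        columns=["branch", "syn_events", "nonsyn_events"],
    ).to_csv(out / "truth" / "true_events.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    return out


def _load_run(run_dir):
    run = Path(run_dir)
    models = eio.read_gene_models(run / "gene_models.tsv")
    tree = eio.read_timetree(run / "tree.nwk")
    references = tuple((run / "references.txt").read_text().split())
    taxa = tree.taxa
    alignments = {}
    for gene, model in models.items():
        alignments[gene] = eio.read_alignment(run / f"{gene}.fasta", model,
                                              expected_taxa=taxa)
    flags: dict[str, dict[str, str]] = {g: {} for g in models}
    fl = run / "evidence_flags.tsv"
    if fl.exists():
        df = pd.read_csv(fl, sep="\t")
        for r in df.itertuples():
            flags[str(r.gene)][str(r.taxon)] = str(r.evidence)
    evidence: dict[str, AlleleEvidence] = {}
    ev = run / "allele_evidence.tsv"
    if ev.exists():
        df = pd.read_csv(ev, sep="\t")
        for r in df.itertuples():
            evidence[str(r.site)] = AlleleEvidence(
                site=str(r.site),
                counts={str(r.lesion_allele): int(r.lesion_count),
                        str(r.ancestral_allele): int(r.ancestral_count)},
                lesion_allele=str(r.lesion_allele),
                ancestral_allele=str(r.ancestral_allele),
            )
    return alignments, models, tree, references, flags, evidence


def run_scan(run_dir) -> list[LesionRecord]:
    """Detect lesions in every gene of a run directory; writes
    ``lesions.tsv`` and a catalog-notation ``lesions.txt`` report."""
    run = Path(run_dir)
    alignments, models, tree, references, flags, evidence = _load_run(run)
    records: list[LesionRecord] = []
    for gene in sorted(alignments):
        recs = scan_gene(alignments[gene], models[gene], references,
                         evidence_flags=flags.get(gene))
        for rec in recs:
            ev = evidence.get(evidence_site(rec))
            records.append(validate_allelic(rec, ev) if ev is not None else rec)
    eio.write_lesion_tsv(records, run / "lesions.tsv")
    by_bearer: dict[str, list[LesionRecord]] = {}
    for rec in records:
        if not rec.noncanonical:
            by_bearer.setdefault(rec.bearer, []).append(rec)
    lines = [f"{b}\t{format_lesion_notation(rs)}" for b, rs in sorted(by_bearer.items())]
    (run / "lesions.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    return records


def run_map(run_dir, method: str = "DELTRAN") -> pd.DataFrame:
    """Map detected lesions onto the tree; writes ``origins.tsv`` and the
    per-branch rate table ``branch_rates.tsv``."""
    run = Path(run_dir)
    tree = eio.read_timetree(run / "tree.nwk")
    records = [r for r in eio.read_lesion_tsv(run / "lesions.tsv")
               if not r.noncanonical]
    mapped = map_all_lesions(records, tree, method=method)
    rows = []
    per_branch: dict[str, list[LesionRecord]] = {}
    for rec, origin in mapped:
        per_branch.setdefault(origin.branch, []).append(rec)
        rows.append({
            "branch": origin.branch, "gene": rec.gene, "class": rec.kind.name,
            "bearer": rec.bearer, "weight": rec.weight,
            "status": classify_origin(origin, tree),
        })
    origins = pd.DataFrame(rows, columns=["branch", "gene", "class", "bearer",
                                          "weight", "status"])
    origins.to_csv(run / "origins.tsv", sep="\t", index=False)
    rates = mutations_per_myr(per_branch, tree)
    pd.DataFrame(
        [(b, tree.duration(b),
          sum(r.weight for r in per_branch.get(b, [])), rates[b])
         for b in tree.branches()],
        columns=["branch", "duration_myr", "lesion_weight", "mutations_per_myr"],
    ).to_csv(run / "branch_rates.tsv", sep="\t", index=False)
    return origins


def run_selection(run_dir, estimator: str = "ml", freq_model: str = "CF1",
                  max_sweeps: int = 200) -> pd.DataFrame:
    """Per-branch dN/dS on the concatenation; writes ``branch_dnds.tsv``.

    ``estimator`` "ml" runs the free-ratio fit; "counting" uses Fitch
    ancestral codons with Nei-Gojobori pathway counting (fast screen).
    """
    run = Path(run_dir)
    alignments, models, tree, references, _, _ = _load_run(run)
    caln = recode_for_selection(
        {g: (alignments[g], models[g]) for g in alignments}, references,
        taxa=tree.taxa,
    )
    if estimator == "ml":
        fit = fit_free_ratio(caln, tree, freq_model=freq_model, max_sweeps=max_sweeps)
        estimates = fit.estimates
        meta = {"estimator": "ml", "lnl": fit.lnl, "kappa": fit.kappa,
                "freq_model": fit.freq_model, "converged": fit.converged,
                "sweeps": fit.sweeps}
    elif estimator == "counting":
        anc = parsimony_ancestral(caln, tree)
        estimates = counting_dnds(caln, tree, anc)
        meta = {"estimator": "counting"}
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    retained = set(filter_branches(estimates))
    df = pd.DataFrame(
        [{
            "branch": b, "t": e.t, "omega": e.omega, "dn": e.dn, "ds": e.ds,
            "n_sites": e.n_sites, "s_sites": e.s_sites,
            "substitution_count": e.substitution_count,
            "inexact": e.inexact, "retained": b in retained,
        } for b, e in sorted(estimates.items())]
    )
    df.to_csv(run / "branch_dnds.tsv", sep="\t", index=False)
    with open(run / "selection_model.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return df


def run_stats(run_dir, resolution: str = "DELTRAN") -> dict:
    """Merge per-branch tables and run the correlation battery; writes
    ``branch_table.tsv`` and ``stats.json``."""
    run = Path(run_dir)
    tree = eio.read_timetree(run / "tree.nwk")
    enamel = eio.read_enamel_scores(run / "enamel_scores.tsv")
    rec = sankoff_ordered(tree, enamel, resolution=resolution)
    scores = branch_scores(tree, rec)
    rates = pd.read_csv(run / "branch_rates.tsv", sep="\t").set_index("branch")
    table = pd.DataFrame({
        "branch": list(scores),
        "enamel_branch_score": [scores[b] for b in scores],
    }).set_index("branch")
    table = table.join(rates, how="left")
    dnds_path = run / "branch_dnds.tsv"
    if dnds_path.exists():
        dnds = pd.read_csv(dnds_path, sep="\t").set_index("branch")
        table = table.join(dnds[["omega", "dn", "ds", "substitution_count",
                                 "inexact", "retained"]], how="left")
    table.reset_index().to_csv(run / "branch_table.tsv", sep="\t", index=False)

    out: dict = {"resolution": resolution, "n_branches": int(len(table))}
    rho, p = spearman(table.mutations_per_myr, table.enamel_branch_score)
    reg = ols_regress(table.mutations_per_myr, table.enamel_branch_score)
    out["rate_vs_score"] = {"rho": rho, "p": p, "slope": reg.slope,
                            "intercept": reg.intercept, "r2": reg.r2,
                            "p_slope": reg.p}
    if reg.residuals.size >= 8:
        a2, ap = anderson_darling(reg.residuals)
        out["rate_vs_score"]["anderson_darling"] = {"a2": a2, "p": ap}
    if "omega" in table:
        sub = table[table.retained == True]  # noqa: E712 (pandas mask)
        sub = sub[np.isfinite(sub.omega)]
        if len(sub) >= 3 and sub.omega.std() > 0:
            rho, p = spearman(sub.omega, sub.enamel_branch_score)
            reg = ols_regress(sub.omega, sub.enamel_branch_score)
            out["omega_vs_score"] = {"rho": rho, "p": p, "slope": reg.slope,
                                     "intercept": reg.intercept, "r2": reg.r2,
                                     "p_slope": reg.p,
                                     "n_retained": int(len(sub))}
            if reg.residuals.size >= 8:
                a2, ap = anderson_darling(reg.residuals)
                out["omega_vs_score"]["anderson_darling"] = {"a2": a2, "p": ap}
            pos = sub[sub.omega > 0]
            if len(pos) >= 3:
                lreg = ols_regress(pos.omega, pos.enamel_branch_score, log_x=True)
                out["log_omega_vs_score"] = {
                    "slope": lreg.slope, "r2": lreg.r2, "p_slope": lreg.p,
                    "n": lreg.n, "excluded_zeros": int(len(sub) - len(pos)),
                }
    with open(run / "stats.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


def run_all(config, out_dir, estimator: str = "ml",
            method: str = "DELTRAN") -> dict:
    """Synthesize inputs and run every stage; returns the report dict."""
    config = _config_from(config)
    run = make_synthetic(config, out_dir)
    records = run_scan(run)
    origins = run_map(run, method=method)
    dnds = run_selection(run, estimator=estimator)
    statsd = run_stats(run, resolution=method)
    cfg_text = json.dumps(dataclasses.asdict(config), sort_keys=True)
    report = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {
            "scan": {"records": len(records)},
            "map": {"origins": int(len(origins))},
            "selection": {"branches": int(len(dnds))},
        },
        "stats": statsd,
    }
    with open(run / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def plot_correlations(run_dir) -> list[Path]:
    """Scatter plots of enamel branch score against the molecular
    measures; written next to ``branch_table.tsv``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    table = pd.read_csv(run / "branch_table.tsv", sep="\t")
    written = []
    panels = [("mutations_per_myr", "inactivating mutations / MYR")]
    if "omega" in table:
        panels.append(("omega", "dN/dS"))
    for col, label in panels:
        sub = table.dropna(subset=[col, "enamel_branch_score"])
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(sub[col], sub.enamel_branch_score, s=18, alpha=0.8)
        ax.set_xlabel(label)
        ax.set_ylabel("branch enamel complexity")
        fig.tight_layout()
        path = run / f"scatter_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def fixture_report(method: str = "DELTRAN") -> dict:
    """Headline tallies of the shipped lesion catalog on the shipped
    species tree (the published-catalog reproduction)."""
    tree = eio.load_species_tree(93)
    records = eio.load_lesion_catalog()
    taxa = eio.load_taxon_table()
    summary = count_summary(records, tree, taxa, method=method)
    return summary.as_dict()
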