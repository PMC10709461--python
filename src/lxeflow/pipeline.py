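"""End-to-end pipeline orchestration with reproducibility metadata.

Stages: simulate -> stats -> sfs -> fit -> compare -> report.  A single JSON
config governs all stages; each stage writes its outputs plus a manifest
entry (config hash, seeds, input digests, timing, warnings).  A stage is
skipped on rerun when its outputs exist and the config hash is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import expression_divergence, pairwise_wilcoxon_letters
from .demography import (
    MODELS,
    bootstrap_ci,
    fit_model_chain,
    lrt,
    model_selection_table,
)
from .io import (
    read_expression,
    read_gene_alignments,
    read_gene_categories,
    write_expression,
    write_gene_alignments,
    write_gene_categories,
)
from .sfs import JointSFS, bootstrap_resample_sfs, build_joint_sfs
from .simulate import SimConfig, simulate_dataset
from .sites import classify_codon_sites
from .stats import DEFAULT_CLASS_SETS, stats_table

__all__ = ["run_pipeline", "report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "pipeline_out",
    "simulate": {"genes_per_category": {"freqA": 120, "rareA": 120, "freqX": 60, "rareX": 60},
                 "gene_length_codons": 200},
    "sfs": {"n1": 20, "n2": 20, "fold": True},
    "fit": {
        "categories": ["rare", "freq"],
        "models": ["IM2", "IM2_2M"],
        "n_reps": 600,
        "stage_runs": [4, 8],
        "maxiter": 120,
        "bootstrap": 0,
    },
    "compare": {"alpha": 0.05, "expression_alpha": 1e-4},
}


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class _Manifest:
    def __init__(self, outdir: Path, cfg: dict):
        self.path = outdir / "manifest.json"
        self.data = {
            "version": __version__,
            "config_hash": _hash_config(cfg),
            "config": cfg,
            "stages": {},
        }
        if self.path.exists():
            try:
                prev = json.loads(self.path.read_text())
                if prev.get("config_hash") == self.data["config_hash"]:
                    self.data["stages"] = prev.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass

    def done(self, stage: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("status") != "ok":
            return False
        for f, dig in rec.get("outputs", {}).items():
            p = Path(f)
            if not p.exists() or _digest(p) != dig:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], elapsed: float, warns: list[str],
               status: str = "ok") -> None:
        self.data["stages"][stage] = {
            "status": status,
            "elapsed_s": round(elapsed, 3),
            "outputs": {str(f): _digest(f) for f in outputs if f.exists()},
            "warnings": warns,
        }
        self.write()

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1, default=str))


def run_pipeline(config: dict | None = None) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Stage outputs land under ``config['outdir']``; a failed stage halts
    downstream stages but the manifest (with the failure recorded) is still
    written.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg)
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("stats", _stage_stats),
        ("sfs", _stage_sfs),
        ("fit", _stage_fit),
        ("compare", _stage_compare),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                outputs = fn(cfg, outdir, state, manifest)
            except Exception as exc:  # record, halt downstream
                manifest.record(name, [], time.perf_counter() - t0,
                                [str(w.message) for w in wlist], status=f"failed: {exc}")
                raise
        manifest.record(name, outputs, time.perf_counter() - t0,
                        [str(w.message) for w in wlist])
    return manifest.data


def _stage_simulate(cfg, outdir, state, manifest):
    sim_cfg = SimConfig(master_seed=cfg["seed"], **cfg["simulate"])
    files = [outdir / "alignments.fasta", outdir / "categories.tsv",
             outdir / "expression.tsv", outdir / "truth.json"]
    ds = simulate_dataset(sim_cfg)
    state["dataset"] = ds
    if not manifest.done("simulate", files):
        write_gene_alignments(ds.alignments, files[0])
        write_gene_categories(ds.categories, files[1])
        write_expression(ds.expression, files[2])
        files[3].write_text(json.dumps(
            {k: v for k, v in ds.truth.items() if k != "genes"}, indent=1, default=str))
    return files


def _stage_stats(cfg, outdir, state, manifest):
    ds = state["dataset"]
    out = outdir / "stats.tsv"
    masks = {a.gene_id: classify_codon_sites(a) for a in ds.alignments}
    state["masks"] = masks
    table = stats_table(ds.alignments, masks, ds.categories)
    state["stats"] = table
    table.to_csv(out, sep="\t", index=False)
    return [out]


def _stage_sfs(cfg, outdir, state, manifest):
    ds = state["dataset"]
    n1, n2, fold = cfg["sfs"]["n1"], cfg["sfs"]["n2"], cfg["sfs"]["fold"]
    cat_of = dict(zip(ds.categories["gene_id"], ds.categories["category"]))
    groups = {
        "rare": [a for a in ds.alignments if cat_of[a.gene_id].startswith("rare")],
        "freq": [a for a in ds.alignments if cat_of[a.gene_id].startswith("freq")],
        **{c: [a for a in ds.alignments if cat_of[a.gene_id] == c]
           for c in sorted(set(cat_of.values()))},
    }
    state["sfs_groups"] = {}
    state["aln_groups"] = groups
    files = []
    for name, alns in groups.items():
        if not alns:
            continue
        spec = build_joint_sfs(alns, n1, n2, fold=fold, ancestral=ds.ancestral)
        state["sfs_groups"][name] = spec
        f = outdir / f"sfs_{name}.txt"
        spec.write(f)
        files.append(f)
    return files


def _stage_fit(cfg, outdir, state, manifest):
    fcfg = cfg["fit"]
    files = []
    state["fits"] = {}
    for cat in fcfg["categories"]:
        obs = state["sfs_groups"][cat]
        fits = fit_model_chain(
            obs, fcfg["models"], seed=cfg["seed"] + 17,
            n_reps=fcfg["n_reps"], stage_runs=tuple(fcfg["stage_runs"]),
            maxiter=fcfg["maxiter"],
        )
        if fcfg.get("bootstrap", 0) > 1:
            best_id = min(fits.values(), key=lambda f: f.aic).model_id
            boots = bootstrap_resample_sfs(
                state["aln_groups"][cat], fcfg["bootstrap"], cfg["seed"] + 23,
                obs.n1, obs.n2, fold=obs.folded,
            )
            bootstrap_ci(best_id, fits[best_id], boots, seed=cfg["seed"] + 29,
                         n_reps=fcfg["n_reps"] // 2)
        state["fits"][cat] = fits
        tab = model_selection_table(list(fits.values()))
        f = outdir / f"fit_{cat}.tsv"
        tab.to_csv(f, sep="\t", index=False)
        files.append(f)
        fjson = outdir / f"fit_{cat}.json"
        fjson.write_text(json.dumps(
            {m: {"params": fit.params.values, "loglik": fit.loglik, "theta": fit.theta,
                 "aic": fit.aic, "ci": fit.ci, "provenance": fit.provenance}
             for m, fit in fits.items()}, indent=1, default=str))
        files.append(fjson)
    return files


def _stage_compare(cfg, outdir, state, manifest):
    ds = state["dataset"]
    stats = state["stats"]
    alpha = cfg["compare"]["alpha"]
    files = []
    letter_rows = []
    for statistic, classes in DEFAULT_CLASS_SETS.items():
        for cls in classes:
            sub = stats[stats["site_class"] == cls]
            for col in _stat_columns(statistic):
                groups = {}
                for cat in ("freqA", "rareA", "freqX", "rareX"):
                    v = sub.loc[sub["category"] == cat, col].dropna().to_numpy()
                    if v.size:
                        groups[cat] = v
                if len(groups) < 2:
                    continue
                res = pairwise_wilcoxon_letters(groups, alpha=alpha, statistic=f"{col}:{cls}")
                state.setdefault("comparisons", {})[f"{col}:{cls}"] = res
                for g in res.groups:
                    letter_rows.append({
                        "statistic": col, "site_class": cls, "group": g,
                        "median": res.medians[g], "letters": res.letters[g],
                        "kw_H": res.kw_H, "kw_p": res.kw_p,
                    })
    f = outdir / "comparisons.tsv"
    pd.DataFrame(letter_rows).to_csv(f, sep="\t", index=False)
    files.append(f)

    div = expression_divergence(ds.expression, ds.categories,
                                alpha=cfg["compare"]["expression_alpha"])
    state["expression_divergence"] = div
    f2 = outdir / "expression_divergence.tsv"
    div.counts.to_csv(f2, sep="\t", index_label="category")
    f3 = outdir / "expression_r2.tsv"
    div.r2.to_csv(f3, sep="\t", index_label="group")
    files += [f2, f3]
    return files


def _stat_columns(statistic: str) -> list[str]:
    if statistic in ("pi", "tajD", "zns"):
        suffix = {"pi": "pi", "tajD": "tajD", "zns": "zns"}[statistic]
        return [f"{suffix}_1", f"{suffix}_2"]
    return [statistic]


def _stage_report(cfg, outdir, state, manifest):
    return [report(state, outdir)]


def report(state: dict, outdir: Path) -> Path:
    """Summary JSON + TSV mirroring the model table, r2 grid, counts and letters."""
    summary: dict = {}
    if "fits" in state:
        summary["models"] = {}
        for cat, fits in state["fits"].items():
            tab = model_selection_table(list(fits.values()))
            rows = tab.to_dict(orient="records")
            pairs = [("IM", "IM_2M"), ("IM2", "IM2_2M")]
            lrts = {}
            for null_id, alt_id in pairs:
                if null_id in fits and alt_id in fits:
                    stat, p = lrt(fits[null_id].loglik, fits[alt_id].loglik,
                                  fits[alt_id].params.k - fits[null_id].params.k)
                    lrts[f"{null_id}_vs_{alt_id}"] = {"stat": stat, "p": p}
            summary["models"][cat] = {"table": rows, "lrt": lrts}
    if "expression_divergence" in state:
        div = state["expression_divergence"]
        summary["expression"] = {
            "counts": div.counts.to_dict(orient="index"),
            "r2": json.loads(div.r2.to_json()),
        }
    if "comparisons" in state:
        summary["letters"] = {
            key: res.letters for key, res in state["comparisons"].items()
        }
    out = outdir / "report.json"
    out.write_text(json.dumps(summary, indent=1, default=str))
    return out
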