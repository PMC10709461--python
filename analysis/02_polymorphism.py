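"""Per-gene polymorphism statistics and category comparisons.

Reads the simulated dataset from results/simulated/, classifies codon sites,
computes pi / Tajima's D / F_ST / D_xy / Z_nS per gene on the three site
classes, and compares the four gene categories with Kruskal-Wallis plus
pairwise Wilcoxon compact letters (pi and D on fourfold and first-two-codon
positions; F_ST, D_xy, Z_nS on all sites).  The ploidy-adjusted view
multiplies autosomal pi by 0.75.

Outputs: results/stats.tsv (per gene x site class), results/comparisons.tsv
(medians + letters), and a genome-track TSV for the fourfold-pi overview.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lxeflow.compare import pairwise_wilcoxon_letters
from lxeflow.io import read_gene_alignments, read_gene_categories
from lxeflow.sites import classify_codon_sites
from lxeflow.stats import DEFAULT_CLASS_SETS, adjust_autosomal_pi, genome_track, stats_table

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    cats = read_gene_categories(SIM / "categories.tsv")
    species_map = {}
    truth = json.loads((SIM / "truth.json").read_text())
    for sp in ("species1", "species2"):
        for i in range(12):
            species_map[f"{sp}_s{i}"] = sp
    alns = read_gene_alignments(SIM / "alignments.fasta", species_map)
    masks = {a.gene_id: classify_codon_sites(a) for a in alns}
    tab = stats_table(alns, masks, cats)
    tab.to_csv(OUT / "stats.tsv", sep="\t", index=False)

    rows = []
    for statistic, classes in DEFAULT_CLASS_SETS.items():
        cols = {"pi": ["pi_1", "pi_2"], "tajD": ["tajD_1", "tajD_2"],
                "zns": ["zns_1", "zns_2"], "fst": ["fst"], "dxy": ["dxy"]}[statistic]
        for cls in classes:
            sub = tab[tab.site_class == cls]
            for col in cols:
                groups = {}
                for cat in ("freqA", "rareA", "freqX", "rareX"):
                    v = sub.loc[sub.category == cat, col].dropna().to_numpy()
                    if v.size:
                        groups[cat] = v
                res = pairwise_wilcoxon_letters(groups, statistic=f"{col}:{cls}")
                for g in res.groups:
                    rows.append({"statistic": col, "site_class": cls, "group": g,
                                 "median": res.medians[g], "letters": res.letters[g],
                                 "kw_H": res.kw_H, "kw_p": res.kw_p})
    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "comparisons.tsv", sep="\t", index=False)

    track = genome_track(tab, cats, "pi_1", "fourfold")
    track.to_csv(OUT / "track_pi_fourfold.tsv", sep="\t", index=False)

    ff = tab[tab.site_class == "fourfold"]
    med = ff.groupby("category")[["pi_1", "pi_2"]].median()
    fst_med = tab[tab.site_class == "all"].groupby("category")["fst"].median()
    print("median fourfold pi per category (species1 / species2):")
    for cat, row in med.iterrows():
        adj = adjust_autosomal_pi(row.pi_1) if cat.endswith("A") else row.pi_1
        print(f"  {cat}: {row.pi_1:.4f} / {row.pi_2:.4f} (ploidy-adjusted sp1: {adj:.4f})")
    print("median F_ST (all sites):", {c: round(v, 3) for c, v in fst_med.items()})
    print(f"wrote {OUT/'stats.tsv'}, {OUT/'comparisons.tsv'}")


if __name__ == "__main__":
    main()
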