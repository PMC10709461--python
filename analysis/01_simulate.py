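"""Generate the synthetic two-species transcriptome dataset.

Emits per-gene haplotype alignments (24 haplotypes per species: 12 diploid
females each), the gene-category table (freqA/rareA/freqX/rareX) and the
FPKM expression matrix, all under the per-category demographies and mutation
scales the generator encodes (rare categories: low diversity, mostly
low-migration sites; X categories: 0.75x autosomal theta).

Scaled problem size for a desk run: 250 genes in each autosomal category and
120 in each X category, 150 codons per gene.  Run `python
analysis/01_simulate.py [seed]`; outputs land under results/simulated/.
"""

import json
import sys
from pathlib import Path

from lxeflow.io import write_expression, write_gene_alignments, write_gene_categories
from lxeflow.simulate import SimConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulated"

GENES = {"freqA": 250, "rareA": 250, "freqX": 120, "rareX": 120}
CODONS = 150


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(master_seed=seed, genes_per_category=GENES, gene_length_codons=CODONS)
    ds = simulate_dataset(cfg)
    write_gene_alignments(ds.alignments, OUT / "alignments.fasta")
    write_gene_categories(ds.categories, OUT / "categories.tsv")
    write_expression(ds.expression, OUT / "expression.tsv")
    (OUT / "truth.json").write_text(
        json.dumps({k: v for k, v in ds.truth.items() if k != "genes"}, indent=1, default=str)
    )
    n_sites = 3 * CODONS
    print(f"simulated {len(ds.alignments)} genes x {ds.alignments[0].n_rows} haplotypes "
          f"x {n_sites} sites (seed {seed}) -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
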