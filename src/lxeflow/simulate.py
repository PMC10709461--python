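"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end without any download:
two diverged dioecious plant species sampled as 12 diploid females each,
per-gene coding alignments simulated gene-by-gene under a structured
coalescent (isolation with migration, exponential post-split growth,
two-class heterogeneous migration), and FPKM expression matrices in which a
configured fraction of genes has species-shifted means.

Per-category demographic defaults are the point estimates of the best
two-class model fitted to the real transcriptome data (rare categories
carry a larger low-migration class fraction, P ~ 0.5-0.56, than the freq
categories, P ~ 0.26-0.31, and migration into species 1 exceeds the reverse
direction).  Per-site theta defaults give rare << freq diversity and set
X-linked theta to 0.75x the autosomal value (3/4 effective size of the X).
Genes are independent (free recombination between genes, none within).

Coding structure: ancestral sequences are random stop-free codons, and
mutations at first/second codon positions are thinned by a selective
constraint factor (default 0.15) relative to fourfold-degenerate third
positions, so the fourfold class is the most variable, as in real coding
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import simulate_genealogy_arrays
from .demography import ModelParams
from .io import ExpressionMatrix, HaplotypeAlignment

__all__ = ["SimConfig", "simulate_genealogy", "drop_mutations", "simulate_dataset", "default_demography"]

SPECIES = ("species1", "species2")

# Best-fit two-class IM model per gene category (point estimates from the
# study system), used as the generator's demographic truth.
_CATEGORY_DEMOGRAPHY = {
    "rareA": dict(s=0.27, N1=1.82, N2=2.48, T=4.84, MA1=0.10, MA2=0.11, MB1=2.52, MB2=0.75, P=0.55),
    "rareX": dict(s=0.29, N1=1.20, N2=1.24, T=3.85, MA1=0.04, MA2=0.13, MB1=3.13, MB2=2.88, P=0.50),
    "freqA": dict(s=0.38, N1=1.38, N2=2.36, T=0.55, MA1=0.38, MA2=0.39, MB1=7.90, MB2=0.52, P=0.31),
    "freqX": dict(s=0.65, N1=1.62, N2=1.95, T=3.77, MA1=0.15, MA2=0.18, MB1=2.50, MB2=1.26, P=0.28),
}

# per-site theta: rare << freq, X = 0.75 x autosomal
_CATEGORY_THETA = {"freqA": 0.032, "rareA": 0.011, "freqX": 0.024, "rareX": 0.00825}

# fraction of genes with species-shifted expression means
_CATEGORY_DIVERGED = {"freqA": 0.072, "rareA": 0.090, "freqX": 0.10, "rareX": 0.10}

# gene counts matching the real category sizes
_CATEGORY_GENES = {"freqA": 2009, "rareA": 1909, "freqX": 209, "rareX": 398}


def default_demography(category: str) -> ModelParams:
    return ModelParams("IM2_2M", dict(_CATEGORY_DEMOGRAPHY[category]))


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset."""

    genes_per_category: dict[str, int] = field(default_factory=lambda: dict(_CATEGORY_GENES))
    diploids_per_species: int = 12
    gene_length_codons: int = 300
    theta_per_site: dict[str, float] = field(default_factory=lambda: dict(_CATEGORY_THETA))
    demography: dict[str, ModelParams] = field(
        default_factory=lambda: {c: default_demography(c) for c in _CATEGORY_DEMOGRAPHY}
    )
    constraint_first_two: float = 0.15  # mutation thinning at codon positions 1-2
    # expression model: log-normal FPKM, species shift on the log scale
    expr_log_mean: float = 3.0
    expr_log_sd_between_genes: float = 1.0
    expr_log_sd_within: float = 0.35
    diverged_fraction: dict[str, float] = field(default_factory=lambda: dict(_CATEGORY_DIVERGED))
    expr_shift_log: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for c, f in self.diverged_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"diverged fraction for {c} outside [0, 1]")
        for c, t in self.theta_per_site.items():
            if t < 0:
                raise ValueError(f"theta for {c} must be >= 0")


def simulate_genealogy(params: ModelParams, n1: int, n2: int, rng: np.random.Generator):
    """One structured-coalescent genealogy under a (possibly mixture) model.

    For two-class models the gene is assigned to migration class A with
    probability P (whole genes, not sites, carry a class in the generator).
    Returns (edge_lengths, edge_leaf_membership, tmrca, class_label).
    """
    v = params.values
    grow = params.model_id != "split_mig"
    comps = {
        "split_mig": lambda: ("-", v["M"], v["M"]),
        "IM": lambda: ("-", v["M"], v["M"]),
        "IM2": lambda: ("-", v["M1"], v["M2"]),
        "IM_2M": lambda: (
            ("A", v["MA"], v["MA"]) if rng.random() < v["P"] else ("B", v["MB"], v["MB"])
        ),
        "IM2_2M": lambda: (
            ("A", v["MA1"], v["MA2"]) if rng.random() < v["P"] else ("B", v["MB1"], v["MB2"])
        ),
    }
    label, m1, m2 = comps[params.model_id]()
    lengths, members, tmrca = simulate_genealogy_arrays(
        n1, n2, v["N1"], v["N2"], v.get("s", 0.5), v["T"], m1, m2, grow, rng
    )
    return lengths, members, tmrca, label


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {b"TAA", b"TAG", b"TGA"}


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random stop-free coding sequence as an S1 array of length 3*n_codons."""
    out = np.empty(3 * n_codons, dtype="S1")
    for c in range(n_codons):
        while True:
            codon = _BASES[rng.integers(0, 4, size=3)]
            if codon.tobytes() not in _STOPS:
                break
        out[3 * c : 3 * c + 3] = codon
    return out


def drop_mutations(
    tree: tuple[np.ndarray, np.ndarray],
    theta_per_site: float,
    n_sites: int,
    codon_structure: bool,
    rng: np.random.Generator,
    ancestral: np.ndarray | None = None,
    constraint_first_two: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Place infinite-sites mutations on a genealogy; return (alignment, ancestral).

    `tree` is (edge lengths, edge-leaf membership) from the genealogy
    simulator.  Mutation count is Poisson(theta/2 per site x total tree
    length) summed over site weights; with `codon_structure` the weight of
    first/second codon positions is `constraint_first_two` relative to third
    positions.  Each mutated site gets exactly one mutation (site choices
    without replacement), assigned to an edge proportional to its length;
    rows below the edge carry a random derived base.
    """
    if theta_per_site < 0:
        raise ValueError("theta must be >= 0")
    lengths, members = tree
    n_rows = members.shape[1]
    if ancestral is None:
        if codon_structure:
            ancestral = _random_cds(n_sites // 3, rng)
            n_sites = ancestral.size
        else:
            ancestral = _BASES[rng.integers(0, 4, size=n_sites)]
    aln = np.tile(ancestral, (n_rows, 1))
    total_len = lengths.sum()
    if total_len == 0 or theta_per_site == 0:
        return aln, ancestral
    if codon_structure:
        weights = np.full(n_sites, constraint_first_two)
        weights[2::3] = 1.0
    else:
        weights = np.ones(n_sites)
    lam = 0.5 * theta_per_site * weights.sum() * total_len
    n_mut = rng.poisson(lam)
    # infinite sites: at most one hit per mutable site
    n_mut = min(n_mut, int(np.count_nonzero(weights)))
    if n_mut == 0:
        return aln, ancestral
    sites = rng.choice(n_sites, size=n_mut, replace=False, p=weights / weights.sum())
    edges = rng.choice(lengths.size, size=n_mut, p=lengths / total_len)
    for site, edge in zip(sites, edges):
        anc = ancestral[site]
        derived = _BASES[rng.integers(0, 3)]
        if derived == anc:
            derived = _BASES[3] if anc != _BASES[3] else _BASES[0]
        aln[members[edge], site] = derived
    return aln, ancestral


@dataclass
class SyntheticDataset:
    alignments: list[HaplotypeAlignment]
    categories: pd.DataFrame
    expression: ExpressionMatrix
    ancestral: dict[str, np.ndarray]
    truth: dict


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic dataset: alignments, category table, FPKM matrix, truth.

    Deterministic under `config.master_seed`.  Gene ids are
    ``<category>_g<index>``; haplotype sample ids ``<species>_s<index>``.
    X-linked categories use the X-specific theta (0.75x autosomal scale is
    part of the theta defaults).
    """
    rng = np.random.default_rng(config.master_seed)
    n_dip = config.diploids_per_species
    n_hap = 2 * n_dip
    samples = {sp: [f"{sp}_s{i}" for i in range(n_dip)] for sp in SPECIES}
    alignments: list[HaplotypeAlignment] = []
    ancestral: dict[str, np.ndarray] = {}
    cat_rows = []
    truth_genes: dict[str, dict] = {}
    n_sites = 3 * config.gene_length_codons

    for cat in sorted(config.genes_per_category):
        params = config.demography[cat]
        theta = config.theta_per_site[cat]
        chrom = "X" if cat.endswith("X") else "A1"
        for g in range(config.genes_per_category[cat]):
            gene = f"{cat}_g{g}"
            lengths, members, tmrca, label = simulate_genealogy(params, n_hap, n_hap, rng)
            aln_mat, anc = drop_mutations(
                (lengths, members), theta, n_sites, True, rng,
                constraint_first_two=config.constraint_first_two,
            )
            species_rows = [SPECIES[0]] * n_hap + [SPECIES[1]] * n_hap
            alignments.append(
                HaplotypeAlignment(
                    gene, aln_mat, samples[SPECIES[0]] + samples[SPECIES[1]], species_rows
                )
            )
            ancestral[gene] = anc
            cat_rows.append(
                {"gene_id": gene, "category": cat, "chromosome": chrom, "position": g * 10_000}
            )
            truth_genes[gene] = {"migration_class": label, "tmrca": tmrca}

    categories = pd.DataFrame(cat_rows)

    # expression: log-normal FPKM; a configured fraction of genes per category
    # gets a species mean shift of +/- expr_shift_log on the log scale
    gene_ids = categories["gene_id"].tolist()
    base_log = rng.normal(config.expr_log_mean, config.expr_log_sd_between_genes, size=len(gene_ids))
    diverged: dict[str, float] = {}
    cols = samples[SPECIES[0]] + samples[SPECIES[1]]
    vals = np.empty((len(gene_ids), 2 * n_dip))
    for i, (gene, cat) in enumerate(zip(gene_ids, categories["category"])):
        shift = 0.0
        if rng.random() < config.diverged_fraction[cat]:
            shift = config.expr_shift_log * (1 if rng.random() < 0.5 else -1)
        diverged[gene] = shift
        mu1, mu2 = base_log[i], base_log[i] + shift
        vals[i, :n_dip] = np.exp(rng.normal(mu1, config.expr_log_sd_within, size=n_dip))
        vals[i, n_dip:] = np.exp(rng.normal(mu2, config.expr_log_sd_within, size=n_dip))
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"), columns=cols),
        {s: sp for sp in SPECIES for s in samples[sp]},
    )

    truth = {
        "master_seed": config.master_seed,
        "demography": {c: {"model_id": p.model_id, **p.values} for c, p in config.demography.items()},
        "theta_per_site": dict(config.theta_per_site),
        "diverged_fraction": dict(config.diverged_fraction),
        "expr_shift_log": config.expr_shift_log,
        "genes": truth_genes,
        "expression_shift": diverged,
    }
    return SyntheticDataset(alignments, categories, expr, ancestral, truth)
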