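"""Per-gene polymorphism and divergence statistics.

Five statistics per gene and site class, computed on haplotype rows after
complete deletion (columns with any missing data dropped):

* pi — nucleotide diversity, the mean per-site Hamming mismatch fraction over
  all unordered pairs of rows (the unbiased n/(n-1) form).
* Tajima's D — normalized difference between the pairwise and
  segregating-sites estimators of theta, with the standard constants.
* D_xy — mean per-site mismatch fraction over all between-species row pairs.
* F_ST — 1 - mean within-species pi / D_xy (Hudson/Nei family); undefined
  when the between-species diversity is zero.
* Z_nS — mean squared allelic correlation r^2 over all pairs of biallelic
  segregating sites.

Comparisons of X-linked with autosomal diversity use a ploidy adjustment:
autosomal pi is multiplied by 0.75 (the X has 3/4 of the autosomal effective
population size in a dioecious species).

Undefined values are returned as NaN and flagged so downstream group tests
can exclude them listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HaplotypeAlignment
from .sites import SiteClassMask, complete_deletion_filter

__all__ = [
    "nucleotide_diversity",
    "tajimas_d",
    "dxy",
    "fst",
    "zns",
    "adjust_autosomal_pi",
    "per_gene_stats",
    "stats_table",
    "StatRecord",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(rows: np.ndarray) -> np.ndarray:
    """Map S1 bases to codes 0..3 (A,C,G,T); N and gaps become -1."""
    return _CODE[rows.view(np.uint8)]


def _allele_counts(codes: np.ndarray) -> np.ndarray:
    """(4, n_cols) counts of each base among non-missing rows."""
    return np.stack([(codes == i).sum(axis=0) for i in range(4)])


def _pairwise_mismatch_per_site(codes: np.ndarray) -> np.ndarray:
    """Per-column mean mismatch fraction over all unordered row pairs."""
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    counts = _allele_counts(codes)
    same_pairs = (counts * (counts - 1)).sum(axis=0) / 2
    total_pairs = n * (n - 1) / 2
    return (total_pairs - same_pairs) / total_pairs


def nucleotide_diversity(rows: np.ndarray, columns: np.ndarray | None = None) -> tuple[float, int]:
    """Per-site nucleotide diversity pi and the number of sites used."""
    codes = _encode(rows if columns is None else rows[:, columns])
    if codes.shape[1] == 0:
        return float("nan"), 0
    return float(_pairwise_mismatch_per_site(codes).mean()), codes.shape[1]


def tajimas_d(rows: np.ndarray, columns: np.ndarray | None = None) -> float:
    """Tajima's D; NaN when there are no segregating sites."""
    codes = _encode(rows if columns is None else rows[:, columns])
    n = codes.shape[0]
    if n < 2 or codes.shape[1] == 0:
        return float("nan")
    counts = _allele_counts(codes)
    seg = (counts > 0).sum(axis=0) > 1
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_total = float(_pairwise_mismatch_per_site(codes).sum())
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:  # n=2,3 can zero the variance constants
        return float("nan")
    return float((pi_total - S / a1) / denom)


def dxy(rows1: np.ndarray, rows2: np.ndarray, columns: np.ndarray | None = None) -> tuple[float, int]:
    """Mean per-site mismatch fraction over all between-species row pairs."""
    if rows1.shape[0] == 0 or rows2.shape[0] == 0:
        raise ValueError("each species needs at least one row")
    c1 = _encode(rows1 if columns is None else rows1[:, columns])
    c2 = _encode(rows2 if columns is None else rows2[:, columns])
    if c1.shape[1] == 0:
        return float("nan"), 0
    n1, n2 = c1.shape[0], c2.shape[0]
    k1 = _allele_counts(c1)
    k2 = _allele_counts(c2)
    same = (k1 * k2).sum(axis=0)
    per_site = (n1 * n2 - same) / (n1 * n2)
    return float(per_site.mean()), c1.shape[1]


def fst(rows1: np.ndarray, rows2: np.ndarray, columns: np.ndarray | None = None) -> float:
    """Hudson-style F_ST = 1 - mean within-species pi / D_xy; NaN when D_xy = 0."""
    if rows1.shape[0] < 2 or rows2.shape[0] < 2:
        raise ValueError("each species needs at least two rows")
    pi1, _ = nucleotide_diversity(rows1, columns)
    pi2, _ = nucleotide_diversity(rows2, columns)
    pib, _ = dxy(rows1, rows2, columns)
    if not np.isfinite(pib) or pib == 0.0:
        return float("nan")
    return float(1.0 - 0.5 * (pi1 + pi2) / pib)


def zns(rows: np.ndarray, columns: np.ndarray | None = None) -> float:
    """Kelly's Z_nS: mean r^2 over all pairs of biallelic segregating sites."""
    codes = _encode(rows if columns is None else rows[:, columns])
    counts = _allele_counts(codes)
    biallelic = (counts > 0).sum(axis=0) == 2
    cols = np.flatnonzero(biallelic)
    if cols.size < 2:
        return float("nan")
    sub = codes[:, cols]
    # indicator of the lexicographically-smaller allele at each site;
    # r^2 is invariant to allele relabeling
    minor = sub == sub.min(axis=0, keepdims=True)
    x = minor.astype(float)
    p = x.mean(axis=0)
    xc = x - p
    cov = xc.T @ xc / x.shape[0]
    var = p * (1 - p)
    denom = np.sqrt(np.outer(var, var))
    r2 = (cov / denom) ** 2
    iu = np.triu_indices(cols.size, k=1)
    return float(r2[iu].mean())


def adjust_autosomal_pi(pi: float) -> float:
    """Ploidy adjustment for X vs autosome comparisons: 0.75 x pi."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return 0.75 * pi


@dataclass
class StatRecord:
    """All five statistics for one gene and one site class."""

    gene_id: str
    category: str
    site_class: str
    n_sites_used: int
    pi_1: float
    pi_2: float
    tajD_1: float
    tajD_2: float
    fst: float
    dxy: float
    zns_1: float
    zns_2: float
    pi_adjusted: bool = False


# statistic -> site classes on which it enters group comparisons
DEFAULT_CLASS_SETS = {
    "pi": ("fourfold", "first_two"),
    "tajD": ("fourfold", "first_two"),
    "fst": ("all",),
    "dxy": ("all",),
    "zns": ("all",),
}


def per_gene_stats(
    aln: HaplotypeAlignment,
    masks: SiteClassMask,
    category: str,
    site_classes: tuple[str, ...] = ("all", "fourfold", "first_two"),
) -> list[StatRecord]:
    """Compute every statistic on each requested site class for one gene.

    Columns with missing data in any row are removed (complete deletion)
    before computation; the retained count is reported per class.
    """
    species = aln.species
    if len(species) != 2:
        raise ValueError(f"{aln.gene_id}: need exactly two species")
    r1 = aln.rows_of_species(species[0])
    r2 = aln.rows_of_species(species[1])
    out = []
    for cls in site_classes:
        cols = complete_deletion_filter(aln, masks.columns(cls))
        if cols.size == 0:
            out.append(
                StatRecord(aln.gene_id, category, cls, 0, *([float("nan")] * 8))
            )
            continue
        pi1, _ = nucleotide_diversity(aln.seqs[r1], cols)
        pi2, _ = nucleotide_diversity(aln.seqs[r2], cols)
        d, _ = dxy(aln.seqs[r1], aln.seqs[r2], cols)
        out.append(
            StatRecord(
                gene_id=aln.gene_id,
                category=category,
                site_class=cls,
                n_sites_used=int(cols.size),
                pi_1=pi1,
                pi_2=pi2,
                tajD_1=tajimas_d(aln.seqs[r1], cols),
                tajD_2=tajimas_d(aln.seqs[r2], cols),
                fst=fst(aln.seqs[r1], aln.seqs[r2], cols),
                dxy=d,
                zns_1=zns(aln.seqs[r1], cols),
                zns_2=zns(aln.seqs[r2], cols),
            )
        )
    return out


def stats_table(
    alns: list[HaplotypeAlignment],
    masks: dict[str, SiteClassMask],
    categories: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format table: one row per gene x site class, all statistics."""
    cat_of = dict(zip(categories["gene_id"], categories["category"]))
    records = []
    for aln in alns:
        cat = cat_of.get(aln.gene_id)
        if cat is None:
            continue
        records.extend(per_gene_stats(aln, masks[aln.gene_id], cat))
    return pd.DataFrame([r.__dict__ for r in records])


def genome_track(stats: pd.DataFrame, categories: pd.DataFrame, statistic: str, site_class: str) -> pd.DataFrame:
    """Per-gene track (chromosome, position, value) for genome-wide overview plots."""
    sub = stats[stats["site_class"] == site_class][["gene_id", statistic]]
    pos = categories.set_index("gene_id")
    cols = [c for c in ("chromosome", "position") if c in pos.columns]
    return sub.join(pos[cols], on="gene_id")
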