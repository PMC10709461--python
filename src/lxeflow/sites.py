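"""Classify alignment columns into codon-structure site classes.

Polymorphism statistics are computed on three site classes: all sites,
fourfold-degenerate sites (third codon positions whose amino acid is
unchanged by any third-position substitution — the most neutral class),
and the first two codon positions (the least neutral class).

Degeneracy is decided per column requiring unanimity among rows: a third
position is fourfold only if every row without missing data in that codon
has a first-two-base context that lies in a fourfold family of the standard
nuclear genetic code.  A polymorphic first/second position that changes the
degeneracy family therefore disqualifies the site, which avoids class flips
between species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .io import HaplotypeAlignment

__all__ = ["SiteClassMask", "classify_codon_sites", "complete_deletion_filter", "fourfold_prefixes"]

SITE_CLASSES = ("all", "fourfold", "first_two")


def fourfold_prefixes() -> frozenset[str]:
    """Two-base codon prefixes whose four completions encode one amino acid.

    Derived from Biopython's standard nuclear code table rather than written
    out by hand.
    """
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {fwd[b1 + b2 + b3] for b3 in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


_FOURFOLD_PREFIXES = fourfold_prefixes()


@dataclass
class SiteClassMask:
    """Boolean masks over alignment columns for each site class."""

    gene_id: str
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.masks) != set(SITE_CLASSES):
            raise ValueError(f"masks must cover exactly {SITE_CLASSES}")
        ff, ft = self.masks["fourfold"], self.masks["first_two"]
        if (ff & ft).any():
            raise ValueError("fourfold and first_two masks overlap")
        if not (self.masks["all"] | ~(ff | ft)).all():
            raise ValueError("'all' must contain fourfold and first_two")

    def columns(self, site_class: str) -> np.ndarray:
        return np.flatnonzero(self.masks[site_class])


def classify_codon_sites(aln: HaplotypeAlignment) -> SiteClassMask:
    """Build site-class masks from the codon structure of one gene alignment.

    Columns in incomplete terminal codons (before `frame_offset` or in a
    trailing partial codon) belong to class ``all`` only.
    """
    n_cols = aln.n_cols
    if aln.frame_offset >= n_cols:
        raise ValueError(f"{aln.gene_id}: frame_offset {aln.frame_offset} >= length {n_cols}")
    all_mask = np.ones(n_cols, dtype=bool)
    fourfold = np.zeros(n_cols, dtype=bool)
    first_two = np.zeros(n_cols, dtype=bool)

    seqs = aln.seqs
    n_codons = (n_cols - aln.frame_offset) // 3
    for c in range(n_codons):
        start = aln.frame_offset + 3 * c
        first_two[start] = True
        first_two[start + 1] = True
        codon_cols = seqs[:, start : start + 3]
        # rows with no missing data in this codon
        ok = ~np.isin(codon_cols, [b"N", b"-"]).any(axis=1)
        if not ok.any():
            continue
        prefixes = {
            (codon_cols[r, 0] + codon_cols[r, 1]).decode() for r in np.flatnonzero(ok)
        }
        if all(p in _FOURFOLD_PREFIXES for p in prefixes):
            fourfold[start + 2] = True
    return SiteClassMask(aln.gene_id, {"all": all_mask, "fourfold": fourfold, "first_two": first_two})


def complete_deletion_filter(aln: HaplotypeAlignment, columns: np.ndarray) -> np.ndarray:
    """Retain the given columns where no row carries N or a gap."""
    columns = np.asarray(columns, dtype=int)
    if columns.size == 0:
        return columns
    sub = aln.seqs[:, columns]
    keep = ~np.isin(sub, [b"N", b"-"]).any(axis=0)
    return columns[keep]


def export_masks_bed(masks: list[SiteClassMask], path) -> None:
    """Write masks as a BED-like TSV: gene, 0-based half-open interval, class."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tsite_class\n")
        for m in masks:
            for cls in ("fourfold", "first_two"):
                vec = m.masks[cls]
                # contiguous runs -> intervals
                idx = np.flatnonzero(vec)
                if idx.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(idx) > 1)
                starts = np.r_[idx[0], idx[breaks + 1]]
                ends = np.r_[idx[breaks], idx[-1]] + 1
                for s, e in zip(starts, ends):
                    fh.write(f"{m.gene_id}\t{s}\t{e}\t{cls}\n")
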