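"""Readers/writers for alignments, VCF pseudo-haplotypes, categories and FPKM.

The canonical in-memory object is :class:`HaplotypeAlignment`: a per-gene
matrix of haplotype sequences (two rows per diploid sample) with a
row -> species map.  All downstream statistics operate on it.

Coordinate conventions: alignment columns are 0-based internally; VCF
positions are 1-based per the standard; any exported interval table is
0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset(b"ACGTN-")
CATEGORIES = ("freqA", "rareA", "freqX", "rareX")


@dataclass
class HaplotypeAlignment:
    """Per-gene haplotype matrix: rows = haplotypes, columns = positions."""

    gene_id: str
    seqs: np.ndarray  # dtype 'S1', shape (n_rows, n_cols)
    sample_ids: list[str]  # one entry per diploid sample; sample i owns rows 2i, 2i+1
    species_of_row: list[str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2:
            raise ValueError(f"{self.gene_id}: sequence matrix must be 2-D")
        if self.seqs.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.gene_id}: {self.seqs.shape[0]} rows for "
                f"{len(self.sample_ids)} diploid samples (need exactly 2 per sample)"
            )
        if len(self.species_of_row) != self.seqs.shape[0]:
            raise ValueError(f"{self.gene_id}: species_of_row length mismatch")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"{self.gene_id}: frame_offset must be 0..2")
        # normalize: uppercase, unknown characters -> N
        up = np.char.upper(self.seqs)
        bad = ~np.isin(up, [bytes([c]) for c in b"ACGTN-"])
        if bad.any():
            up = up.copy()
            up[bad] = b"N"
        self.seqs = up

    @property
    def n_rows(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_cols(self) -> int:
        return self.seqs.shape[1]

    def rows_of_species(self, species: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species_of_row) if s == species])

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for s in self.species_of_row:
            if s not in out:
                out.append(s)
        return out


def _records_to_alignment(
    gene_id: str,
    named_rows: list[tuple[str, str]],
    species_map: Mapping[str, str],
    frame_offset: int = 0,
) -> HaplotypeAlignment:
    lengths = {len(seq) for _, seq in named_rows}
    if len(lengths) != 1:
        raise ValueError(f"{gene_id}: sequences differ in length ({sorted(lengths)})")
    samples: list[str] = []
    for name, _ in named_rows:
        if name not in samples:
            samples.append(name)
    counts = {s: sum(1 for n, _ in named_rows if n == s) for s in samples}
    bad = {s: c for s, c in counts.items() if c != 2}
    if bad:
        raise ValueError(f"{gene_id}: samples without exactly 2 haplotypes: {bad}")
    missing = [s for s in samples if s not in species_map]
    if missing:
        raise ValueError(f"{gene_id}: samples missing from species map: {missing}")
    order = {s: i for i, s in enumerate(samples)}
    rows: list[tuple[int, str]] = [(order[n], seq) for n, seq in named_rows]
    # stable: keep haplotype order within sample as encountered
    mat = np.empty((2 * len(samples), len(named_rows[0][1])), dtype="S1")
    slot = {s: 0 for s in samples}
    for name, seq in named_rows:
        r = 2 * order[name] + slot[name]
        slot[name] += 1
        mat[r, :] = np.frombuffer(seq.encode(), dtype="S1")
    species = [species_map[s] for s in samples for _ in range(2)]
    return HaplotypeAlignment(gene_id, mat, samples, species, frame_offset)


def read_gene_alignments(
    path: str | os.PathLike,
    species_map: Mapping[str, str],
    frame_offsets: Mapping[str, int] | None = None,
) -> list[HaplotypeAlignment]:
    """Read per-gene haplotype alignments from FASTA.

    `path` is either a directory of per-gene FASTA files (gene id = file stem,
    record ids = ``sample|hap``) or a single multi-FASTA whose record ids are
    ``gene|sample|hap``.  Lowercase bases are uppercased and characters
    outside {A,C,G,T,N,-} become N.
    """
    path = Path(path)
    per_gene: dict[str, list[tuple[str, str]]] = {}
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.suffix.lower() not in {".fa", ".fasta", ".fas"}:
                continue
            gene = f.stem
            for rec in SeqIO.parse(str(f), "fasta"):
                sample = rec.id.split("|")[0]
                per_gene.setdefault(gene, []).append((sample, str(rec.seq)))
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) < 2:
                raise ValueError(f"record id {rec.id!r} lacks 'gene|sample' structure")
            gene, sample = parts[0], parts[1]
            per_gene.setdefault(gene, []).append((sample, str(rec.seq)))
    out = []
    for gene, named in per_gene.items():
        off = frame_offsets.get(gene, 0) if frame_offsets else 0
        out.append(_records_to_alignment(gene, named, species_map, off))
    return out


def write_gene_alignments(alns: Iterable[HaplotypeAlignment], path: str | os.PathLike) -> None:
    """Write alignments to one multi-FASTA with ``gene|sample|hap`` record ids."""
    records = []
    for aln in alns:
        for i, sample in enumerate(aln.sample_ids):
            for hap in (0, 1):
                seq = aln.seqs[2 * i + hap].tobytes().decode()
                records.append(
                    SeqRecord(Seq(seq), id=f"{aln.gene_id}|{sample}|{hap + 1}", description="")
                )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def vcf_to_pseudohaplotypes(
    vcf_path: str | os.PathLike,
    reference_cds: str | os.PathLike,
    species_map: Mapping[str, str],
    phasing_rule: str = "random",
    seed: int = 0,
) -> list[HaplotypeAlignment]:
    """Convert a multi-sample VCF plus reference CDS to pseudo-haplotype alignments.

    Each VCF contig is one gene (transcriptome mapping).  Homozygous genotypes
    copy the allele to both rows; heterozygotes split per `phasing_rule`
    ('random' assigns REF/ALT to the two rows in random order under `seed`,
    'ref_alt_split' puts REF on row 1 and ALT on row 2).  Missing genotypes
    become N on both rows; sites with >2 observed alleles are set to N for
    all rows; indel records are skipped.
    """
    import pysam

    if phasing_rule not in {"random", "ref_alt_split"}:
        raise ValueError(f"unknown phasing rule {phasing_rule!r}")
    rng = np.random.default_rng(seed)
    ref = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_cds), "fasta")}

    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    missing = [s for s in samples if s not in species_map]
    if missing:
        raise ValueError(f"VCF samples missing from species map: {missing}")

    mats: dict[str, np.ndarray] = {}
    skipped_indels = 0
    masked_multiallelic = 0
    for gene, seq in ref.items():
        mat = np.tile(np.frombuffer(seq.encode(), dtype="S1"), (2 * len(samples), 1))
        mats[gene] = mat

    for rec in vf:
        gene = rec.chrom
        if gene not in mats:
            continue
        alleles = [a.upper() for a in (rec.ref, *(rec.alts or ()))]
        if any(len(a) != 1 for a in alleles):
            skipped_indels += 1
            continue
        col = rec.pos - 1  # VCF is 1-based
        mat = mats[gene]
        observed = set()
        gts = []
        for s in samples:
            gt = rec.samples[s].get("GT", (None, None))
            gts.append(gt)
            for g in gt:
                if g is not None:
                    observed.add(g)
        if len(observed) > 2:
            mat[:, col] = b"N"
            masked_multiallelic += 1
            continue
        for i, gt in enumerate(gts):
            r = 2 * i
            a, b = (gt + (None,))[:2] if len(gt) < 2 else gt[:2]
            if a is None or b is None:
                mat[r, col] = b"N"
                mat[r + 1, col] = b"N"
            elif a == b:
                mat[r, col] = alleles[a].encode()
                mat[r + 1, col] = alleles[a].encode()
            else:
                first, second = alleles[a], alleles[b]
                if phasing_rule == "random" and rng.random() < 0.5:
                    first, second = second, first
                elif phasing_rule == "ref_alt_split":
                    first, second = alleles[min(a, b)], alleles[max(a, b)]
                mat[r, col] = first.encode()
                mat[r + 1, col] = second.encode()

    species = [species_map[s] for s in samples for _ in range(2)]
    return [
        HaplotypeAlignment(gene, mats[gene], list(samples), list(species))
        for gene in ref
    ]


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with a sample -> species map."""

    values: pd.DataFrame  # index = gene_id, columns = sample_id
    species_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            r, c = np.argwhere(self.values.values < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        sp_sets: dict[str, set[str]] = {}
        for s, sp in self.species_of_sample.items():
            sp_sets.setdefault(sp, set()).add(s)
        if len(sp_sets) == 2:
            a, b = sp_sets.values()
            if a & b:
                raise ValueError("sample sets of the two species overlap")

    def samples_of(self, species: str) -> list[str]:
        return [s for s in self.values.columns if self.species_of_sample.get(s) == species]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            sp = self.species_of_sample[s]
            if sp not in seen:
                seen.append(sp)
        return seen


def read_expression(path: str | os.PathLike, species_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV (first column gene_id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing FPKM value at gene {gene!r}")
    missing = [s for s in df.columns if s not in species_map]
    if missing:
        raise ValueError(f"expression samples missing from species map: {missing}")
    return ExpressionMatrix(df.astype(float), {s: species_map[s] for s in df.columns})


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_categories(path: str | os.PathLike) -> pd.DataFrame:
    """Gene category table: columns gene_id, category, chromosome, position."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"category table needs columns {sorted(required)}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"gene {dup!r} appears more than once")
    return df


def write_gene_categories(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
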