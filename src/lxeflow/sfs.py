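"""Joint two-population site-frequency spectra.

A :class:`JointSFS` is a (n1+1) x (n2+1) matrix of (possibly fractional)
site counts; entry (i, j) holds sites whose variant allele is carried by i
haplotypes in species 1 and j in species 2.  The monomorphic corners (0, 0)
and (n1, n2) are always masked.  Sites with missing rows are projected down
to the target sample sizes by hypergeometric expectation.  Without outgroup
polarization, spectra are folded to minor-allele orientation: each cell is
combined with its point reflection through (n1/2, n2/2), the mass stored in
the representative cell on or below the folding diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import HaplotypeAlignment
from .stats import _encode

__all__ = ["JointSFS", "build_joint_sfs", "project_sfs", "bootstrap_resample_sfs"]


@dataclass
class JointSFS:
    counts: np.ndarray
    n1: int
    n2: int
    folded: bool = False
    var: np.ndarray | None = None  # per-cell MC variance for expected spectra
    total_var: float | None = None  # MC variance of the total mass

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({self.n1 + 1}, {self.n2 + 1})"
            )
        self.counts[0, 0] = 0.0
        self.counts[self.n1, self.n2] = 0.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "JointSFS":
        """Fold to minor-allele orientation; idempotent."""
        if self.folded:
            return self.copy()
        n1, n2 = self.n1, self.n2
        out = np.zeros_like(self.counts)
        var = np.zeros_like(self.counts) if self.var is not None else None
        ntot = n1 + n2
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                mi, mj = n1 - i, n2 - j
                tot = i + j
                if 2 * tot < ntot or (2 * tot == ntot and (i, j) <= (mi, mj)):
                    if (i, j) == (mi, mj):
                        out[i, j] += self.counts[i, j]  # self-conjugate, count once
                        if var is not None:
                            var[i, j] += self.var[i, j]
                    else:
                        out[i, j] += self.counts[i, j] + self.counts[mi, mj]
                        if var is not None:
                            var[i, j] += self.var[i, j] + self.var[mi, mj]
        return JointSFS(out, n1, n2, True, var, self.total_var)

    def copy(self) -> "JointSFS":
        return JointSFS(
            self.counts.copy(), self.n1, self.n2, self.folded,
            None if self.var is None else self.var.copy(), self.total_var,
        )

    def write(self, path) -> None:
        """Plain-text serialization: header 'n1 n2 folded', then the matrix."""
        with open(path, "w") as fh:
            fh.write(f"{self.n1} {self.n2} {'folded' if self.folded else 'unfolded'}\n")
            np.savetxt(fh, self.counts, fmt="%.10g")

    @classmethod
    def read(cls, path) -> "JointSFS":
        with open(path) as fh:
            n1, n2, fold_word = fh.readline().split()
            counts = np.loadtxt(fh)
        return cls(counts.reshape(int(n1) + 1, int(n2) + 1), int(n1), int(n2), fold_word == "folded")


def _projection_weights(n_from: int, target: int) -> np.ndarray:
    """weights[i, k] = P(k of target | i of n_from) under hypergeometric subsampling."""
    w = np.zeros((n_from + 1, target + 1))
    for i in range(n_from + 1):
        k = np.arange(target + 1)
        w[i] = hypergeom.pmf(k, n_from, i, target)
    return w


def build_joint_sfs(
    alns: list[HaplotypeAlignment],
    n1: int,
    n2: int,
    fold: bool = True,
    ancestral: dict[str, np.ndarray] | None = None,
) -> JointSFS:
    """Joint SFS from per-gene alignments, projected to (n1, n2) haploid sizes.

    Each biallelic segregating site contributes total mass 1, spread by
    hypergeometric projection when the site has missing rows.  Orientation is
    by ancestral state when `ancestral` provides a per-gene ancestral sequence
    (derived-allele counts), otherwise by the alphabetically first allele —
    meaningful only after folding, which is the default.  Sites with more
    than two alleles, or with fewer non-missing rows than the projection
    target in either species, are skipped.
    """
    counts = np.zeros((n1 + 1, n2 + 1))
    wcache: dict[tuple[int, int], np.ndarray] = {}
    for aln in alns:
        species = aln.species
        if len(species) != 2:
            raise ValueError(f"{aln.gene_id}: need two species")
        r1, r2 = aln.rows_of_species(species[0]), aln.rows_of_species(species[1])
        c1, c2 = _encode(aln.seqs[r1]), _encode(aln.seqs[r2])
        anc = None
        if ancestral is not None and aln.gene_id in ancestral:
            anc = _encode(ancestral[aln.gene_id].reshape(1, -1))[0]
        for col in range(aln.n_cols):
            a = c1[:, col]
            b = c2[:, col]
            obs1 = a[a >= 0]
            obs2 = b[b >= 0]
            alleles = np.union1d(obs1, obs2)
            if len(alleles) != 2:
                continue  # monomorphic or >2 alleles
            if obs1.size < n1 or obs2.size < n2:
                continue  # cannot project up
            if anc is not None and anc[col] in alleles:
                variant = alleles[alleles != anc[col]][0]
            else:
                variant = alleles[1]  # alphabetically second; folding fixes orientation
            i = int((obs1 == variant).sum())
            j = int((obs2 == variant).sum())
            key1 = (obs1.size, n1)
            key2 = (obs2.size, n2)
            if obs1.size == n1 and obs2.size == n2:
                counts[i, j] += 1.0
            else:
                if key1 not in wcache:
                    wcache[key1] = _projection_weights(obs1.size, n1)
                if key2 not in wcache:
                    wcache[key2] = _projection_weights(obs2.size, n2)
                counts += np.outer(wcache[key1][i], wcache[key2][j])
    out = JointSFS(counts, n1, n2, folded=False)
    return out.fold() if fold else out


def project_sfs(sfs: JointSFS, m1: int, m2: int) -> JointSFS:
    """Hypergeometric projection of an unfolded spectrum to smaller sizes."""
    if m1 > sfs.n1 or m2 > sfs.n2:
        raise ValueError("projection target exceeds current sample size")
    if sfs.folded:
        raise ValueError("project before folding")
    w1 = _projection_weights(sfs.n1, m1)
    w2 = _projection_weights(sfs.n2, m2)
    out = w1.T @ sfs.counts @ w2
    return JointSFS(out, m1, m2, folded=False)


def bootstrap_resample_sfs(
    alns: list[HaplotypeAlignment],
    n_boot: int,
    seed: int,
    n1: int,
    n2: int,
    fold: bool = True,
    ancestral: dict[str, np.ndarray] | None = None,
) -> list[JointSFS]:
    """Gene-level bootstrap: resample genes with replacement, rebuild the SFS.

    Per-gene spectra are computed once and summed per replicate, so the
    result is identical to rebuilding from the resampled alignment list.
    """
    if len(alns) < 2:
        raise ValueError("need at least two genes to bootstrap")
    rng = np.random.default_rng(seed)
    per_gene = [
        build_joint_sfs([aln], n1, n2, fold=False, ancestral=ancestral).counts
        for aln in alns
    ]
    out = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(alns), size=len(alns))
        total = np.zeros_like(per_gene[0])
        for g in pick:
            total += per_gene[g]
        rep = JointSFS(total, n1, n2, folded=False)
        out.append(rep.fold() if fold else rep)
    return out
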