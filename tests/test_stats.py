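"""Statistics against brute-force all-pairs oracles and an independent
Tajima's-D implementation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lxeflow.sites import classify_codon_sites
from lxeflow.stats import (
    adjust_autosomal_pi,
    dxy,
    fst,
    nucleotide_diversity,
    per_gene_stats,
    tajimas_d,
    zns,
)

from conftest import make_alignment, random_alignment


# ---------- independent oracles ----------

def pi_bruteforce(rows: np.ndarray) -> float:
    """Mean per-site mismatch fraction over all unordered row pairs."""
    n, m = rows.shape
    vals = [
        np.mean(rows[a] != rows[b]) for a, b in itertools.combinations(range(n), 2)
    ]
    return float(np.mean(vals))


def dxy_bruteforce(r1: np.ndarray, r2: np.ndarray) -> float:
    vals = [np.mean(a != b) for a in r1 for b in r2]
    return float(np.mean(vals))


def tajd_oracle(rows: np.ndarray) -> float:
    """Second implementation straight from the published constants."""
    n, m = rows.shape
    S = sum(1 for c in range(m) if len(set(rows[:, c])) > 1)
    if S == 0:
        return float("nan")
    k = np.mean(
        [np.sum(rows[a] != rows[b]) for a, b in itertools.combinations(range(n), 2)]
    )
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))


def zns_bruteforce(rows: np.ndarray) -> float:
    n, m = rows.shape
    bial = [c for c in range(m) if len(set(rows[:, c])) == 2]
    if len(bial) < 2:
        return float("nan")
    r2s = []
    for u, v in itertools.combinations(bial, 2):
        au = rows[:, u] == sorted(set(rows[:, u]))[0]
        av = rows[:, v] == sorted(set(rows[:, v]))[0]
        pa, pb = au.mean(), av.mean()
        D = (au & av).mean() - pa * pb
        r2s.append(D * D / (pa * (1 - pa) * pb * (1 - pb)))
    return float(np.mean(r2s))


# ---------- trivial fixed cases ----------

def test_pi_identical_rows_zero():
    rows = np.array([list("ACGTACGTAC")] * 4, dtype="S1")
    pi, n = nucleotide_diversity(rows)
    assert pi == 0.0 and n == 10


def test_pi_two_rows_one_difference():
    rows = np.array([list("ACGTACGTAC"), list("ACGTACGTAT")], dtype="S1")
    pi, _ = nucleotide_diversity(rows)
    assert pi == pytest.approx(0.1)


def test_pi_requires_two_rows():
    with pytest.raises(ValueError):
        nucleotide_diversity(np.array([list("ACGT")], dtype="S1"))


def test_tajd_no_segregating_sites_undefined():
    rows = np.array([list("ACGTAC")] * 5, dtype="S1")
    assert np.isnan(tajimas_d(rows))


def test_tajd_singletons_negative():
    # n=10, 5 singleton sites: excess of rare variants drives D below zero
    rows = np.array([list("AAAAA") for _ in range(10)], dtype="S1")
    for s in range(5):
        rows[s, s] = b"T"
    assert tajimas_d(rows) < 0


def test_dxy_identical_fixed_sequences():
    r = np.array([list("ACGT")] * 3, dtype="S1")
    d, _ = dxy(r, r.copy())
    assert d == 0.0


def test_dxy_half_fixed_difference():
    r1 = np.array([list("AAAA")] * 3, dtype="S1")
    r2 = np.array([list("AATT")] * 3, dtype="S1")
    d, _ = dxy(r1, r2)
    assert d == pytest.approx(0.5)


def test_fst_monomorphic_same_allele_undefined():
    r = np.array([list("AAAA")] * 4, dtype="S1")
    assert np.isnan(fst(r, r.copy()))


def test_fst_fixed_difference_is_one():
    r1 = np.array([list("AAAA")] * 4, dtype="S1")
    r2 = np.array([list("TTTT")] * 4, dtype="S1")
    assert fst(r1, r2) == pytest.approx(1.0)


def test_zns_identical_partition_complete_ld():
    rows = np.array(
        [list("AATT"), list("AATT"), list("GGCC"), list("GGCC")], dtype="S1"
    )
    assert zns(rows) == pytest.approx(1.0)


def test_zns_single_site_undefined():
    rows = np.array([list("AAA"), list("AAA"), list("TAA"), list("AAA")], dtype="S1")
    assert np.isnan(zns(rows))


@pytest.mark.parametrize("pi,expected", [(0.04, 0.03), (0.0, 0.0)])
def test_adjust_autosomal_pi(pi, expected):
    assert adjust_autosomal_pi(pi) == pytest.approx(expected)


def test_adjusted_median_scale_equivariance(rng):
    vals = rng.gamma(2.0, 0.01, size=101)
    adj = np.array([adjust_autosomal_pi(v) for v in vals])
    assert np.median(adj) == pytest.approx(0.75 * np.median(vals), abs=1e-15)


# ---------- oracle comparisons on random instances ----------

@pytest.mark.parametrize("trial", range(10))
def test_pi_dxy_match_bruteforce(trial):
    rng = np.random.default_rng(100 + trial)
    aln = random_alignment(rng, n_rows=6, n_cols=30)
    r1 = aln.seqs[:3]
    r2 = aln.seqs[3:]
    pi, _ = nucleotide_diversity(aln.seqs)
    assert pi == pytest.approx(pi_bruteforce(aln.seqs), abs=1e-12)
    d, _ = dxy(r1, r2)
    assert d == pytest.approx(dxy_bruteforce(r1, r2), abs=1e-12)


def test_statistics_match_oracles_many_random_alignments():
    """pi, D_xy, Z_nS, F_ST and Tajima's D vs brute force on 100 instances."""
    checked_zns = 0
    for trial in range(100):
        rng = np.random.default_rng(1000 + trial)
        n_rows = int(rng.integers(2, 6)) * 2
        n_cols = int(rng.integers(5, 40))
        aln = random_alignment(rng, n_rows=n_rows, n_cols=n_cols)
        rows = aln.seqs
        half = n_rows // 2
        r1, r2 = rows[:half], rows[half:]
        pi, _ = nucleotide_diversity(rows)
        assert pi == pytest.approx(pi_bruteforce(rows), abs=1e-12)
        d, _ = dxy(r1, r2)
        assert d == pytest.approx(dxy_bruteforce(r1, r2), abs=1e-12)
        td = tajimas_d(rows)
        oracle_td = tajd_oracle(rows.astype("U1"))
        if np.isnan(oracle_td):
            assert np.isnan(td)
        else:
            assert td == pytest.approx(oracle_td, abs=1e-12)
        z = zns(rows)
        oracle_z = zns_bruteforce(rows.astype("U1"))
        if np.isnan(oracle_z):
            assert np.isnan(z)
        else:
            checked_zns += 1
            assert z == pytest.approx(oracle_z, abs=1e-12)
        f = fst(r1, r2) if half >= 2 else np.nan
        if half >= 2 and not np.isnan(f):
            pw = 0.5 * (pi_bruteforce(r1) + pi_bruteforce(r2))
            assert f == pytest.approx(1 - pw / dxy_bruteforce(r1, r2), abs=1e-12)
    assert checked_zns > 20  # the r^2 branch was actually exercised


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_zns_invariant_to_row_order_and_relabeling(seed):
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng, n_rows=8, n_cols=20)
    z = zns(aln.seqs)
    perm = rng.permutation(8)
    z_perm = zns(aln.seqs[perm])
    if np.isnan(z):
        assert np.isnan(z_perm)
    else:
        assert z_perm == pytest.approx(z, abs=1e-12)
        # complement relabeling A<->T, C<->G preserves partitions
        comp = aln.seqs.copy()
        for a, b in ((b"A", b"T"), (b"C", b"G")):
            ma, mb = aln.seqs == a, aln.seqs == b
            comp[ma], comp[mb] = b, a
        assert zns(comp) == pytest.approx(z, abs=1e-12)


def test_fst_bounds_on_random_two_deme_samples():
    for trial in range(50):
        rng = np.random.default_rng(3000 + trial)
        aln = random_alignment(rng, n_rows=8, n_cols=25)
        f = fst(aln.seqs[:4], aln.seqs[4:])
        if not np.isnan(f):
            assert f <= 1.0 + 1e-12


# ---------- per-gene dispatch ----------

def test_per_gene_stats_monomorphic():
    aln = make_alignment(["ACGGCT" * 3] * 8)
    masks = classify_codon_sites(aln)
    recs = per_gene_stats(aln, masks, "freqA")
    rec = {r.site_class: r for r in recs}["all"]
    assert rec.pi_1 == 0.0
    assert np.isnan(rec.tajD_1)
    assert np.isnan(rec.zns_1)


def test_per_gene_stats_planted_snps_hand_computed():
    # 6 rows x 12 cols; two segregating sites placed in species-specific patterns
    base = "ACGGCTAAGGCT"
    rows = [list(base) for _ in range(6)]
    rows[0][2] = "T"  # singleton in species 1 at col 2
    for r in (3, 4, 5):
        rows[r][8] = "C"  # fixed difference: species2 carries C at col 8
    aln = make_alignment(["".join(r) for r in rows])
    masks = classify_codon_sites(aln)
    rec = {r.site_class: r for r in per_gene_stats(aln, masks, "rareX")}["all"]
    # species1 rows: one singleton among 3 rows -> pi = (2/3 pairs differ)/12
    assert rec.pi_1 == pytest.approx((2 / 3) / 12, abs=1e-12)
    assert rec.pi_2 == 0.0
    # dxy: col 2 mismatches in 3/9 pairs; col 8 in all 9
    assert rec.dxy == pytest.approx((3 / 9 + 9 / 9) / 12, abs=1e-12)
    assert rec.fst == pytest.approx(1 - (0.5 * (2 / 3) / 12) / rec.dxy, abs=1e-12)


def test_species_swap_symmetry():
    rng = np.random.default_rng(7)
    aln = random_alignment(rng, n_rows=8, n_cols=30)
    masks = classify_codon_sites(aln)
    rec = {r.site_class: r for r in per_gene_stats(aln, masks, "freqA")}["all"]
    # present the same data with the species halves exchanged
    swapped_rows = ["".join(r) for r in np.vstack([aln.seqs[4:], aln.seqs[:4]]).astype("U1")]
    swapped = make_alignment(swapped_rows)
    rec2 = {r.site_class: r for r in per_gene_stats(swapped, masks, "freqA")}["all"]
    assert rec2.dxy == pytest.approx(rec.dxy, abs=1e-12)
    assert (rec2.pi_1, rec2.pi_2) == (rec.pi_2, rec.pi_1)
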