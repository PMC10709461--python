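"""Group comparisons, compact letter display and expression divergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lxeflow.compare import (
    chi_square_2x2,
    expression_divergence,
    kruskal_wallis,
    pairwise_wilcoxon_letters,
    spearman_correlation,
)
from lxeflow.io import ExpressionMatrix


def test_kw_identical_split_is_zero():
    data = np.array([1.0, 2.0, 3.0, 4.0] * 3)
    h, p = kruskal_wallis([data[:4], data[4:8], data[8:]])
    assert h == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_kw_matches_hand_ranked_oracle():
    groups = [np.array([1.2, 3.4, 2.2]), np.array([5.0, 6.1]), np.array([0.5, 7.7, 8.8])]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # no ties here, so the tie correction is a no-op
    got, _ = kruskal_wallis(groups)
    assert got == pytest.approx(h, abs=1e-10)


def test_kw_label_permutation_invariance(rng):
    groups = [rng.normal(size=10), rng.normal(size=12), rng.normal(size=8)]
    h1, _ = kruskal_wallis(groups)
    h2, _ = kruskal_wallis(groups[::-1])
    assert h1 == pytest.approx(h2, abs=1e-12)


def test_kw_all_identical_degenerate():
    h, p = kruskal_wallis([np.ones(5), np.ones(4)])
    assert (h, p) == (0.0, 1.0)


def test_kw_two_groups_monotone_with_wilcoxon(rng):
    """With two groups, KW H and the Mann-Whitney U map to each other."""
    for _ in range(10):
        a = rng.normal(size=12)
        b = rng.normal(rng.uniform(0, 2), size=15)
        h, hp = kruskal_wallis([a, b])
        _, wp = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert hp == pytest.approx(wp, rel=1e-9)


def test_letters_identical_data_share_one_letter():
    v = np.arange(20.0)
    res = pairwise_wilcoxon_letters({c: v for c in ("freqA", "rareA", "freqX", "rareX")})
    assert set(res.letters.values()) == {"a"}
    assert res.consistent()


def test_letters_well_separated_groups_all_distinct(rng):
    groups = {f"g{i}": rng.normal(10 * i, 1.0, size=100) for i in range(4)}
    res = pairwise_wilcoxon_letters(groups)
    assert len(set(res.letters.values())) == 4
    assert all(len(v) == 1 for v in res.letters.values())
    assert res.consistent()


def test_letters_chain_structure(rng):
    # a < b < c with adjacent overlap: middle group shares letters with both
    a = rng.normal(0.0, 1.0, 60)
    b = rng.normal(1.0, 1.0, 60)
    c = rng.normal(2.0, 1.0, 60)
    res = pairwise_wilcoxon_letters({"a": a, "b": b, "c": c})
    assert res.consistent()


def test_letters_consistency_on_random_instances(rng):
    for trial in range(20):
        k = int(rng.integers(2, 6))
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, 1.5), 1.0, size=int(rng.integers(5, 40)))
            for i in range(k)
        }
        res = pairwise_wilcoxon_letters(groups)
        assert res.consistent()


def test_empty_group_errors():
    with pytest.raises(ValueError):
        pairwise_wilcoxon_letters({"a": np.array([1.0]), "b": np.array([])})


def test_spearman_monotone_and_reversed(rng):
    x = rng.normal(size=30)
    rho, _ = spearman_correlation(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    rho, _ = spearman_correlation(x, -(x**3))
    assert rho == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    rho, _ = spearman_correlation(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)


def test_spearman_constant_vector_flagged():
    rho, p = spearman_correlation(np.ones(5), np.arange(5.0))
    assert np.isnan(rho)


# ---------- expression divergence ----------

def make_expr(n_genes, n_per_species, shift_genes, rng, shift=3.0):
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"a{i}" for i in range(n_per_species)] + [f"b{i}" for i in range(n_per_species)]
    base = rng.normal(3, 1, size=n_genes)
    vals = np.empty((n_genes, 2 * n_per_species))
    for i in range(n_genes):
        mu2 = base[i] + (shift if i in shift_genes else 0.0)
        vals[i, :n_per_species] = np.exp(rng.normal(base[i], 0.2, n_per_species))
        vals[i, n_per_species:] = np.exp(rng.normal(mu2, 0.2, n_per_species))
    species = {c: ("species1" if c.startswith("a") else "species2") for c in cols}
    return ExpressionMatrix(pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"),
                                         columns=cols), species)


def make_categories(n_genes):
    cats = ["freqA", "rareA", "freqX", "rareX"]
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                         "category": [cats[i % 4] for i in range(n_genes)]})


def test_identical_matrices_zero_significant(rng):
    expr = make_expr(40, 6, set(), rng)
    div = expression_divergence(expr, make_categories(40))
    assert div.counts.loc["all", "significant"] == 0


def test_shifted_genes_detected_and_percentages_recompute(rng):
    shifted = set(range(0, 12))
    expr = make_expr(60, 8, shifted, rng, shift=4.0)
    div = expression_divergence(expr, make_categories(60))
    assert div.counts.loc["all", "significant"] >= 10
    for cat in div.counts.index:
        t, s, pct = div.counts.loc[cat]
        if t > 0:
            assert pct == pytest.approx(100.0 * s / t, abs=1e-9)


def test_r2_grid_high_for_correlated_expression(rng):
    expr = make_expr(80, 6, set(), rng)
    div = expression_divergence(expr, make_categories(80))
    assert div.r2.loc["all", "all"] > 0.8


def test_table4_percentages_from_printed_counts():
    """Published per-category proportions recompute from their own counts."""
    counts = pd.DataFrame(
        {"total": [209, 2009, 398, 1909], "significant": [21, 145, 40, 172]},
        index=["freqX", "freqA", "rareX", "rareA"],
    )
    pct = 100.0 * counts["significant"] / counts["total"]
    assert round(pct["freqA"], 2) == 7.22
    assert round(pct["rareA"], 2) == 9.01
    assert round(pct["freqX"], 2) == round(pct["rareX"], 2) == 10.05


# ---------- chi-square ----------

def test_chi2_proportional_table_zero():
    chi2, p = chi_square_2x2(10, 90, 20, 180)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_matches_expected_counts_oracle():
    a, b, c, d = 145, 1864, 172, 1737
    n = a + b + c + d
    chi2 = 0.0
    for obs, rtot, ctot in [
        (a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)
    ]:
        exp = rtot * ctot / n
        chi2 += (obs - exp) ** 2 / exp
    got, _ = chi_square_2x2(a, b, c, d)
    assert got == pytest.approx(chi2, abs=1e-10)


def test_chi2_row_swap_invariance():
    assert chi_square_2x2(5, 10, 8, 30)[0] == pytest.approx(
        chi_square_2x2(8, 30, 5, 10)[0], abs=1e-12
    )


def test_chi2_zero_margin_errors():
    with pytest.raises(ValueError):
        chi_square_2x2(0, 0, 5, 10)
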