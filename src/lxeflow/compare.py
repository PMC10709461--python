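"""Nonparametric group comparisons and gene-expression divergence.

Per-gene statistics are compared across the four gene categories (freqA,
rareA, freqX, rareX) with the Kruskal-Wallis test and pairwise Wilcoxon
rank-sum (Mann-Whitney U) tests summarized as a compact letter display:
two groups share a letter iff their pairwise test is not significant at
alpha.  Expression divergence between the two species is a per-gene Welch
t-test on FPKM with a stringent threshold (P < 1e-4), tabulated as counts
and percentages per category, plus the squared Pearson correlation of
per-gene species-mean FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "kruskal_wallis",
    "pairwise_wilcoxon_letters",
    "spearman_correlation",
    "expression_divergence",
    "chi_square_2x2",
    "GroupComparisonResult",
    "ExpressionDivergence",
]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(df = k-1).

    Degenerate all-identical data returns (0, 1) instead of raising.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation; NaN rho when a rank vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GroupComparisonResult:
    statistic: str
    groups: list[str]
    kw_H: float
    kw_p: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    medians: dict[str, float]
    alpha: float = 0.05

    def consistent(self) -> bool:
        """Letters agree with the pairwise matrix: shared letter <=> p >= alpha."""
        for a in self.groups:
            for b in self.groups:
                if a >= b:
                    continue
                share = bool(set(self.letters[a]) & set(self.letters[b]))
                signif = self.pairwise_p.loc[a, b] < self.alpha
                if share == signif:
                    return False
        return True


def _insert_absorb(groups: list[str], differ) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Starts with one letter covering all groups; every significantly
    different pair found inside a letter's set splits it into two sets
    (each excluding one member of the pair); duplicate/contained sets are
    absorbed.  Letters are assigned to the final sets in group order.
    """
    sets: list[set[str]] = [set(groups)]
    changed = True
    while changed:
        changed = False
        for s in list(sets):
            pair = next(
                ((a, b) for a in sorted(s) for b in sorted(s) if a < b and differ(a, b)),
                None,
            )
            if pair is None:
                continue
            a, b = pair
            sets.remove(s)
            for drop in (a, b):
                cand = s - {drop}
                if cand and not any(cand <= other for other in sets):
                    sets.append(cand)
            sets = [s1 for s1 in sets if not any(s1 < s2 for s2 in sets if s1 is not s2)]
            changed = True
            break
    # deterministic letter order: sets sorted by earliest member
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def pairwise_wilcoxon_letters(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    statistic: str = "",
    holm: bool = False,
) -> GroupComparisonResult:
    """Pairwise Mann-Whitney U tests with a compact letter display.

    Uses the normal approximation with tie correction.  `holm=True` applies
    a Holm step-down correction to the pairwise p-values before letters are
    assigned (off by default).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pvals = []
    for a, b in pairs:
        if np.array_equal(arrs[a], arrs[b]):
            p = 1.0
        else:
            _, p = sps.mannwhitneyu(arrs[a], arrs[b], alternative="two-sided", method="asymptotic")
        pvals.append(float(p))
    if holm and pairs:
        idx = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(idx):
            running = max(running, (m - rank) * pvals[i])
            adj[i] = min(1.0, running)
        pvals = list(adj)
    for (a, b), p in zip(pairs, pvals):
        pmat.loc[a, b] = p
        pmat.loc[b, a] = p
    h, kp = kruskal_wallis([arrs[g] for g in names])
    letters = _insert_absorb(names, lambda a, b: pmat.loc[a, b] < alpha)
    return GroupComparisonResult(
        statistic=statistic,
        groups=names,
        kw_H=h,
        kw_p=kp,
        pairwise_p=pmat,
        letters=letters,
        medians={g: float(np.median(arrs[g])) for g in names},
        alpha=alpha,
    )


@dataclass
class ExpressionDivergence:
    """Per-category expression divergence summary between two species."""

    per_gene_p: pd.Series  # Welch t-test p per gene
    counts: pd.DataFrame  # index = category (+ aggregates), columns total/significant/percent
    r2: pd.DataFrame  # squared Pearson r of species-mean FPKM, {freq,rare,all} x {X,A,all}
    alpha: float


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    _, p = sps.ttest_ind(x, y, equal_var=False)
    return float(p)


def expression_divergence(
    expr: ExpressionMatrix,
    categories: pd.DataFrame,
    alpha: float = 1e-4,
) -> ExpressionDivergence:
    """Welch two-sample t-test per gene on FPKM; tabulate significance by category.

    Also computes r^2 (squared Pearson correlation of per-gene species-mean
    FPKM) for each {freq, rare, all} x {X, A, all} cell.
    """
    sp = expr.species
    if len(sp) != 2:
        raise ValueError("expression matrix must cover exactly two species")
    s1 = expr.samples_of(sp[0])
    s2 = expr.samples_of(sp[1])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 samples per species")
    v1 = expr.values[s1].to_numpy()
    v2 = expr.values[s2].to_numpy()
    pvals = pd.Series(
        [_welch_p(v1[i], v2[i]) for i in range(v1.shape[0])],
        index=expr.values.index,
        name="p_welch",
    )
    cat = categories.set_index("gene_id")["category"].reindex(pvals.index)
    sig = pvals < alpha

    def tab(mask: pd.Series) -> tuple[int, int]:
        return int(mask.sum()), int((sig & mask).sum())

    rows = {}
    for c in ("freqX", "freqA", "rareX", "rareA"):
        rows[c] = tab(cat == c)
    rows["freq"] = tab(cat.isin(["freqX", "freqA"]))
    rows["rare"] = tab(cat.isin(["rareX", "rareA"]))
    rows["all"] = tab(cat.notna())
    counts = pd.DataFrame(rows, index=["total", "significant"]).T
    counts["percent"] = 100.0 * counts["significant"] / counts["total"].replace(0, np.nan)

    m1 = v1.mean(axis=1)
    m2 = v2.mean(axis=1)
    is_x = cat.str.endswith("X")
    is_freq = cat.str.startswith("freq")
    r2 = pd.DataFrame(index=["freq", "rare", "all"], columns=["X", "A", "all"], dtype=float)
    for rname, rmask in (("freq", is_freq), ("rare", ~is_freq & cat.notna()), ("all", cat.notna())):
        for cname, cmask in (("X", is_x), ("A", ~is_x & cat.notna()), ("all", cat.notna())):
            m = (rmask & cmask).to_numpy()
            if m.sum() >= 3 and np.var(m1[m]) > 0 and np.var(m2[m]) > 0:
                r = np.corrcoef(m1[m], m2[m])[0, 1]
                r2.loc[rname, cname] = r * r
    return ExpressionDivergence(pvals, counts, r2, alpha)


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    Continuity correction off by default.  A table whose rows are
    proportional gives exactly 0.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)
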