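"""Monte-Carlo structured coalescent for two demes with migration and growth.

The engine simulates genealogies backward in time for samples from two
populations that split T time units ago (time in units of 2*N_A generations,
sizes relative to the ancestral size N_A).  Between the present and the split
each deme has its own size trajectory — constant, or exponential interpolation
from (s, 1-s) at the split to (N1, N2) at present — and lineages migrate
between demes.  At the split all lineages merge into a single ancestral deme
of relative size 1.

Conventions follow the diffusion-based inference literature: migration
parameters M are 2*N_A*m where m is the fraction of the receiving population
replaced by immigrants per generation, so the backward per-lineage migration
rate is M per unit of 2*N_A generations; the pair-coalescence rate in a deme
of relative size nu is 1/nu.

Expected joint-SFS entries are accumulated as branch lengths: every lineage
ancestral to i present-day sample copies from species 1 and j from species 2
adds its length to cell (i, j).  Scaling expected lengths by theta gives
expected site counts under the Poisson random field.

Events under time-varying deme sizes are sampled exactly by thinning against
an upper-bound hazard computed from the minimum deme size on the remaining
interval (the exponential trajectories are monotone, so the minimum is at an
endpoint).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["expected_branch_sfs", "simulate_genealogy_arrays"]


@njit(cache=True)
def _deme_size(nu_now: float, nu_split: float, frac: float, grow: bool) -> float:
    # frac = t/T with t measured backward from the present
    if not grow:
        return nu_now
    return nu_now * (nu_split / nu_now) ** frac


@njit(cache=True)
def _pick_in_deme(deme, k, target, which):
    """Index of the `which`-th active lineage (0..k-1) currently in `target`."""
    seen = -1
    for idx in range(k):
        if deme[idx] == target:
            seen += 1
            if seen == which:
                return idx
    return -1  # unreachable when counts are consistent


@njit(cache=True)
def _sim_core(n1, n2, nu1, nu2, s, T, m1, m2, grow, n_reps, seed, sfs, sfs_sq, lsum):
    """Accumulate branch lengths (and their squares across genealogies, for
    per-cell Monte-Carlo variance) into (n1+1) x (n2+1) matrices; lsum gets
    the sum and sum of squares of the per-genealogy total length."""
    np.random.seed(seed)
    ntot = n1 + n2
    deme = np.empty(ntot, dtype=np.int8)
    ci = np.empty(ntot, dtype=np.int64)
    cj = np.empty(ntot, dtype=np.int64)
    tmp = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    nu1_split = s if grow else nu1
    nu2_split = (1.0 - s) if grow else nu2

    for _rep in range(n_reps):
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                tmp[a, b] = 0.0
        for x in range(n1):
            deme[x] = 0
            ci[x] = 1
            cj[x] = 0
        for x in range(n2):
            deme[n1 + x] = 1
            ci[n1 + x] = 0
            cj[n1 + x] = 1
        k = ntot
        t = 0.0

        # island phase: two demes until the split at time T
        while k > 1 and t < T:
            k0 = 0
            for idx in range(k):
                if deme[idx] == 0:
                    k0 += 1
            k1 = k - k0
            # monotone trajectories: min size on [t, T] is at an endpoint
            f = t / T if T > 0.0 else 1.0
            nu1_t = _deme_size(nu1, nu1_split, f, grow)
            nu2_t = _deme_size(nu2, nu2_split, f, grow)
            min1 = min(nu1_t, nu1_split)
            min2 = min(nu2_t, nu2_split)
            bound = (
                0.5 * k0 * (k0 - 1) / min1
                + 0.5 * k1 * (k1 - 1) / min2
                + k0 * m1
                + k1 * m2
            )
            if bound <= 0.0:
                dt = T - t
            else:
                dt = np.random.exponential(1.0 / bound)
            if t + dt >= T or bound <= 0.0:
                rem = T - t
                for idx in range(k):
                    tmp[ci[idx], cj[idx]] += rem
                t = T
                break
            for idx in range(k):
                tmp[ci[idx], cj[idx]] += dt
            t += dt
            f = t / T
            nu1_t = _deme_size(nu1, nu1_split, f, grow)
            nu2_t = _deme_size(nu2, nu2_split, f, grow)
            rc0 = 0.5 * k0 * (k0 - 1) / nu1_t
            rc1 = 0.5 * k1 * (k1 - 1) / nu2_t
            rm0 = k0 * m1
            rm1 = k1 * m2
            u = np.random.random() * bound
            if u < rc0 or u < rc0 + rc1:
                target = 0 if u < rc0 else 1
                kk = k0 if target == 0 else k1
                a = np.random.randint(0, kk)
                b = np.random.randint(0, kk - 1)
                if b >= a:
                    b += 1
                ia = _pick_in_deme(deme, k, target, a)
                ib = _pick_in_deme(deme, k, target, b)
                ci[ia] += ci[ib]
                cj[ia] += cj[ib]
                k -= 1
                deme[ib] = deme[k]
                ci[ib] = ci[k]
                cj[ib] = cj[k]
            elif u < rc0 + rc1 + rm0:
                ia = _pick_in_deme(deme, k, 0, np.random.randint(0, k0))
                deme[ia] = 1
            elif u < rc0 + rc1 + rm0 + rm1:
                ia = _pick_in_deme(deme, k, 1, np.random.randint(0, k1))
                deme[ia] = 0
            # else: thinning rejection

        # ancestral phase: one panmictic deme of relative size 1
        while k > 1:
            rate = 0.5 * k * (k - 1)
            dt = np.random.exponential(1.0 / rate)
            for idx in range(k):
                tmp[ci[idx], cj[idx]] += dt
            a = np.random.randint(0, k)
            b = np.random.randint(0, k - 1)
            if b >= a:
                b += 1
            ci[a] += ci[b]
            cj[a] += cj[b]
            k -= 1
            deme[b] = deme[k]
            ci[b] = ci[k]
            cj[b] = cj[k]

        ltot = 0.0
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                sfs[a, b] += tmp[a, b]
                sfs_sq[a, b] += tmp[a, b] * tmp[a, b]
                ltot += tmp[a, b]
        lsum[0] += ltot
        lsum[1] += ltot * ltot


def expected_branch_sfs(
    n1: int,
    n2: int,
    nu1: float,
    nu2: float,
    s: float,
    T: float,
    m1: float,
    m2: float,
    grow: bool,
    n_reps: int,
    seed: int,
    return_var: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Expected branch-length joint SFS, shape (n1+1, n2+1), per-genealogy units.

    Cells (0, 0) and (n1, n2) are fixed at zero (monomorphic classes).
    Multiplying by theta (per-locus population mutation rate on the 2*N_A
    generation scale) gives the expected site-count spectrum.  With
    `return_var`, also returns the per-cell variance of the Monte-Carlo mean
    (used to debias downstream log-likelihoods).
    """
    if nu1 <= 0 or nu2 <= 0:
        raise ValueError("population sizes must be positive")
    if T < 0:
        raise ValueError("split time must be non-negative")
    if grow and not (0.0 < s < 1.0):
        raise ValueError("split fraction s must be in (0, 1)")
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages")
    sfs = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    sfs_sq = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    lsum = np.zeros(2, dtype=np.float64)
    _sim_core(
        n1, n2, float(nu1), float(nu2), float(s), float(T),
        float(m1), float(m2), bool(grow), int(n_reps), int(seed) % (2**31),
        sfs, sfs_sq, lsum,
    )
    sfs /= n_reps
    sfs[0, 0] = 0.0
    sfs[n1, n2] = 0.0
    if not return_var:
        return sfs
    var = np.maximum(sfs_sq / n_reps - sfs**2, 0.0) / n_reps
    var[0, 0] = 0.0
    var[n1, n2] = 0.0
    lmean = lsum[0] / n_reps
    total_var = max(lsum[1] / n_reps - lmean * lmean, 0.0) / n_reps
    return sfs, var, total_var


def simulate_genealogy_arrays(
    n1: int,
    n2: int,
    nu1: float,
    nu2: float,
    s: float,
    T: float,
    m1: float,
    m2: float,
    grow: bool,
    rng: np.random.Generator,
):
    """One genealogy; returns (edge lengths, leaf-membership bool matrix, tmrca).

    Row r of the membership matrix marks the present-day leaves descending
    from edge r.  Leaves 0..n1-1 are species-1 haplotypes, n1..n1+n2-1
    species 2.  Implemented in Python (one tree at a time) because the
    synthetic-data generator needs topology, not just branch-length spectra.
    """
    ntot = n1 + n2
    deme = [0] * n1 + [1] * n2
    members = [frozenset([x]) for x in range(ntot)]
    birth = [0.0] * ntot  # time each current lineage started
    nu1_split = s if grow else nu1
    nu2_split = (1.0 - s) if grow else nu2
    edges_len: list[float] = []
    edges_members: list[frozenset] = []
    t = 0.0

    def size(nu_now, nu_split, tt):
        if not grow or T == 0.0:
            return nu_now
        return nu_now * (nu_split / nu_now) ** (tt / T)

    while len(members) > 1 and t < T:
        k0 = sum(1 for d in deme if d == 0)
        k1 = len(deme) - k0
        min1 = min(size(nu1, nu1_split, t), nu1_split)
        min2 = min(size(nu2, nu2_split, t), nu2_split)
        bound = 0.5 * k0 * (k0 - 1) / min1 + 0.5 * k1 * (k1 - 1) / min2 + k0 * m1 + k1 * m2
        if bound <= 0.0:
            t = T
            break
        dt = rng.exponential(1.0 / bound)
        if t + dt >= T:
            t = T
            break
        t += dt
        rc0 = 0.5 * k0 * (k0 - 1) / size(nu1, nu1_split, t)
        rc1 = 0.5 * k1 * (k1 - 1) / size(nu2, nu2_split, t)
        rm0 = k0 * m1
        rm1 = k1 * m2
        u = rng.random() * bound
        if u < rc0 + rc1:
            target = 0 if u < rc0 else 1
            pool = [x for x in range(len(members)) if deme[x] == target]
            a, b = rng.choice(len(pool), size=2, replace=False)
            ia, ib = pool[a], pool[b]
            for idx in (ia, ib):
                edges_len.append(t - birth[idx])
                edges_members.append(members[idx])
            merged = members[ia] | members[ib]
            members[ia] = merged
            birth[ia] = t
            del members[ib], birth[ib], deme[ib]
        elif u < rc0 + rc1 + rm0:
            pool = [x for x in range(len(members)) if deme[x] == 0]
            deme[pool[rng.integers(len(pool))]] = 1
        elif u < rc0 + rc1 + rm0 + rm1:
            pool = [x for x in range(len(members)) if deme[x] == 1]
            deme[pool[rng.integers(len(pool))]] = 0

    while len(members) > 1:
        k = len(members)
        rate = 0.5 * k * (k - 1)
        t += rng.exponential(1.0 / rate)
        a, b = rng.choice(k, size=2, replace=False)
        ia, ib = int(a), int(b)
        for idx in (ia, ib):
            edges_len.append(t - birth[idx])
            edges_members.append(members[idx])
        merged = members[ia] | members[ib]
        members[ia] = merged
        birth[ia] = t
        del members[ib], birth[ib], deme[ib]

    lengths = np.asarray(edges_len, dtype=float)
    mat = np.zeros((len(edges_members), ntot), dtype=bool)
    for r, mem in enumerate(edges_members):
        mat[r, list(mem)] = True
    return lengths, mat, t
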