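"""Demographic models: expected-SFS engine properties, Poisson likelihood,
AIC/LRT arithmetic and model bookkeeping."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from lxeflow.demography import (
    MODELS,
    FitResult,
    ModelParams,
    aic,
    collapse_params,
    embed_params,
    expected_sfs,
    lrt,
    model_selection_table,
    poisson_loglik,
    simulate_sfs_counts,
)
from lxeflow.sfs import JointSFS


def test_free_parameter_counts_match_model_table():
    ks = {m: len(names) for m, names in MODELS.items()}
    assert ks == {"split_mig": 4, "IM": 5, "IM_2M": 7, "IM2": 6, "IM2_2M": 9}


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams("IM", dict(s=1.2, N1=1, N2=1, T=1, M=1))
    with pytest.raises(ValueError):
        ModelParams("IM", dict(s=0.5, N1=-1, N2=1, T=1, M=1))
    with pytest.raises(ValueError):
        ModelParams("nope", {})
    with pytest.raises(ValueError):
        ModelParams("IM2", dict(s=0.5, N1=1, N2=1, T=1, M1=1))  # missing M2


# ---------- expected-SFS engine ----------

def test_symmetric_model_gives_symmetric_spectrum():
    p = ModelParams("IM", dict(s=0.5, N1=2.0, N2=2.0, T=1.0, M=1.0))
    e = expected_sfs(p, 6, 6, n_reps=30000, seed=5).counts
    # exchangeability of the two demes: (i,j) ~ (j,i) within MC tolerance
    off = [(e[i, j], e[j, i]) for i in range(7) for j in range(7) if i < j and e[i, j] > 0.05]
    rel = [abs(a - b) / (a + b) for a, b in off]
    assert np.mean(rel) < 0.05


def test_t_zero_constant_size_matches_kingman_marginal():
    """T=0 collapses to one deme of size 1: E[xi_k] proportional to 1/k."""
    p = ModelParams("split_mig", dict(N1=1.0, N2=1.0, T=0.0, M=0.0))
    n_reps = 20000
    sfs, var, _ = __import__("lxeflow.coalescent", fromlist=["expected_branch_sfs"]).expected_branch_sfs(
        10, 0, 1.0, 1.0, 0.5, 0.0, 0.0, 0.0, False, n_reps, 3, return_var=True
    )
    marg = sfs.sum(axis=1)
    se = np.sqrt(var.sum(axis=1))
    for k in range(1, 10):
        assert abs(marg[k] - 2.0 / k) < 3 * se[k] + 1e-9


def test_no_migration_large_t_no_shared_polymorphism():
    p = ModelParams("IM", dict(s=0.5, N1=1.0, N2=1.0, T=5.0, M=0.0))
    e = expected_sfs(p, 6, 6, n_reps=20000, seed=9).counts
    interior = e[1:6, 1:6].sum()
    assert interior / e.sum() < 0.01


def test_t_zero_handled_as_immediate_merge():
    p = ModelParams("split_mig", dict(N1=5.0, N2=0.2, T=0.0, M=3.0))
    e = expected_sfs(p, 4, 4, n_reps=2000, seed=1)
    assert e.counts.sum() > 0


def test_mixture_model_is_weighted_sum_of_components():
    from lxeflow.coalescent import expected_branch_sfs

    base = dict(s=0.4, N1=1.5, N2=2.0, T=1.0)
    p2m = ModelParams("IM2_2M", {**base, "MA1": 0.2, "MA2": 0.1, "MB1": 2.0, "MB2": 1.0, "P": 0.3})
    seed = 77
    e_mix = expected_sfs(p2m, 4, 4, n_reps=3000, seed=seed).counts
    e_a = expected_branch_sfs(4, 4, 1.5, 2.0, 0.4, 1.0, 0.2, 0.1, True, 3000, seed)
    e_b = expected_branch_sfs(4, 4, 1.5, 2.0, 0.4, 1.0, 2.0, 1.0, True, 3000, seed + 1)
    mix = np.maximum(0.3 * e_a + 0.7 * e_b, 0.5 / 3000)
    mix[0, 0] = mix[4, 4] = 0.0  # monomorphic corners stay masked
    assert np.allclose(e_mix, mix, rtol=1e-9, atol=1e-12)


def test_engine_agrees_with_msprime_oracle():
    """Independent cross-check: split_mig expected branch SFS vs msprime.

    Units map: our deme size nu (in N_A) = msprime diploid size nu/2 with
    time in our 2*N_A-generation units; backward per-lineage migration rate
    M on both scales.
    """
    import msprime

    N1, N2, T, M = 2.0, 1.0, 0.5, 1.0
    dem = msprime.Demography()
    dem.add_population(name="p1", initial_size=N1 / 2)
    dem.add_population(name="p2", initial_size=N2 / 2)
    dem.add_population(name="anc", initial_size=0.5)
    dem.set_migration_rate("p1", "p2", M)
    dem.set_migration_rate("p2", "p1", M)
    dem.add_population_split(time=T, derived=["p1", "p2"], ancestral="anc")
    reps = 8000
    afs = np.zeros((7, 7))
    for ts in msprime.sim_ancestry(samples={"p1": 3, "p2": 3}, demography=dem,
                                   ploidy=2, num_replicates=reps, random_seed=5):
        afs += ts.allele_frequency_spectrum(
            [ts.samples(population=0), ts.samples(population=1)],
            mode="branch", polarised=True, span_normalise=True,
        )
    afs /= reps
    from lxeflow.coalescent import expected_branch_sfs

    mine = expected_branch_sfs(6, 6, N1, N2, 0.5, T, M, M, False, 20000, 9)
    m = (afs > 0.02) & (mine > 0.02)
    rel = np.abs(afs[m] - mine[m]) / (afs[m] + mine[m])
    assert rel.mean() < 0.05
    assert rel.max() < 0.2


# ---------- Poisson composite likelihood ----------

def test_theta_hat_recovers_scale_and_is_optimal():
    rng = np.random.default_rng(0)
    E = rng.gamma(2.0, 1.0, size=(5, 5))
    exp = JointSFS(E.copy(), 4, 4)
    c = 3.7
    obs = JointSFS(c * exp.counts, 4, 4)
    ll, theta = poisson_loglik(obs, exp)
    assert theta == pytest.approx(c)

    def ll_at(scale):
        lam = scale * exp.counts
        m = lam > 0
        return float(np.sum(obs.counts[m] * np.log(lam[m]) - lam[m] - gammaln(obs.counts[m] + 1)))

    assert ll == pytest.approx(ll_at(c), abs=1e-9)
    assert ll > ll_at(c * 1.1) and ll > ll_at(c * 0.9)


def test_loglik_matches_term_by_term_hand_sum():
    obs = JointSFS(np.array([[0, 2, 1], [3, 0, 4], [1, 2, 0]], dtype=float), 2, 2)
    exp = JointSFS(np.array([[0, 1.0, 0.5], [2.0, 0.1, 3.0], [0.4, 1.5, 0]], dtype=float), 2, 2)
    ll, theta = poisson_loglik(obs, exp)
    th = obs.counts.sum() / exp.counts.sum()
    hand = 0.0
    for i in range(3):
        for j in range(3):
            lam = th * exp.counts[i, j]
            if lam > 0 or obs.counts[i, j] > 0:
                hand += obs.counts[i, j] * math.log(max(lam, 1e-12)) - lam - math.lgamma(obs.counts[i, j] + 1)
    assert ll == pytest.approx(hand, abs=1e-9)


def test_all_zero_observation_degenerate():
    obs = JointSFS(np.zeros((3, 3)), 2, 2)
    exp = JointSFS(np.ones((3, 3)), 2, 2)
    ll, theta = poisson_loglik(obs, exp)
    assert (ll, theta) == (0.0, 0.0)


def test_shape_mismatch_errors():
    with pytest.raises(ValueError):
        poisson_loglik(JointSFS(np.ones((3, 3)), 2, 2), JointSFS(np.ones((4, 4)), 3, 3))


# ---------- AIC / LRT / model selection arithmetic ----------

def test_aic_definition():
    assert aic(0.0, 0) == 0.0
    assert aic(-100.0, 5) == pytest.approx(210.0)


def test_lrt_equal_logliks():
    stat, p = lrt(-50.0, -50.0, 3)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_lrt_alt_below_null_clamped_with_warning():
    with pytest.warns(UserWarning):
        stat, p = lrt(-50.0, -51.0, 2)
    assert stat == 0.0 and p == 1.0


def test_model_selection_table_delta_aic_and_rel_like():
    def fit(model, ll):
        pnames = MODELS[model]
        vals = {n: 0.5 for n in pnames}
        pr = ModelParams(model, vals)
        return FitResult(params=pr, loglik=ll, theta=1.0, aic=aic(ll, pr.k))

    fits = [fit("IM", -100.0), fit("IM2", -99.0), fit("split_mig", -120.0)]
    tab = model_selection_table(fits)
    assert tab.iloc[0]["model"] == "IM"  # AIC 210 vs IM2's 210... tie-break by order
    best = tab["aic"].min()
    assert (tab["delta_aic"] == tab["aic"] - best).all()
    for _, row in tab.iterrows():
        assert row["rel_like"] == pytest.approx(math.exp(-row["delta_aic"] / 2))
    row2 = tab[tab.delta_aic == 2.0]
    if len(row2):
        assert row2.iloc[0]["rel_like"] == pytest.approx(math.exp(-1.0))


def test_embedding_and_collapse_are_inverse_on_shared_params():
    im2 = ModelParams("IM2", dict(s=0.3, N1=1.2, N2=2.2, T=0.8, M1=0.7, M2=0.2))
    up = embed_params(im2, "IM2_2M")
    assert up.values["P"] == 0.5
    back = collapse_params(up, "IM2")
    assert back.values["M1"] == pytest.approx(im2.values["M1"])
    assert back.values["M2"] == pytest.approx(im2.values["M2"])
    assert back.values["T"] == im2.values["T"]


def test_simulated_counts_poisson_mass(rng):
    p = ModelParams("split_mig", dict(N1=1.0, N2=1.0, T=0.5, M=1.0))
    obs = simulate_sfs_counts(p, theta=500.0, n1=4, n2=4, seed=3, n_reps=4000)
    e = expected_sfs(p, 4, 4, n_reps=20000, seed=5)
    expected_mass = 500.0 * e.counts.sum()
    assert abs(obs.total - expected_mass) < 5 * np.sqrt(expected_mass)
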