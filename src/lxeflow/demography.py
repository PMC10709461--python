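"""Two-population isolation-with-migration demographic inference from joint SFS.

Five models of a population split T time units ago (time in 2*N_A
generations, sizes relative to the ancestral size N_A, migration in units of
2*N_A*m):

* ``split_mig`` — split with constant sizes N1, N2 and one symmetric rate M.
* ``IM``        — split at relative sizes (s, 1-s) with exponential change to
                  (N1, N2) at present and one symmetric rate M.
* ``IM2``       — IM with direction-specific rates M1 (into population 1)
                  and M2.
* ``IM_2M``     — IM with two latent site classes A and B in proportions
                  (P, 1-P) carrying different symmetric rates M_A, M_B.
* ``IM2_2M``    — IM2 with two site classes, rates (M_A1, M_A2) and
                  (M_B1, M_B2).

Expected spectra come from the Monte-Carlo structured coalescent
(:mod:`lxeflow.coalescent`) with common random numbers across likelihood
evaluations, so each fit optimizes a deterministic surface.  The data
likelihood is the Poisson random field composite likelihood with the
per-category mutation scale theta profiled out analytically.  Model fits are
compared by AIC and likelihood-ratio tests; parameter uncertainty by a
gene-level bootstrap (CI = M +/- 1.96 * SD over replicate refits).

Reported log-likelihoods of competing fits are re-evaluated at a higher
replicate count with a fresh shared seed, so model comparisons are not
inflated by the optimizer exploiting one Monte-Carlo noise realization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy.special import gammaln
from scipy.stats import chi2

from .coalescent import expected_branch_sfs
from .sfs import JointSFS

__all__ = [
    "ModelParams",
    "FitResult",
    "MODELS",
    "expected_sfs",
    "poisson_loglik",
    "optimize_model",
    "aic",
    "lrt",
    "model_selection_table",
    "bootstrap_ci",
    "simulate_sfs_counts",
    "embed_params",
    "fit_model_chain",
]

# model_id -> ordered free-parameter names (k = length, as printed in model tables)
MODELS: dict[str, tuple[str, ...]] = {
    "split_mig": ("N1", "N2", "T", "M"),
    "IM": ("s", "N1", "N2", "T", "M"),
    "IM2": ("s", "N1", "N2", "T", "M1", "M2"),
    "IM_2M": ("s", "N1", "N2", "T", "MA", "MB", "P"),
    "IM2_2M": ("s", "N1", "N2", "T", "MA1", "MA2", "MB1", "MB2", "P"),
}

# optimization box: the wide ranges of the two-stage search protocol
WIDE_RANGES = {
    "s": (0.02, 0.98),
    "P": (0.02, 0.98),
    "N1": (1e-2, 100.0),
    "N2": (1e-2, 100.0),
    "T": (1e-2, 5.0),
}
_MIG_RANGE = (1e-2, 10.0)


def _param_range(name: str) -> tuple[float, float]:
    return WIDE_RANGES.get(name, _MIG_RANGE)


def _is_logit(name: str) -> bool:
    return name in ("s", "P")


@dataclass
class ModelParams:
    model_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")
        names = MODELS[self.model_id]
        missing = set(names) - set(self.values)
        if missing:
            raise ValueError(f"{self.model_id}: missing parameters {sorted(missing)}")
        self.values = {n: float(self.values[n]) for n in names}
        for n, v in self.values.items():
            if _is_logit(n):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{n} must be in [0, 1]")
            elif n == "T" or n.startswith("M"):
                if v < 0:
                    raise ValueError(f"{n} must be non-negative")
            elif v <= 0:
                raise ValueError(f"{n} must be positive")

    @property
    def k(self) -> int:
        return len(MODELS[self.model_id])

    def vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in MODELS[self.model_id]])

    @classmethod
    def from_vector(cls, model_id: str, x: np.ndarray) -> "ModelParams":
        return cls(model_id, dict(zip(MODELS[model_id], map(float, x))))


def _mixture_components(p: ModelParams) -> list[tuple[float, float, float]]:
    """[(weight, m1, m2), ...] migration components of the model."""
    v = p.values
    if p.model_id == "split_mig":
        return [(1.0, v["M"], v["M"])]
    if p.model_id == "IM":
        return [(1.0, v["M"], v["M"])]
    if p.model_id == "IM2":
        return [(1.0, v["M1"], v["M2"])]
    if p.model_id == "IM_2M":
        return [(v["P"], v["MA"], v["MA"]), (1.0 - v["P"], v["MB"], v["MB"])]
    return [
        (v["P"], v["MA1"], v["MA2"]),
        (1.0 - v["P"], v["MB1"], v["MB2"]),
    ]


def expected_sfs(
    params: ModelParams,
    n1: int,
    n2: int,
    n_reps: int = 2000,
    seed: int = 0,
    fold: bool = False,
) -> JointSFS:
    """Expected joint SFS (branch-length scale, unit theta) under one model.

    Site-class mixtures (the *_2M models) are weighted sums of component
    spectra computed with the same random numbers.
    """
    v = params.values
    grow = params.model_id != "split_mig"
    s = v.get("s", 0.5)
    total = np.zeros((n1 + 1, n2 + 1))
    cell_var = np.zeros((n1 + 1, n2 + 1))
    mass_var = 0.0
    for ci, (w, m1, m2) in enumerate(_mixture_components(params)):
        if w == 0.0:
            continue
        comp, comp_var, comp_tot_var = expected_branch_sfs(
            n1, n2, v["N1"], v["N2"], s, v["T"], m1, m2, grow, n_reps,
            seed + ci, return_var=True,
        )
        # components get distinct seeds so their MC variances are independent
        total += w * comp
        cell_var += w * w * comp_var
        mass_var += w * w * comp_tot_var
    # floor at the Monte-Carlo resolution: a cell the simulation happened to
    # miss is "below half a replicate", not impossible — leaving it at zero
    # makes the composite likelihood wildly non-smooth in the parameters
    total = np.maximum(total, 0.5 / n_reps)
    out = JointSFS(total, n1, n2, folded=False, var=cell_var, total_var=mass_var)
    return out.fold() if fold else out


def poisson_loglik(obs: JointSFS, expected: JointSFS) -> tuple[float, float]:
    """Poisson composite log-likelihood with theta profiled out analytically.

    theta-hat = sum(obs) / sum(expected); expected cells that are exactly zero
    where data exist are floored at 1e-12.

    When the expected spectrum carries Monte-Carlo variances, the profiled
    log-likelihood Sum S*ln(E-hat) - S_tot*ln(Sum E-hat) + const is debiased
    by the second-order Taylor correction of E[ln E-hat]:
    + Sum S*delta_cell^2/2 - S_tot*delta_mass^2/2, with delta the relative MC
    standard error.  Both terms are needed: the first alone rewards, and its
    absence penalizes, parameter regions whose genealogies are highly
    variable (deep trees), whereas only noise in the spectrum *shape* matters
    once theta is profiled out — pure scale noise cancels exactly between the
    two terms.
    """
    if obs.counts.shape != expected.counts.shape or obs.folded != expected.folded:
        raise ValueError("observed and expected spectra must match in shape and folding")
    S = obs.counts
    E = expected.counts
    tot_e = E.sum()
    if tot_e <= 0:
        raise ValueError("expected spectrum has no mass")
    theta = float(S.sum() / tot_e)
    if theta == 0.0:
        return 0.0, 0.0
    lam = theta * E
    lam = np.where((lam == 0) & (S > 0), 1e-12, lam)
    mask = (S > 0) | (lam > 0)
    ll = np.sum(S[mask] * np.log(np.where(lam[mask] > 0, lam[mask], 1.0)))
    ll -= lam.sum()
    ll -= gammaln(S[mask] + 1).sum()
    if expected.var is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            delta2 = np.where(E > 0, expected.var / (E * E), 0.0)
        ll += 0.5 * np.sum(S * np.minimum(delta2, 1.0))
        if expected.total_var is not None:
            ll -= 0.5 * S.sum() * min(expected.total_var / tot_e**2, 1.0)
    return float(ll), theta


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 ln L."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * loglik


def lrt(loglik_null: float, loglik_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2*(lnL_alt - lnL_null) and chi-square p-value."""
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < 0:
        warnings.warn("alternative likelihood below null; reporting statistic 0")
        stat = 0.0
    return stat, float(chi2.sf(stat, df))


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    theta: float
    aic: float
    ci: dict[str, tuple[float, float]] | None = None
    delta_aic: float | None = None
    rel_like: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def model_id(self) -> str:
        return self.params.model_id


def _to_internal(x: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for i, n in enumerate(names):
        if _is_logit(n):
            p = min(max(x[i], 1e-6), 1 - 1e-6)
            out[i] = math.log(p / (1 - p))
        else:
            out[i] = math.log(max(x[i], 1e-12))
    return out


def _from_internal(z: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    for i, n in enumerate(names):
        if _is_logit(n):
            out[i] = 1.0 / (1.0 + math.exp(-z[i]))
        else:
            out[i] = math.exp(z[i])
    return out


def _objective_factory(model_id, obs, n_reps, seed, ranges):
    names = MODELS[model_id]

    def neg_loglik(z: np.ndarray) -> float:
        x = _from_internal(z, names)
        penalty = 0.0
        for i, n in enumerate(names):
            lo, hi = ranges[n]
            if not _is_logit(n):
                if x[i] < lo:
                    penalty += (math.log(lo) - math.log(x[i])) ** 2
                    x[i] = lo
                elif x[i] > hi:
                    penalty += (math.log(x[i]) - math.log(hi)) ** 2
                    x[i] = hi
        params = ModelParams.from_vector(model_id, x)
        exp = expected_sfs(params, obs.n1, obs.n2, n_reps, seed, fold=obs.folded)
        ll, _ = poisson_loglik(obs, exp)
        return -ll + 1e3 * penalty

    return neg_loglik


def _random_start(names, ranges, rng) -> np.ndarray:
    x = np.empty(len(names))
    for i, n in enumerate(names):
        lo, hi = ranges[n]
        if _is_logit(n):
            x[i] = rng.uniform(lo, hi)
        else:
            x[i] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return x


def _tighten(ranges, best, names, factor=3.0):
    """Stage-2 ranges: factor-3 interval around the stage-1 best, clipped wide."""
    out = {}
    for i, n in enumerate(names):
        lo, hi = _param_range(n)
        if _is_logit(n):
            out[n] = (max(lo, best[i] - 0.2), min(hi, best[i] + 0.2))
        else:
            out[n] = (max(lo, best[i] / factor), min(hi, best[i] * factor))
    return out


def optimize_model(
    model_id: str,
    obs: JointSFS,
    seed: int = 0,
    n_reps: int = 1000,
    stage_runs: tuple[int, int] = (10, 30),
    maxiter: int = 400,
    eval_reps: int | None = None,
    extra_starts: list[ModelParams] | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    screen: int = 50,
) -> FitResult:
    """Two-stage multi-start Nelder-Mead fit of one model to an observed SFS.

    Stage 1 runs `stage_runs[0]` local searches from the best of `screen`
    log-uniform candidates in the wide parameter ranges (the candidate
    screening costs one likelihood evaluation each and keeps local searches
    out of hopeless corners); stage 2 runs `stage_runs[1]` more from ranges
    tightened (factor 3) around the stage-1 best, keeping the stage-1 best
    and any `extra_starts` (e.g. embeddings of a simpler nested model's fit)
    as additional starts, and finishes with a polish restart from the
    incumbent.  Local searches use a wide initial simplex (log-scale step)
    because the search space spans orders of magnitude.  All likelihood
    evaluations of one fit share a common random-number seed; the returned
    log-likelihood is re-evaluated at `eval_reps` (default 8x the fit
    replicates) with a distinct seed.
    """
    names = MODELS[model_id]
    wide = {n: (ranges[n] if ranges and n in ranges else _param_range(n)) for n in names}
    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(2**31))
    eval_seed = int(rng.integers(2**31))
    obj = _objective_factory(model_id, obs, n_reps, fit_seed, wide)

    runs: list[dict] = []

    def do_run(x0: np.ndarray, step: float = 0.8) -> None:
        z0 = _to_internal(x0, names)
        simplex = np.vstack([z0] + [z0 + step * np.eye(len(z0))[i] for i in range(len(z0))])
        res = sciopt.minimize(
            obj, z0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2,
                     "initial_simplex": simplex, "adaptive": True},
        )
        runs.append({"x": _from_internal(res.x, names), "fun": float(res.fun)})

    if stage_runs[0] > 0:
        cands = [_random_start(names, wide, rng) for _ in range(max(screen, stage_runs[0]))]
        scored = sorted(cands, key=lambda x: obj(_to_internal(x, names)))
        for x0 in scored[: stage_runs[0]]:
            do_run(x0)
        best1 = min(runs, key=lambda r: r["fun"])
        tight = _tighten(wide, best1["x"], names)
        do_run(best1["x"], step=0.3)
    for p in extra_starts or []:
        if p.model_id != model_id:
            p = embed_params(p, model_id)
        do_run(p.vector(), step=0.3)
    if stage_runs[0] > 0:
        for _ in range(stage_runs[1]):
            do_run(_random_start(names, tight, rng), step=0.4)
    if not runs:
        raise ValueError("no optimization runs requested")
    # polish restart from the incumbent
    do_run(min(runs, key=lambda r: r["fun"])["x"], step=0.15)

    best = min(runs, key=lambda r: r["fun"])
    params = ModelParams.from_vector(model_id, best["x"])
    ereps = eval_reps if eval_reps is not None else 8 * n_reps
    exp = expected_sfs(params, obs.n1, obs.n2, ereps, eval_seed, fold=obs.folded)
    ll, theta = poisson_loglik(obs, exp)
    return FitResult(
        params=params,
        loglik=ll,
        theta=theta,
        aic=aic(ll, params.k),
        provenance={
            "seed": seed,
            "fit_seed": fit_seed,
            "eval_seed": eval_seed,
            "n_reps": n_reps,
            "eval_reps": ereps,
            "stage_runs": list(stage_runs),
            "maxiter": maxiter,
            "n_runs": len(runs),
            "loglik_opt": -best["fun"],
        },
    )


def embed_params(
    fit_params: ModelParams | FitResult, target_model: str, exact: bool = False
) -> ModelParams:
    """Embed a simpler model's estimate as a starting point of a nested richer model.

    By default symmetric rates are split into near-equal class rates (the
    class proportion then starts unidentifiable, so it is seeded at 0.5 with
    a small rate contrast to break the tie for the optimizer); `exact=True`
    reproduces the simpler model exactly inside the richer one.
    """
    p = fit_params.params if isinstance(fit_params, FitResult) else fit_params
    v = p.values
    src, dst = p.model_id, target_model

    def base():
        return {"s": v.get("s", 0.5), "N1": v["N1"], "N2": v["N2"], "T": v["T"]}

    if (src, dst) == ("split_mig", "IM"):
        return ModelParams("IM", {**base(), "M": v["M"]})
    if (src, dst) == ("IM", "IM2"):
        return ModelParams("IM2", {**base(), "M1": v["M"], "M2": v["M"]})
    if (src, dst) == ("IM", "IM_2M"):
        f_lo, f_hi = (1.0, 1.0) if exact else (0.9, 1.1)
        return ModelParams(
            "IM_2M", {**base(), "MA": f_lo * v["M"], "MB": f_hi * v["M"], "P": 0.5}
        )
    if (src, dst) == ("IM2", "IM2_2M"):
        f_lo, f_hi = (1.0, 1.0) if exact else (0.9, 1.1)
        return ModelParams(
            "IM2_2M",
            {
                **base(),
                "MA1": f_lo * v["M1"], "MA2": f_lo * v["M2"],
                "MB1": f_hi * v["M1"], "MB2": f_hi * v["M2"],
                "P": 0.5,
            },
        )
    raise ValueError(f"no embedding {src} -> {dst}")


def low_migration_fraction(params: ModelParams) -> float:
    """Fraction of sites in the lower-migration class of a two-class model.

    The mixture likelihood is invariant to swapping class labels together
    with P -> 1-P, so the raw P is reported up to label switching; this
    canonicalizes it.
    """
    v = params.values
    if params.model_id == "IM_2M":
        a, b = v["MA"], v["MB"]
    elif params.model_id == "IM2_2M":
        a = 0.5 * (v["MA1"] + v["MA2"])
        b = 0.5 * (v["MB1"] + v["MB2"])
    else:
        raise ValueError(f"{params.model_id} has no migration classes")
    return v["P"] if a <= b else 1.0 - v["P"]


def collapse_params(fit_params: ModelParams | FitResult, target_model: str) -> ModelParams:
    """Project a richer model's estimate onto a nested simpler model.

    Class-specific migration rates collapse to their class-weighted mean,
    directional rates to their average.  Used to re-polish a null-model fit
    from the alternative's optimum so likelihood-ratio statistics measure
    model structure, not unequal optimization effort.
    """
    p = fit_params.params if isinstance(fit_params, FitResult) else fit_params
    v = p.values
    src, dst = p.model_id, target_model

    def base():
        return {"s": v.get("s", 0.5), "N1": v["N1"], "N2": v["N2"], "T": v["T"]}

    if (src, dst) == ("IM2_2M", "IM2"):
        return ModelParams("IM2", {
            **base(),
            "M1": v["P"] * v["MA1"] + (1 - v["P"]) * v["MB1"],
            "M2": v["P"] * v["MA2"] + (1 - v["P"]) * v["MB2"],
        })
    if (src, dst) == ("IM_2M", "IM"):
        return ModelParams("IM", {**base(), "M": v["P"] * v["MA"] + (1 - v["P"]) * v["MB"]})
    if (src, dst) == ("IM2", "IM"):
        return ModelParams("IM", {**base(), "M": 0.5 * (v["M1"] + v["M2"])})
    if (src, dst) == ("IM", "split_mig"):
        return ModelParams("split_mig", {"N1": v["N1"], "N2": v["N2"], "T": v["T"], "M": v["M"]})
    raise ValueError(f"no collapse {src} -> {dst}")


def nested_lrt(
    obs: JointSFS,
    null_id: str,
    alt_id: str,
    seed: int = 0,
    null_anchor: ModelParams | None = None,
    alt_anchor: ModelParams | None = None,
    **opt_kwargs,
) -> tuple[dict[str, FitResult], float, float]:
    """Likelihood-ratio test of nested models with symmetric optimization effort.

    Fits the null, fits the alternative seeded with the embedded null
    optimum, then symmetrizes optimization effort: the collapsed alternative
    optimum is evaluated as a null candidate (with one polish run when it
    improves the null), and the exactly-embedded final null as an
    alternative candidate.  Without this, the statistic measures which model
    got the luckier search, not model structure.  Both models share the seed
    and therefore the common-random-number streams, and all final
    log-likelihoods come from the same high-replicate evaluation seed.

    `null_anchor` / `alt_anchor` switch to anchored mode: instead of global
    multi-start searches, each model is locally optimized from the supplied
    anchor (plus the embedded counterpart).  Used by replicated simulation
    experiments where the true parameters are known and the question is the
    behavior of the statistic, not of the global search.
    """
    anchored = null_anchor is not None or alt_anchor is not None
    if anchored:
        local = {**opt_kwargs, "stage_runs": (0, 0)}
        null_extras = [null_anchor] if null_anchor is not None else []
        null_fit = optimize_model(null_id, obs, seed=seed, extra_starts=null_extras, **local)
        alt_extras = [embed_params(null_fit, alt_id)]
        if alt_anchor is not None:
            alt_extras.insert(0, alt_anchor)
        alt_fit = optimize_model(alt_id, obs, seed=seed, extra_starts=alt_extras, **local)
    else:
        null_fit = optimize_model(null_id, obs, seed=seed, **opt_kwargs)
        alt_fit = optimize_model(
            alt_id, obs, seed=seed, extra_starts=[embed_params(null_fit, alt_id)], **opt_kwargs
        )
    er = alt_fit.provenance["eval_reps"]
    es = alt_fit.provenance["eval_seed"]

    def evaluate(params: ModelParams) -> FitResult:
        exp = expected_sfs(params, obs.n1, obs.n2, er, es, fold=obs.folded)
        ll, theta = poisson_loglik(obs, exp)
        return FitResult(params=params, loglik=ll, theta=theta, aic=aic(ll, params.k),
                         provenance={"eval_reps": er, "eval_seed": es})

    # null side: adopt (and polish) the collapsed alternative basin if better
    collapsed = evaluate(collapse_params(alt_fit, null_id))
    if collapsed.loglik > null_fit.loglik:
        polish_kwargs = {**opt_kwargs, "stage_runs": (0, 0)}
        polished = optimize_model(
            null_id, obs, seed=seed, extra_starts=[collapsed.params], **polish_kwargs
        )
        null_fit = max((collapsed, polished), key=lambda f: f.loglik)
    # alternative side: never below its exactly-embedded null
    embedded = evaluate(embed_params(null_fit, alt_id, exact=True))
    if embedded.loglik > alt_fit.loglik:
        alt_fit = embedded
    stat, p = lrt(null_fit.loglik, alt_fit.loglik, alt_fit.params.k - null_fit.params.k)
    return {null_id: null_fit, alt_id: alt_fit}, stat, p


# nested chains used for model selection; each model is seeded with the
# embedded best fit of its parent
NESTED_PARENT = {"IM": "split_mig", "IM2": "IM", "IM_2M": "IM", "IM2_2M": "IM2"}


def fit_model_chain(
    obs: JointSFS,
    models: list[str],
    seed: int = 0,
    **opt_kwargs,
) -> dict[str, FitResult]:
    """Fit several models to one spectrum, seeding each with its nested parent.

    All models share one seed, hence the same common-random-number stream
    for likelihood evaluations: nested log-likelihood differences are then
    differences on correlated surfaces, which keeps likelihood-ratio
    statistics from being dominated by Monte-Carlo noise.
    """
    fits: dict[str, FitResult] = {}
    for m in models:
        extra = []
        parent = NESTED_PARENT.get(m)
        if parent in fits:
            extra.append(embed_params(fits[parent], m))
        fit = optimize_model(m, obs, seed=seed, extra_starts=extra, **opt_kwargs)
        if parent in fits:
            # a richer model is never reported below its exactly-embedded parent
            emb = embed_params(fits[parent], m, exact=True)
            exp = expected_sfs(
                emb, obs.n1, obs.n2,
                fit.provenance["eval_reps"], fit.provenance["eval_seed"],
                fold=obs.folded,
            )
            ll, theta = poisson_loglik(obs, exp)
            if ll > fit.loglik:
                fit = FitResult(params=emb, loglik=ll, theta=theta,
                                aic=aic(ll, emb.k), provenance=fit.provenance)
        fits[m] = fit
    return fits


def model_selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC ranking: delta-AIC vs the best model and relative likelihoods."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    rows = []
    best_aic = min(f.aic for f in fits)
    for f in fits:
        d = f.aic - best_aic
        f.delta_aic = d
        f.rel_like = math.exp(-d / 2.0)
        rows.append(
            {
                "model": f.model_id,
                "k": f.params.k,
                "loglik": f.loglik,
                "theta": f.theta,
                "aic": f.aic,
                "delta_aic": d,
                "rel_like": f.rel_like,
                "best": d == 0.0,
                **{f"param_{n}": v for n, v in f.params.values.items()},
            }
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def bootstrap_ci(
    model_id: str,
    best: FitResult,
    boot_spectra: list[JointSFS],
    seed: int = 0,
    n_starts: int = 5,
    n_reps: int | None = None,
    maxiter: int = 100,
) -> dict[str, tuple[float, float]]:
    """Per-parameter CI = M +/- 1.96 * SD of bootstrap-replicate refits.

    Each replicate is refit single-stage from `n_starts` starts perturbed
    around the point estimate M.
    """
    names = MODELS[model_id]
    reps = n_reps if n_reps is not None else best.provenance.get("n_reps", 1000)
    rng = np.random.default_rng(seed)
    estimates = []
    wide = {n: _param_range(n) for n in names}
    for b, spec in enumerate(boot_spectra):
        fit_seed = int(rng.integers(2**31))
        obj = _objective_factory(model_id, spec, reps, fit_seed, wide)
        best_run = None
        for _ in range(n_starts):
            x0 = best.params.vector().copy()
            for i, n in enumerate(names):
                if _is_logit(n):
                    x0[i] = min(max(x0[i] + rng.normal(0, 0.05), 0.02), 0.98)
                else:
                    lo, hi = wide[n]
                    x0[i] = min(max(x0[i] * math.exp(rng.normal(0, 0.3)), lo), hi)
            z0 = _to_internal(x0, names)
            simplex = np.vstack(
                [z0] + [z0 + 0.3 * np.eye(len(z0))[i] for i in range(len(z0))]
            )
            res = sciopt.minimize(
                obj, z0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2,
                         "initial_simplex": simplex},
            )
            if best_run is None or res.fun < best_run.fun:
                best_run = res
        estimates.append(_from_internal(best_run.x, names))
    est = np.array(estimates)
    if est.shape[0] < 50:
        warnings.warn(f"only {est.shape[0]} bootstrap replicates; CIs may be unstable")
    sd = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.zeros(len(names))
    m = best.params.vector()
    ci = {n: (float(m[i] - 1.96 * sd[i]), float(m[i] + 1.96 * sd[i])) for i, n in enumerate(names)}
    best.ci = ci
    return ci


def simulate_sfs_counts(
    params: ModelParams,
    theta: float,
    n1: int,
    n2: int,
    seed: int = 0,
    n_reps: int = 20000,
    fold: bool = False,
) -> JointSFS:
    """Poisson-sampled site counts around theta x expected spectrum.

    This simulates data exactly under the Poisson random field, for parameter
    recovery and likelihood-ratio calibration experiments.
    """
    rng = np.random.default_rng(seed)
    exp = expected_sfs(params, n1, n2, n_reps, int(rng.integers(2**31)), fold=fold)
    counts = rng.poisson(theta * exp.counts).astype(float)
    return JointSFS(counts, n1, n2, folded=exp.folded)
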