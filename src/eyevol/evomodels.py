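"""Phylogenetic signal and homogeneous-rate models of continuous evolution.

Implements Pagel's lambda with a full likelihood profile, and ML fits of the
five standard single-rate models — Brownian motion (BM), Ornstein-Uhlenbeck
(OU), early burst (EB), BM with a trend, and non-phylogenetic white noise —
compared by AICc and Akaike weights, with an optional sensitivity sweep over
a set of posterior trees.

Every model is expressed as a multivariate normal ``trait ~ N(mean(theta),
sigma2 * R(theta))``: the Brownian rate ``sigma2`` and the mean parameters
are profiled analytically, leaving at most one free covariance parameter to
a bounded scalar optimizer.  Log-likelihoods include all constants, so AICc
values are comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import Phylogeny, StructureParams, transform_structure, vcv_matrix
from .regression import _gls_profile_loglik

__all__ = [
    "EvoModelFit",
    "SignalEstimate",
    "MODELS",
    "pagel_lambda",
    "fit_continuous",
    "aicc_weights",
    "posterior_sensitivity",
]

MODELS = ("BM", "OU", "EB", "trend", "white")


@dataclass
class EvoModelFit:
    model: str
    params: dict
    loglik: float
    n_params: int
    aicc: float
    n: int
    converged: bool = True
    note: str = ""
    weight: float = float("nan")


@dataclass
class SignalEstimate:
    """Pagel's lambda with its likelihood profile and LRT against lambda=0."""

    lambda_hat: float
    loglik: float
    p_vs_zero: float
    profile: pd.DataFrame  # columns: lam, loglik

    def profile_csv(self, path) -> None:
        self.profile.to_csv(path, index=False)


def _align_trait(trait, tree: Phylogeny) -> np.ndarray:
    s = pd.Series(trait)
    missing = [t for t in tree.tips if t not in s.index]
    if missing:
        raise KeyError(f"trait missing for tips: {missing}")
    return s.loc[tree.tips].to_numpy(dtype=float)


def _aicc(ll: float, k: int, n: int) -> float:
    aic = -2.0 * ll + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------- #
# Pagel's lambda
# ---------------------------------------------------------------------- #

def pagel_lambda(trait, tree: Phylogeny, grid_points: int = 101) -> SignalEstimate:
    """ML estimate of Pagel's lambda for one continuous trait.

    The mean and Brownian rate are profiled analytically at each lambda; the
    profile is scanned on a grid over [0, 1] and the maximum refined by
    bounded Brent.  ``p_vs_zero`` is the chi-square(1) likelihood-ratio test
    against the star-phylogeny model (lambda = 0).
    """
    y = _align_trait(trait, tree)
    if len(y) < 4:
        raise ValueError("need at least 4 species")
    if np.ptp(y) == 0:
        raise ValueError("constant trait has no definable signal")
    C = vcv_matrix(tree)
    X = np.ones((len(y), 1))

    def ll_at(lam: float) -> float:
        R = transform_structure(C, tree, StructureParams("lambda", lam=lam)).matrix
        return _gls_profile_loglik(R, X, y)[0]

    lams = np.linspace(0.0, 1.0, grid_points)
    profile = np.array([ll_at(l) for l in lams])
    j = int(np.argmax(profile))
    lo, hi = lams[max(j - 1, 0)], lams[min(j + 1, grid_points - 1)]
    res = optimize.minimize_scalar(lambda l: -ll_at(l), bounds=(lo, hi),
                                   method="bounded", options={"xatol": 1e-8})
    lam_hat, ll_hat = float(res.x), float(-res.fun)
    for b, llb in ((0.0, profile[0]), (1.0, profile[-1])):
        if llb >= ll_hat:
            lam_hat, ll_hat = b, float(llb)
    p = float(stats.chi2.sf(max(2.0 * (ll_hat - profile[0]), 0.0), df=1))
    return SignalEstimate(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        p_vs_zero=p,
        profile=pd.DataFrame({"lam": lams, "loglik": profile}),
    )


# ---------------------------------------------------------------------- #
# homogeneous-rate model fits
# ---------------------------------------------------------------------- #

def fit_continuous(
    trait,
    tree: Phylogeny,
    model: str,
    alpha_bounds: tuple | None = None,
    r_eb_bounds: tuple | None = None,
) -> EvoModelFit:
    """ML fit of one homogeneous-rate model of continuous trait evolution.

    Parameter counts: BM and white estimate (z0, sigma2); OU adds alpha, EB
    adds the decay r, trend adds the drift mu.  The trend model's mean is
    ``z0 + mu * depth_i`` and is unidentifiable on an ultrametric tree; such
    fits are returned flagged as not converged and are excluded from Akaike
    weights.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    y = _align_trait(trait, tree)
    n = len(y)
    C = vcv_matrix(tree)
    height = tree.root_height
    ones = np.ones((n, 1))

    def fit_fixed(kind: str, **kw):
        R = transform_structure(C, tree, StructureParams(kind, **kw)).matrix
        X = ones
        if kind == "trend":
            X = np.column_stack([ones, tree.tip_depths])
        return _gls_profile_loglik(R, X, y)

    if model in ("BM", "white"):
        ll, beta, s2, _ = fit_fixed(model)
        params = {"z0": float(beta[0]), "sigma2": float(s2)}
        k = 2
        return EvoModelFit(model, params, float(ll), k, _aicc(ll, k, n), n)

    if model == "trend":
        depths = tree.tip_depths
        if np.ptp(depths) < 1e-8 * max(height, 1e-300):
            return EvoModelFit(
                model, {}, float("-inf"), 3, float("inf"), n,
                converged=False,
                note="trend drift unidentifiable on an ultrametric tree",
            )
        ll, beta, s2, _ = fit_fixed("trend")
        params = {"z0": float(beta[0]), "mu": float(beta[1]), "sigma2": float(s2)}
        k = 3
        return EvoModelFit(model, params, float(ll), k, _aicc(ll, k, n), n)

    # OU / EB: one bounded scalar parameter.  The default alpha ceiling
    # keeps the phylogenetic half-life above ~7% of tree height: beyond it
    # the OU covariance is statistically indistinguishable from white
    # noise at these sample sizes and the fit degenerates onto that ridge.
    if model == "OU":
        lo, hi = alpha_bounds or (1e-8, 10.0 / height)
        key = "alpha"
    else:
        lo, hi = r_eb_bounds or (-10.0 / height, -1e-12)
        key = "r_eb"

    def negll(v: float) -> float:
        return -fit_fixed(model, **{key: v})[0]

    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    best_v, best_ll = float(res.x), float(-res.fun)
    for b in (lo, hi):
        llb = -negll(b)
        if llb > best_ll:
            best_v, best_ll = b, llb
    ll, beta, s2, _ = fit_fixed(model, **{key: best_v})
    params = {"z0": float(beta[0]), "sigma2": float(s2), key: best_v}
    k = 3
    converged = bool(res.success)
    note = "" if converged else "optimizer did not converge"
    return EvoModelFit(model, params, float(ll), k, _aicc(ll, k, n), n,
                       converged=converged, note=note)


def aicc_weights(fits) -> pd.Series:
    """Akaike weights over converged fits: ``w_i = exp(-d_i/2)/sum(...)``.

    Non-converged fits keep weight NaN and do not enter the normalization.
    The returned Series is indexed by model name; weights are also written
    back onto the fit objects.
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not ok:
        raise ValueError("no converged fits to weight")
    aiccs = np.array([f.aicc for f in ok])
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(ok, w):
        f.weight = float(wi)
    return pd.Series({f.model: f.weight for f in fits})


def fits_table(fits) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"model": f.model, "loglik": f.loglik, "k": f.n_params,
               "aicc": f.aicc, "weight": f.weight, "converged": f.converged,
               "note": f.note}
        row.update({f"param_{k}": v for k, v in f.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# posterior-tree sensitivity
# ---------------------------------------------------------------------- #

def posterior_sensitivity(trait, trees, op: str = "lambda") -> dict:
    """Replicate an analysis over a set of posterior trees.

    ``op='lambda'`` re-estimates Pagel's lambda per tree; ``op='best_model'``
    refits the five homogeneous-rate models and records the AICc-best one.
    Returns per-tree values plus a median and central 95% interval (or a
    modal-model tally).  Deterministic given tree order.
    """
    if op not in ("lambda", "best_model"):
        raise ValueError(f"unknown sensitivity op {op!r}")
    ref = set(trees[0].tips)
    for i, t in enumerate(trees):
        if set(t.tips) != ref:
            raise ValueError(f"tree {i} has a mismatched tip set")
    if op == "lambda":
        vals = np.array([pagel_lambda(trait, t, grid_points=21).lambda_hat
                         for t in trees])
        return {
            "op": op,
            "values": vals,
            "median": float(np.median(vals)),
            "q025": float(np.quantile(vals, 0.025)),
            "q975": float(np.quantile(vals, 0.975)),
        }
    best = []
    for t in trees:
        fits = [fit_continuous(trait, t, m) for m in MODELS]
        aicc_weights(fits)
        ok = [f for f in fits if f.converged]
        best.append(min(ok, key=lambda f: f.aicc).model)
    tally = pd.Series(best).value_counts()
    return {"op": op, "values": best, "tally": tally,
            "modal_model": tally.index[0]}
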