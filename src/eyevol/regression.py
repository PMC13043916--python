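"""Phylogenetic regressions: species-level PGLS and individual-level PGLMM.

Two regression engines share this module:

* :func:`fit_pgls` — generalized least squares on species means, with the
  error covariance following the phylogeny under a chosen structure (BM,
  Pagel's lambda, OU, EB, white).  The structure's free parameter can be
  profiled by maximum likelihood.
* :func:`fit_pglmm` — a phylogenetic linear mixed model on individuals:
  ``y ~ N(X beta, sigma2_phylo * Z C Z' + sigma2_resid * I)`` with ``C`` the
  species-level Brownian covariance and ``Z`` the species indicator matrix.
  Used for the allometry suite (forewing-length slope, sex and family
  effects) where within-species replication matters.

Both are fit by full maximum likelihood (not REML) so that AIC values are
comparable across different fixed-effect structures.  Likelihoods include
all normalization constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import Phylogeny, PhyloCovariance, StructureParams, transform_structure, vcv_matrix

__all__ = [
    "GlsFit",
    "MixedFit",
    "R2Partition",
    "fit_pgls",
    "fit_pglmm",
    "lrt",
    "residuals_relative_size",
    "r2_phylo",
    "FORMULAS",
]

FORMULAS = ("wing", "wing+sex", "wing*sex", "wing+family", "wing+family+sex")

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GlsFit:
    """A fitted phylogenetic GLS model."""

    structure: StructureParams
    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    sigma2: float
    n: int
    k: int
    species: list
    residuals: pd.Series  # raw response-scale residuals, keyed by species
    fitted: pd.Series
    profiled: bool = False
    boundary: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.coefficients, "se": self.se, "p": self.pvalues}
        )


@dataclass
class MixedFit:
    """A fitted phylogenetic linear mixed model (individual-level)."""

    formula: str
    fixed_effects: pd.Series
    se: pd.Series
    pvalues: pd.Series  # normal approximation; flagged approximate
    sigma2_phylo: float
    sigma2_resid: float
    loglik: float
    aic: float
    n_obs: int
    n_species: int

    @property
    def k(self) -> int:
        return len(self.fixed_effects) + 2

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"estimate": self.fixed_effects, "se": self.se,
             "p_approx": self.pvalues}
        )
        return out


@dataclass
class R2Partition:
    """Likelihood-based partial R^2 between a phylogenetic and a
    non-phylogenetic fit of the same fixed effects."""

    r2_phylo_contribution: float
    loglik_full: float
    loglik_reduced: float
    flavor: str = "R2_lik"


# ---------------------------------------------------------------------- #
# PGLS
# ---------------------------------------------------------------------- #

def _gls_profile_loglik(R: np.ndarray, X: np.ndarray, y: np.ndarray):
    """ML log-likelihood with sigma2 profiled out of y ~ N(X b, sigma2 R)."""
    n = len(y)
    L = np.linalg.cholesky(R)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0) - 0.5 * logdet
    XtX = Xw.T @ Xw
    cov_beta = sigma2 * np.linalg.inv(XtX) * n / n  # ML sigma2
    return ll, beta, sigma2, cov_beta


def _gls_fixed_loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Log-likelihood of y ~ N(X b, V) with only beta profiled (V fully
    specified) — the path used when a known measurement-error diagonal
    makes the overall scale non-profilable."""
    n = len(y)
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * _LOG2PI + logdet + float(r @ r))
    cov_beta = np.linalg.inv(Xw.T @ Xw)
    return ll, beta, cov_beta


def fit_pgls(
    means: pd.DataFrame,
    C: PhyloCovariance,
    structure: StructureParams,
    predictors=("mean_log10_wing",),
    response: str = "mean_log10_eye",
    profile: bool = False,
    meas_var=None,
) -> GlsFit:
    """Fit a PGLS regression of species means under one correlation structure.

    ``means`` must carry a ``species`` column matching ``C.taxa`` as a set;
    rows are aligned to the covariance by label, never by position.  With
    ``profile=True`` the structure's free parameter (lambda, alpha or the EB
    decay) is optimized by ML; a boundary optimum is reported via the
    ``boundary`` flag, not hidden.

    ``meas_var`` (optional, keyed by species or a column name in ``means``)
    adds a known sampling-variance diagonal to the covariance — the
    measurement-error PGLS for species means built from few individuals.
    Ignoring that diagonal badly miscalibrates tests on trees with short
    terminal branches.
    """
    df = means.set_index("species")
    missing = set(C.taxa) ^ set(df.index)
    if missing:
        raise ValueError(f"species sets of means and covariance differ: {sorted(missing)}")
    df = df.loc[list(C.taxa)]
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["intercept"] + list(predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design: columns {names}")
    mv = None
    if meas_var is not None:
        if isinstance(meas_var, str):
            mv = df[meas_var].to_numpy(dtype=float)
        else:
            mv = pd.Series(meas_var).loc[list(C.taxa)].to_numpy(dtype=float)
        if np.any(mv < 0):
            raise ValueError("measurement variances must be >= 0")

    def build(par_value=None) -> np.ndarray:
        p = structure
        if par_value is not None:
            kw = {"lambda": "lam", "OU": "alpha", "EB": "r_eb"}.get(p.kind)
            if kw is None:
                raise ValueError(f"structure {p.kind} has no free parameter to profile")
            p = StructureParams(kind=p.kind, **{kw: par_value})
        return transform_structure(C, None, p).matrix / p.sigma2

    par_bounds = None
    if structure.kind in ("lambda", "OU", "EB"):
        height = float(np.max(np.diag(C.matrix)))
        par_bounds = {
            "lambda": (0.0, 1.0),
            "OU": (1e-8, 50.0 / height),
            "EB": (-10.0 / height, -1e-12),
        }[structure.kind]

    profiled_value = None
    boundary = False

    if mv is not None:
        # sigma2 no longer profiles analytically: optimize (par, log s2)
        def negll(par_value, log_s2):
            V = np.exp(log_s2) * build(par_value) + np.diag(mv)
            return -_gls_fixed_loglik(V, X, y)[0]

        s2_init = np.log(max(_gls_profile_loglik(build(), X, y)[2], 1e-10))

        def s2_opt(par_value):
            res = optimize.minimize_scalar(
                lambda ls: negll(par_value, ls),
                bounds=(s2_init - 12.0, s2_init + 12.0), method="bounded",
                options={"xatol": 1e-9})
            return float(res.fun), float(res.x)

        if profile and par_bounds is not None:
            res = optimize.minimize_scalar(
                lambda v: s2_opt(v)[0], bounds=par_bounds, method="bounded",
                options={"xatol": 1e-6})
            profiled_value = float(res.x)
            for b in par_bounds:
                if s2_opt(b)[0] < s2_opt(profiled_value)[0]:
                    profiled_value = b
            boundary = profiled_value in par_bounds
            kw = {"lambda": "lam", "OU": "alpha", "EB": "r_eb"}[structure.kind]
            structure = StructureParams(kind=structure.kind,
                                        **{kw: profiled_value})
        _, ls_hat = s2_opt(profiled_value)
        sigma2 = float(np.exp(ls_hat))
        V = sigma2 * build(profiled_value) + np.diag(mv)
        ll, beta, cov_beta = _gls_fixed_loglik(V, X, y)
        k = X.shape[1] + 1 + (structure.n_free if profiled_value is not None
                              else 0)
        se = np.sqrt(np.diag(cov_beta))
        tvals = beta / se
        dof = max(len(y) - X.shape[1], 1)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        fitted = X @ beta
        return GlsFit(
            structure=structure,
            coefficients=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            pvalues=pd.Series(pvals, index=names),
            loglik=float(ll),
            aic=float(-2.0 * ll + 2.0 * k),
            sigma2=sigma2,
            n=len(y),
            k=k,
            species=list(C.taxa),
            residuals=pd.Series(y - fitted, index=list(C.taxa)),
            fitted=pd.Series(fitted, index=list(C.taxa)),
            profiled=profiled_value is not None,
            boundary=boundary,
        )

    if profile and par_bounds is not None:
        lo, hi = par_bounds
        res = optimize.minimize_scalar(
            lambda v: -_gls_profile_loglik(build(v), X, y)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        profiled_value = float(res.x)
        # also test the exact boundaries (bounded Brent stays interior)
        for b in (lo, hi):
            if _gls_profile_loglik(build(b), X, y)[0] > -res.fun:
                profiled_value = b
        boundary = profiled_value in (lo, hi)
        kw = {"lambda": "lam", "OU": "alpha", "EB": "r_eb"}[structure.kind]
        structure = StructureParams(kind=structure.kind, **{kw: profiled_value})

    R = build()
    ll, beta, sigma2, cov_beta = _gls_profile_loglik(R, X, y)
    k = X.shape[1] + 1 + (structure.n_free if (profile or profiled_value is not None) else 0)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    dof = max(len(y) - X.shape[1], 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    fitted = X @ beta
    return GlsFit(
        structure=structure,
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        sigma2=float(sigma2),
        n=len(y),
        k=k,
        species=list(C.taxa),
        residuals=pd.Series(y - fitted, index=list(C.taxa)),
        fitted=pd.Series(fitted, index=list(C.taxa)),
        profiled=profiled_value is not None,
        boundary=boundary,
    )


# ---------------------------------------------------------------------- #
# PGLMM
# ---------------------------------------------------------------------- #

def _design_matrix(df: pd.DataFrame, formula: str, reference_family: str | None):
    """Fixed-effect design for the allometry formula presets.

    Family uses treatment coding with the reference family (Hesperiidae when
    present) absorbed into the intercept.  The three-way wing x family x sex
    model is deliberately not offered.
    """
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    n = len(df)
    cols = {"intercept": np.ones(n), "log10_wing": df["log10_wing"].to_numpy(float)}
    if "sex" in formula:
        cols["sex_male"] = (df["sex"] == "male").to_numpy(float)
    if formula == "wing*sex":
        cols["log10_wing:sex_male"] = cols["log10_wing"] * cols["sex_male"]
    if "family" in formula:
        fams = sorted(df["family"].unique())
        if reference_family is None:
            reference_family = "Hesperiidae" if "Hesperiidae" in fams else fams[0]
        for fam in fams:
            if fam != reference_family:
                cols[f"family_{fam}"] = (df["family"] == fam).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"non-identifiable design (collinear columns) among {names}")
    return X, names


def fit_pglmm(
    records: pd.DataFrame,
    tree: Phylogeny,
    formula: str = "wing",
    response: str = "log10_eye",
    reference_family: str | None = None,
) -> MixedFit:
    """Fit the individual-level phylogenetic mixed model by ML.

    The marginal model is ``y ~ N(X beta, sigma2_p Z C Z' + sigma2_e I)``
    with ``C`` the Brownian species covariance of the (pruned) tree and
    ``Z`` the individuals-to-species indicator.  The variance ratio
    ``gamma = sigma2_p / sigma2_e`` is profiled on a log grid with Brent
    refinement; beta and the residual variance have closed forms given
    gamma.  Species missing from the tree raise — they are never dropped.
    """
    species = sorted(records["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    unmatched = [s for s in species if s not in set(tree.tips)]
    if unmatched:
        raise ValueError(f"species not on tree (prune/fix first): {unmatched}")
    if set(tree.tips) != set(species):
        from .phylo import prune_to_taxa

        tree = prune_to_taxa(tree, species)
    C = vcv_matrix(tree)
    order = {s: i for i, s in enumerate(C.taxa)}
    sp_idx = records["species"].map(order).to_numpy()

    y = records[response].to_numpy(dtype=float)
    X, names = _design_matrix(records, formula, reference_family)
    n, p = X.shape

    K = C.matrix[np.ix_(sp_idx, sp_idx)]  # Z C Z'
    evals, U = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def negll(log_gamma: float) -> float:
        return -_pglmm_profile(np.exp(log_gamma), evals, Xt, yt)[0]

    def _pglmm_profile(gamma, d, Xt, yt):
        w = 1.0 / (gamma * d + 1.0)
        Xw = Xt * w[:, None]
        XtVX = Xt.T @ Xw
        XtVy = Xw.T @ yt
        beta = np.linalg.solve(XtVX, XtVy)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        s2e = rss / n
        ll = -0.5 * n * (_LOG2PI + np.log(s2e) + 1.0) - 0.5 * np.sum(
            np.log(gamma * d + 1.0)
        )
        return ll, beta, s2e, XtVX

    # coarse log-grid then local refinement; gamma = 0 boundary checked too
    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([negll(g) for g in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    ll0 = _pglmm_profile(1e-300, evals, Xt, yt)[0]  # effectively gamma = 0
    if ll0 >= -res.fun:
        gamma = 0.0
    ll, beta, s2e, XtVX = _pglmm_profile(max(gamma, 1e-300), evals, Xt, yt)
    cov_beta = s2e * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    k = p + 2
    return MixedFit(
        formula=formula,
        fixed_effects=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_phylo=float(gamma * s2e),
        sigma2_resid=float(s2e),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        n_obs=n,
        n_species=len(species),
    )


def fit_lm(records: pd.DataFrame, formula: str = "wing",
           response: str = "log10_eye",
           reference_family: str | None = None) -> MixedFit:
    """Ordinary (non-phylogenetic) ML regression on individuals.

    The reduced model of the phylogeny R^2 partition: same fixed effects as
    :func:`fit_pglmm` but i.i.d. errors and no species random effect.
    Returned in the MixedFit container with ``sigma2_phylo = 0``.
    """
    y = records[response].to_numpy(dtype=float)
    X, names = _design_matrix(records, formula, reference_family)
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    s2 = float(r @ r) / n
    ll = -0.5 * n * (_LOG2PI + np.log(s2) + 1.0)
    cov_beta = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_beta))
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    k = p + 1
    return MixedFit(
        formula=formula,
        fixed_effects=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_phylo=0.0,
        sigma2_resid=s2,
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        n_obs=n,
        n_species=records["species"].nunique(),
    )


# ---------------------------------------------------------------------- #
# tests and partitions
# ---------------------------------------------------------------------- #

def lrt(fit_full, fit_reduced, df: int) -> float:
    """Likelihood-ratio p-value for nested ML fits on identical data."""
    delta = fit_full.loglik - fit_reduced.loglik
    if delta < -1e-6:
        raise ValueError(
            f"nesting violated: full loglik {fit_full.loglik:.6f} < "
            f"reduced {fit_reduced.loglik:.6f}"
        )
    stat = max(2.0 * delta, 0.0)
    return float(stats.chi2.sf(stat, df))


def residuals_relative_size(fit: GlsFit) -> pd.Series:
    """Relative eye size: raw PGLS residuals keyed by species.

    Requires the Brownian-motion structure, matching the downstream use of
    these residuals for phylogenetic signal and rate analyses; residuals
    from other structures would carry a different covariance meaning.
    """
    if fit.structure.kind != "BM":
        raise ValueError("relative-size residuals are defined for the BM fit")
    return fit.residuals.copy()


def r2_phylo(full_phylo, reduced_nonphylo) -> R2Partition:
    """Likelihood-based partial R^2 for the phylogenetic variance component.

    ``R2_lik = 1 - exp(-(2/n) * (loglik_full - loglik_reduced))``, clipped to
    [0, 1].  Both fits must share fixed effects and data and be ML fits.
    """
    n = getattr(full_phylo, "n_obs", None) or full_phylo.n
    ll_f, ll_r = full_phylo.loglik, reduced_nonphylo.loglik
    if ll_r > ll_f + 1e-6:
        raise ValueError("nesting violated: non-phylogenetic fit has higher loglik")
    r2 = 1.0 - np.exp(-(2.0 / n) * max(ll_f - ll_r, 0.0))
    return R2Partition(float(np.clip(r2, 0.0, 1.0)), float(ll_f), float(ll_r))
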