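"""Heterogeneous-rate models: Bayesian variable-rates regression and
penalized-likelihood multi-rate Brownian motion.

The variable-rates model regresses species-mean eye size on forewing length
under a Brownian covariance whose branch lengths carry multiplicative rate
scalars ``r`` (r > 1: faster than the background rate; r < 1: slower;
r = 1: background).  A reversible-jump MCMC explores which branches or
whole clades carry a scalar: shifts are born and die on discrete "slots"
(one branch slot and one clade slot per eligible node), each occupied
independently a priori with a small probability so the expected number of
active shifts is ~1, and scalar values follow a gamma(shape 1.1) prior
rescaled so the prior median is exactly 1.  Regression coefficients are
uniform on [-100, 100] and Pagel's lambda uniform on [0, 1].

Model comparison uses the stepping-stone estimate of the log marginal
likelihood over a Beta(0.3, 1)-spaced power-posterior ladder, and the Bayes
factor ``2 * (log ml complex - log ml simple)``.

The penalized-likelihood alternative (:func:`multirate_bm`) estimates one
log rate per node, with edge rates the mean of their endpoint node values,
maximizing ``loglik(trait | rates) + lambda_pen * loglik(log-rates | BM)``;
larger penalties shrink the rate surface toward homogeneity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotrs

from .phylo import Phylogeny, write_newick


def _chol(V):
    """Raw LAPACK Cholesky: the sampler calls this hundreds of thousands
    of times, so the scipy wrapper overhead matters."""
    c, info = dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"covariance not positive definite ({info})")
    return c


def _chol_solve(c, b):
    x, info = dpotrs(c, b, lower=1)
    return x

logger = logging.getLogger(__name__)

__all__ = [
    "VarRatesConfig",
    "VarRatesPosterior",
    "MultiRateFit",
    "scalar_prior_scale",
    "sample_scalar_prior",
    "varrates_loglik",
    "varrates_mcmc",
    "marginal_likelihood",
    "stepping_stone_logml",
    "power_ladder",
    "bayes_factor",
    "mcmc_diagnostics",
    "consensus_scaled_tree",
    "multirate_bm",
]

_LOG2PI = np.log(2.0 * np.pi)
_GAMMA_SHAPE = 1.1


def scalar_prior_scale(shape: float = _GAMMA_SHAPE) -> float:
    """Gamma scale rescaled so the prior median of a rate scalar is 1."""
    return 1.0 / stats.gamma.ppf(0.5, a=shape)


def sample_scalar_prior(n: int, rng: np.random.Generator,
                        shape: float = _GAMMA_SHAPE) -> np.ndarray:
    return rng.gamma(shape, scalar_prior_scale(shape), size=n)


@dataclass
class VarRatesConfig:
    """Sampler settings.  The defaults are a desk-scale configuration
    (3 chains x 200k single-proposal iterations); heavier runs are obtained
    by overriding fields."""

    n_chains: int = 3
    n_iterations: int = 200_000
    burnin: int = 20_000
    thinning: int = 20
    seed: int = 0
    rj_enabled: bool = True
    param_move_prob: float = 0.5   # parameter vs reversible-jump move
    birth_prob: float = 0.25       # within rj moves
    death_prob: float = 0.25
    clade_prob: float = 0.5        # clade vs single-branch slot on birth
    expected_shifts: float = 8.0   # prior mean number of active scalars;
                                   # deliberately permissive: reference
                                   # rjMCMC implementations carry many
                                   # diffuse scalars in their posteriors
    beta_bound: float = 100.0
    perturb_sd: float = 0.6        # log-normal rj value-perturbation SD
    birth_sd: float = 1.25         # log-normal SD of proposed newborn scalars
    beta_step: float = 0.1
    sigma2_step: float = 0.3
    lambda_step: float = 0.1
    power: float = 1.0             # likelihood temperature (stepping stone)

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be > 0")
        if not 0 <= self.burnin < self.n_iterations:
            raise ValueError("need burnin < n_iterations")


@dataclass
class VarRatesPosterior:
    """Thinned posterior samples, one table per chain, plus per-edge scalars.

    ``chains[c]`` has columns loglik, beta0, beta1, sigma2, lam, n_shifts;
    ``edge_rates[c]`` is (n_samples, n_edges) of effective per-branch r.
    Edges are identified by the preorder index of their child node
    (``edge_nodes``).
    """

    chains: list
    edge_rates: list
    edge_nodes: np.ndarray
    tree: Phylogeny
    config: VarRatesConfig
    log_marginal: float = float("nan")

    @property
    def n_samples(self) -> int:
        return sum(len(c) for c in self.chains)

    def stacked(self) -> pd.DataFrame:
        return pd.concat(self.chains, ignore_index=True)

    def edge_rate_matrix(self) -> np.ndarray:
        return np.vstack(self.edge_rates)

    def branch_rate_summary(self) -> pd.DataFrame:
        R = self.edge_rate_matrix()
        return pd.DataFrame(
            {
                "edge_node": self.edge_nodes,
                "median_r": np.median(R, axis=0),
                "mean_r": R.mean(axis=0),
                "q025": np.quantile(R, 0.025, axis=0),
                "q975": np.quantile(R, 0.975, axis=0),
            }
        )

    def to_table(self, path) -> None:
        """Plain-text posterior sample table, one labeled row per draw."""
        df = self.stacked()
        df.insert(0, "chain", np.repeat(range(len(self.chains)),
                                        [len(c) for c in self.chains]))
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- #
# model geometry
# ---------------------------------------------------------------------- #

class _TreeMachinery:
    """Edge masks and slot bookkeeping shared by likelihood and sampler."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        M_all = tree.tip_mask_below()
        self.edge_nodes = np.arange(1, tree.n_nodes)
        self.M = M_all[1:].astype(float)          # edges x tips
        self.bl = tree.length[1:].copy()
        self.stem = float(tree.length[0])  # root edge: shared, not scalable
        self.n_edges = len(self.bl)
        n_tips = tree.n_tips
        # clade slots: internal non-root nodes with >= 2 tips below
        tips_below = M_all.sum(axis=1)
        self.clade_nodes = np.array(
            [i for i in range(1, tree.n_nodes)
             if tree.children(i) and tips_below[i] >= 2],
            dtype=int,
        )
        # edges covered by a clade shift at v: its stem edge + all edges
        # below (a node is in v's subtree iff its tips are a subset of v's)
        self.clade_edges = {}
        for v in self.clade_nodes:
            below = [j for j, node in enumerate(self.edge_nodes)
                     if not (M_all[node] & ~M_all[v]).any()]
            self.clade_edges[v] = np.array(below, dtype=int)
        self.n_slots = self.n_edges + len(self.clade_nodes)

    def shift_edges(self, slot: int) -> np.ndarray:
        """Edge indices affected by a shift in the given slot."""
        if slot < self.n_edges:
            return np.array([slot], dtype=int)
        v = self.clade_nodes[slot - self.n_edges]
        return self.clade_edges[v]

    def rates_from_shifts(self, shifts: dict) -> np.ndarray:
        r = np.ones(self.n_edges)
        for slot, value in shifts.items():
            r[self.shift_edges(slot)] *= value
        return r


def _mvn_parts(V: np.ndarray, X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Cholesky, log|V| and the V^-1-quadratic of the residual."""
    cf = cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    resid = y - X @ beta
    quad = float(resid @ cho_solve(cf, resid, check_finite=False))
    return cf, logdet, quad


def varrates_loglik(
    tree: Phylogeny,
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    lam: float,
    edge_rates: np.ndarray | None = None,
) -> float:
    """Exact MVN log-likelihood of the variable-rates regression model.

    With all scalars equal to 1 this is the plain Brownian PGLS likelihood.
    """
    mach = _TreeMachinery(tree)
    r = np.ones(mach.n_edges) if edge_rates is None else np.asarray(edge_rates)
    w = r * mach.bl
    V = (mach.M * w[:, None]).T @ mach.M + mach.stem
    d = np.diag(V).copy()
    V = lam * V + np.diag((1.0 - lam) * d)
    _, logdet, quad = _mvn_parts(V, X, y, np.asarray(beta, dtype=float))
    n = len(y)
    return -0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet + quad / sigma2)


# ---------------------------------------------------------------------- #
# the sampler
# ---------------------------------------------------------------------- #

class _Chain:
    """One MCMC chain over (beta, sigma2, lambda, shift set)."""

    def __init__(self, mach, X, y, cfg: VarRatesConfig, rng):
        self.mach, self.X, self.y, self.cfg, self.rng = mach, X, y, cfg, rng
        self.n = len(y)
        self._diag_idx = np.arange(self.n) * (self.n + 1)
        self.prior_scale = scalar_prior_scale()
        # gamma(shape, scale) log-density, constants precomputed (hot path)
        from scipy.special import gammaln
        self._glogc = (-_GAMMA_SHAPE * math.log(self.prior_scale)
                       - float(gammaln(_GAMMA_SHAPE)))
        self.pi_slot = min(cfg.expected_shifts / mach.n_slots, 0.5)
        # sigma2 prior: uniform(0, S) with S generous relative to the data
        V0 = (mach.M * mach.bl[:, None]).T @ mach.M + mach.stem
        self.sigma2_cap = 1000.0 * float(np.var(y) / np.mean(np.diag(V0)))
        # initial state
        self.beta = np.zeros(X.shape[1])
        self.beta[0] = float(np.mean(y))
        self.sigma2 = float(np.var(y) / np.mean(np.diag(V0))) + 1e-12
        self.lam = 0.5
        self.shifts: dict = {}
        self._rebuild_cov()
        self._refresh_quad()

    # -- cached covariance pieces ------------------------------------- #
    def _rebuild_cov(self):
        mach = self.mach
        r = mach.rates_from_shifts(self.shifts)
        w = r * mach.bl
        V = (mach.M * w[:, None]).T @ mach.M + mach.stem
        self._V_raw = V
        self._cf, self._logdet = self._apply_lambda(self.lam)

    def _apply_lambda(self, lam):
        V = self._V_raw
        Vl = lam * V
        idx = self._diag_idx
        Vl.flat[idx] = V.flat[idx]  # diagonal untouched by lambda
        cf = _chol(Vl)
        return cf, 2.0 * float(np.sum(np.log(np.diagonal(cf))))

    def _quad(self, beta, cf):
        resid = self.y - self.X @ beta
        return float(resid @ _chol_solve(cf, resid))

    def _refresh_quad(self):
        self.quad = self._quad(self.beta, self._cf)

    def loglik(self, sigma2=None, logdet=None, quad=None) -> float:
        sigma2 = self.sigma2 if sigma2 is None else sigma2
        logdet = self._logdet if logdet is None else logdet
        quad = self.quad if quad is None else quad
        return -0.5 * (self.n * (_LOG2PI + math.log(sigma2)) + logdet
                       + quad / sigma2)

    # -- moves ---------------------------------------------------------- #
    def _accept(self, log_ratio: float) -> bool:
        return math.log(self.rng.random()) < log_ratio

    def _step_scale(self) -> float:
        # widen random-walk steps at low likelihood temperature so the
        # power-posterior rungs near the prior still mix
        return 1.0 / np.sqrt(max(self.cfg.power, 0.01))

    def _sample_prior_state(self):
        """Independent draw from the joint prior (used as the exact
        power-0 rung of the stepping-stone ladder)."""
        rng = self.rng
        self.beta = rng.uniform(-self.cfg.beta_bound, self.cfg.beta_bound,
                                size=len(self.beta))
        self.sigma2 = rng.uniform(0.0, self.sigma2_cap)
        self.lam = rng.uniform(0.0, 1.0)
        self.shifts = {}
        if self.cfg.rj_enabled:
            occ = rng.random(self.mach.n_slots) < self.pi_slot
            for slot in np.nonzero(occ)[0]:
                self.shifts[int(slot)] = float(
                    rng.gamma(_GAMMA_SHAPE, self.prior_scale))
        self._rebuild_cov()
        self._refresh_quad()

    def step(self):
        cfg, rng = self.cfg, self.rng
        if cfg.power == 0.0:
            self._sample_prior_state()
            return
        if (not cfg.rj_enabled) or rng.random() < cfg.param_move_prob:
            which = rng.integers(0, len(self.beta) + 2)
            if which < len(self.beta):
                self._move_beta(int(which))
            elif which == len(self.beta):
                self._move_sigma2()
            else:
                self._move_lambda()
        else:
            u = rng.random()
            if u < cfg.birth_prob:
                self._move_birth()
            elif u < cfg.birth_prob + cfg.death_prob:
                self._move_death()
            else:
                self._move_perturb()

    def _move_beta(self, j: int):
        step = min(self.cfg.beta_step * self._step_scale(),
                   0.3 * self.cfg.beta_bound)
        prop = self.beta.copy()
        prop[j] += self.rng.normal(0.0, step)
        if abs(prop[j]) > self.cfg.beta_bound:
            return
        quad = self._quad(prop, self._cf)
        ll_new = self.loglik(quad=quad)
        if self._accept(self.cfg.power * (ll_new - self.loglik())):
            self.beta, self.quad = prop, quad

    def _move_sigma2(self):
        step = min(self.cfg.sigma2_step * self._step_scale(), 3.0)
        prop = self.sigma2 * np.exp(self.rng.normal(0.0, step))
        if not (0.0 < prop < self.sigma2_cap):
            return
        ll_ratio = self.loglik(sigma2=prop) - self.loglik()
        # log-scale proposal Jacobian: q(s->s') / q(s'->s) = s'/s
        if self._accept(self.cfg.power * ll_ratio + np.log(prop / self.sigma2)):
            self.sigma2 = prop

    def _move_lambda(self):
        step = min(self.cfg.lambda_step * self._step_scale(), 0.5)
        prop = self.lam + self.rng.normal(0.0, step)
        prop = abs(prop)
        if prop > 1.0:
            prop = 2.0 - prop
        if not (0.0 <= prop <= 1.0):
            return
        cf, logdet = self._apply_lambda(prop)
        quad = self._quad(self.beta, cf)
        ll_new = self.loglik(logdet=logdet, quad=quad)
        if self._accept(self.cfg.power * (ll_new - self.loglik())):
            self.lam = prop
            self._cf, self._logdet, self.quad = cf, logdet, quad

    def _rj_try(self, new_shifts: dict, log_extra: float):
        old = self.shifts
        old_state = (self._V_raw, self._cf, self._logdet, self.quad)
        ll_old = self.loglik()
        self.shifts = new_shifts
        self._rebuild_cov()
        quad = self._quad(self.beta, self._cf)
        ll_new = self.loglik(quad=quad)
        if self._accept(self.cfg.power * (ll_new - ll_old) + log_extra):
            self.quad = quad
            return
        self.shifts = old
        self._V_raw, self._cf, self._logdet, self.quad = old_state

    def _birth_slot_prob(self, free: list, slot: int) -> float:
        """Exact probability that a birth move proposes ``slot`` given the
        free-slot set (clade vs branch chosen first, w.p. clade_prob, with
        fallback to the whole free set when the chosen kind is empty)."""
        c = self.cfg.clade_prob
        clades = [s for s in free if s >= self.mach.n_edges]
        branches = [s for s in free if s < self.mach.n_edges]
        p = 0.0
        for kind_p, pool in ((c, clades), ((1.0 - c), branches)):
            target = pool if pool else free
            if slot in target:
                p += kind_p / len(target)
        return p

    def _birth_value_logq(self, v: float) -> float:
        """Log density of the newborn-scalar proposal: log-normal(0,
        birth_sd), heavier-tailed than the gamma prior so large shifts are
        reachable in one jump (corrected for in the Hastings ratio)."""
        s = self.cfg.birth_sd
        lv = math.log(v)
        return -lv - 0.5 * math.log(2.0 * math.pi * s * s) \
            - lv * lv / (2.0 * s * s)

    def _move_birth(self):
        mach, rng = self.mach, self.rng
        free = [s for s in range(mach.n_slots) if s not in self.shifts]
        if not free:
            return
        clades = [s for s in free if s >= mach.n_edges]
        branches = [s for s in free if s < mach.n_edges]
        pool = clades if rng.random() < self.cfg.clade_prob else branches
        if not pool:
            pool = free
        slot = pool[rng.integers(len(pool))]
        value = float(math.exp(rng.normal(0.0, self.cfg.birth_sd)))
        k = len(self.shifts)
        log_prior = (math.log(self.pi_slot) - math.log(1.0 - self.pi_slot)
                     + self._gamma_logpdf(value))
        q_fwd = self._birth_slot_prob(free, slot)
        q_rev = 1.0 / (k + 1)  # death picks uniformly among occupied slots
        log_hastings = (math.log(q_rev) - math.log(q_fwd)
                        - self._birth_value_logq(value))
        new = dict(self.shifts)
        new[slot] = value
        self._rj_try(new, log_prior + log_hastings)

    def _move_death(self):
        rng = self.rng
        if not self.shifts:
            return
        k = len(self.shifts)
        slot = list(self.shifts)[rng.integers(k)]
        value = self.shifts[slot]
        free_after = [s for s in range(self.mach.n_slots)
                      if s not in self.shifts or s == slot]
        log_prior = (math.log(1.0 - self.pi_slot) - math.log(self.pi_slot)
                     - self._gamma_logpdf(value))
        q_fwd = 1.0 / k
        q_rev = (self._birth_slot_prob(free_after, slot)
                 * math.exp(self._birth_value_logq(value)))
        new = dict(self.shifts)
        del new[slot]
        self._rj_try(new, log_prior + math.log(q_rev) - math.log(q_fwd))

    def _gamma_logpdf(self, v: float) -> float:
        return ((_GAMMA_SHAPE - 1.0) * math.log(v) - v / self.prior_scale
                + self._glogc)

    def _move_perturb(self):
        rng = self.rng
        if not self.shifts:
            return
        slot = list(self.shifts)[rng.integers(len(self.shifts))]
        v = self.shifts[slot]
        v_new = v * math.exp(rng.normal(0.0, self.cfg.perturb_sd))
        # log-normal proposal Jacobian: q ratio contributes v_new / v
        log_extra = (self._gamma_logpdf(v_new) - self._gamma_logpdf(v)
                     + math.log(v_new / v))
        new = dict(self.shifts)
        new[slot] = v_new
        self._rj_try(new, log_extra)

    # -- recording ------------------------------------------------------ #
    def record(self):
        """One thinned sample, rebased so the background rate is the rate
        of the typical branch.

        The likelihood is invariant to jointly multiplying sigma2 by c and
        dividing every scalar by c (the covariance is linear in the
        scalars), so the chain can drift along that ridge; samples are
        normalized by the median edge scalar, which pins r = 1 to the
        majority of branches — the background, in the model's own terms.
        """
        r = self.mach.rates_from_shifts(self.shifts)
        c = float(np.median(r))
        return (
            self.loglik(),
            *self.beta,
            self.sigma2 * c,
            self.lam,
            len(self.shifts),
            r / c,
        )


def _prepare_regression(means: pd.DataFrame, tree: Phylogeny,
                        response: str, predictor: str | None):
    df = means.set_index("species")
    missing = set(tree.tips) - set(df.index)
    if missing:
        raise ValueError(f"species missing from means: {sorted(missing)}")
    df = df.loc[tree.tips]
    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if predictor is None:
        X = np.ones((len(y), 1))
    else:
        X = np.column_stack([np.ones(len(y)), df[predictor].to_numpy(float)])
    return y, X


def varrates_mcmc(
    means: pd.DataFrame,
    tree: Phylogeny,
    config: VarRatesConfig | None = None,
    response: str = "mean_log10_eye",
    predictor: str | None = "mean_log10_wing",
) -> VarRatesPosterior:
    """Run the reversible-jump variable-rates regression sampler.

    ``means`` is a species-means table (see :func:`eyevol.traits.species_means`);
    the regression is response ~ predictor with phylogenetic covariance
    rebuilt each move from the active branch/clade rate scalars and the
    sampled Pagel's lambda.  Fully seeded and reproducible.
    """
    cfg = config or VarRatesConfig()
    y, X = _prepare_regression(means, tree, response, predictor)
    mach = _TreeMachinery(tree)
    logger.info("varrates: %d tips, %d edges, %d slots, seed=%d",
                tree.n_tips, mach.n_edges, mach.n_slots, cfg.seed)

    chains, rate_chains = [], []
    ss = np.random.SeedSequence(cfg.seed)
    for c, child in enumerate(ss.spawn(cfg.n_chains)):
        rng = np.random.default_rng(child)
        chain = _Chain(mach, X, y, cfg, rng)
        rows, rates = [], []
        accept_window = 0
        for it in range(cfg.n_iterations):
            chain.step()
            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thinning == 0:
                *scalars, r = chain.record()
                rows.append(scalars)
                rates.append(r)
        names = (["loglik"] + [f"beta{j}" for j in range(X.shape[1])]
                 + ["sigma2", "lam", "n_shifts"])
        chains.append(pd.DataFrame(rows, columns=names))
        rate_chains.append(np.array(rates))
        if cfg.rj_enabled and chains[-1]["n_shifts"].sum() == 0:
            logger.warning("chain %d: no rj shift ever accepted", c)
    return VarRatesPosterior(chains, rate_chains, mach.edge_nodes, tree, cfg)


# ---------------------------------------------------------------------- #
# marginal likelihood / Bayes factor
# ---------------------------------------------------------------------- #

def power_ladder(K: int, shape: float = 0.3) -> np.ndarray:
    """Temperatures beta_k = (k/K)^(1/shape), k = 0..K (Beta(0.3,1) spacing)."""
    if K < 2:
        raise ValueError("need at least 2 power posteriors")
    return (np.arange(K + 1) / K) ** (1.0 / shape)


def stepping_stone_logml(loglik_samples_at, K: int = 32,
                         shape: float = 0.3) -> float:
    """Generic stepping-stone estimator of the log marginal likelihood.

    ``loglik_samples_at(beta)`` must return an array of data log-likelihood
    values for draws from the power posterior with temperature ``beta``.
    Combines rungs as ``sum_k log mean exp((b_{k+1}-b_k) * ll_k)``.
    """
    betas = power_ladder(K, shape)
    total = 0.0
    for b_lo, b_hi in zip(betas[:-1], betas[1:]):
        ll = np.asarray(loglik_samples_at(b_lo), dtype=float)
        d = (b_hi - b_lo) * ll
        m = d.max()
        total += m + np.log(np.mean(np.exp(d - m)))
    return float(total)


def marginal_likelihood(
    means: pd.DataFrame,
    tree: Phylogeny,
    config: VarRatesConfig | None = None,
    K: int = 32,
    rung_iterations: int = 10_000,
    rung_burnin: int = 2_000,
    response: str = "mean_log10_eye",
    predictor: str | None = "mean_log10_wing",
) -> float:
    """Stepping-stone log marginal likelihood of the (variable- or
    homogeneous-rate, per ``config.rj_enabled``) regression model."""
    cfg = config or VarRatesConfig()
    y, X = _prepare_regression(means, tree, response, predictor)
    mach = _TreeMachinery(tree)

    def samples_at(beta_t: float) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, int(beta_t * 1e9) % (2**31)))
        )
        rcfg = replace(cfg, power=max(beta_t, 0.0))
        chain = _Chain(mach, X, y, rcfg, rng)
        out = np.empty(rung_iterations)
        for it in range(rung_burnin):
            chain.step()
        for it in range(rung_iterations):
            chain.step()
            out[it] = chain.loglik()
        return out

    return stepping_stone_logml(samples_at, K=K)


def bayes_factor(logml_complex: float, logml_simple: float) -> float:
    """``2 * (log ml complex - log ml simple)``; > 2 favors the complex
    (variable-rates) model."""
    if not (np.isfinite(logml_complex) and np.isfinite(logml_simple)):
        raise ValueError("marginal likelihoods must be finite")
    return 2.0 * (logml_complex - logml_simple)


# ---------------------------------------------------------------------- #
# diagnostics and summaries
# ---------------------------------------------------------------------- #

def mcmc_diagnostics(posterior: VarRatesPosterior,
                     params=("beta0", "beta1", "sigma2", "lam")) -> pd.DataFrame:
    """Per-parameter effective sample size and split-R-hat (arviz).

    With a single chain R-hat is reported as NaN (unavailable), ESS still
    computed.  Thresholds are the caller's business; the conventional
    targets are ESS > 1000 and R-hat in [1, 1.2].
    """
    import arviz as az

    present = [p for p in params if p in posterior.chains[0].columns]
    data = {p: np.stack([c[p].to_numpy() for c in posterior.chains])
            for p in present}
    idata = az.from_dict(posterior=data)
    rows = []
    multi = len(posterior.chains) >= 2
    ess = az.ess(idata)
    rhat = az.rhat(idata) if multi else None
    for p in present:
        rows.append({
            "parameter": p,
            "ess": float(ess[p].values),
            "rhat": float(rhat[p].values) if multi else float("nan"),
        })
    return pd.DataFrame(rows)


def consensus_scaled_tree(posterior: VarRatesPosterior,
                          tree: Phylogeny | None = None) -> Phylogeny:
    """Tree with each branch multiplied by the posterior mean of its scalar."""
    tree = tree or posterior.tree
    if posterior.n_samples == 0:
        raise ValueError("empty posterior")
    mean_r = posterior.edge_rate_matrix().mean(axis=0)
    new_len = tree.length.copy()
    new_len[1:] = new_len[1:] * mean_r
    return Phylogeny(tree.parent.copy(), new_len, list(tree.label))


# ---------------------------------------------------------------------- #
# penalized-likelihood multi-rate BM
# ---------------------------------------------------------------------- #

@dataclass
class MultiRateFit:
    lambda_pen: float
    edge_nodes: np.ndarray
    branch_sigma2: np.ndarray     # per-edge Brownian rate
    node_log_rates: np.ndarray    # per-node ln sigma2 (preorder)
    penalized_loglik: float
    loglik_data: float
    converged: bool

    def rate_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"edge_node": self.edge_nodes,
                             "sigma2": self.branch_sigma2})


def multirate_bm(trait, tree: Phylogeny, lambda_pen: float = 1.0) -> MultiRateFit:
    """Penalized-likelihood multi-rate Brownian motion.

    One log-rate ``eta`` is estimated per node; the rate on an edge is
    ``exp((eta_parent + eta_child)/2)``.  The objective is the exact MVN
    log-likelihood of the trait (ancestral state profiled) plus
    ``lambda_pen`` times the log-likelihood of the node log-rates
    themselves evolving by unit-rate BM along the tree.  Gradients are
    analytic.  The standard penalty sweep is {0.1, 1, 10, 50}.
    """
    if lambda_pen <= 0:
        raise ValueError("lambda_pen must be > 0")
    s = pd.Series(trait)
    y = s.loc[tree.tips].to_numpy(dtype=float)
    n = len(y)
    mach = _TreeMachinery(tree)
    M, bl = mach.M, mach.bl
    parent = tree.parent
    child_nodes = mach.edge_nodes

    ones = np.ones(n)

    def unpack(eta):
        edge_eta = 0.5 * (eta[parent[child_nodes]] + eta[child_nodes])
        return np.exp(edge_eta), edge_eta

    def objective(eta):
        rate, _ = unpack(eta)
        w = rate * bl
        V = (M * w[:, None]).T @ M + mach.stem
        cf = cho_factor(V, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi1 = cho_solve(cf, ones, check_finite=False)
        z0 = float(Vi1 @ y) / float(Vi1 @ ones)
        resid = y - z0
        u = cho_solve(cf, resid, check_finite=False)
        quad = float(resid @ u)
        ll = -0.5 * (n * _LOG2PI + logdet + quad)
        # gradient wrt per-edge rates: bl_e * m_e' G m_e,
        # G = 0.5 (u u' - V^-1); diag of M G M' without forming V^-1 fully
        Vi = cho_solve(cf, np.eye(n), check_finite=False)
        G = 0.5 * (np.outer(u, u) - Vi)
        grad_edge = bl * np.einsum("ei,ij,ej->e", M, G, M)
        grad_rate = grad_edge * rate  # d/d(edge_eta)
        grad_eta = np.zeros(tree.n_nodes)
        np.add.at(grad_eta, child_nodes, 0.5 * grad_rate)
        np.add.at(grad_eta, parent[child_nodes], 0.5 * grad_rate)
        # BM penalty on eta: sum over edges of N(d_eta; 0, bl)
        d_eta = eta[child_nodes] - eta[parent[child_nodes]]
        pen = -0.5 * np.sum(d_eta**2 / bl + np.log(2.0 * np.pi * bl))
        gpen = np.zeros(tree.n_nodes)
        np.add.at(gpen, child_nodes, -d_eta / bl)
        np.add.at(gpen, parent[child_nodes], d_eta / bl)
        obj = ll + lambda_pen * pen
        grad = grad_eta + lambda_pen * gpen
        return -obj, -grad, ll

    # init at the homogeneous ML rate
    V0 = (M * bl[:, None]).T @ M + mach.stem
    cf0 = cho_factor(V0, lower=True, check_finite=False)
    Vi1 = cho_solve(cf0, ones, check_finite=False)
    z0 = float(Vi1 @ y) / float(Vi1 @ ones)
    r0 = y - z0
    s2_hat = float(r0 @ cho_solve(cf0, r0, check_finite=False)) / n
    eta0 = np.full(tree.n_nodes, np.log(max(s2_hat, 1e-12)))

    res = optimize.minimize(
        lambda e: objective(e)[:2], eta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    _, _, ll_data = objective(res.x)
    rate, _ = unpack(res.x)
    return MultiRateFit(
        lambda_pen=lambda_pen,
        edge_nodes=child_nodes,
        branch_sigma2=rate,
        node_log_rates=res.x,
        penalized_loglik=float(-res.fun),
        loglik_data=float(ll_data),
        converged=bool(res.success),
    )
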