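"""End-to-end orchestration: load or simulate inputs, run every analysis
stage, and write tidy per-stage CSVs plus one machine-readable JSON summary.

Stages, in order: ``data`` (load/simulate), ``means`` (species averaging),
``allometry`` (the PGLMM formula suite, with and without the Hesperiidae
analogue), ``pgls`` (correlation-structure comparison, residuals, LRT,
phylogeny R2), ``signal`` (Pagel's lambda, the five-model AICc table,
posterior-tree sensitivity), ``varrates`` (rjMCMC + diagnostics +
consensus tree + penalized multi-rate BM), and ``habitat`` (segment
coverage, species medians, habitat PGLS, CWM regressions).  Any stage can
be toggled off; a failure halts the pipeline naming the stage, keeping
partial outputs.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phylo import (StructureParams, parse_newick, prune_to_taxa,
                    read_newick_file, read_posterior_trees, vcv_matrix,
                    write_newick)
from .traits import add_log10, load_traits, species_means
from .regression import (FORMULAS, fit_lm, fit_pgls, fit_pglmm, lrt,
                         r2_phylo, residuals_relative_size)
from .evomodels import (MODELS, aicc_weights, fit_continuous, fits_table,
                        pagel_lambda, posterior_sensitivity)
from .varrates import (VarRatesConfig, bayes_factor, consensus_scaled_tree,
                       marginal_likelihood, mcmc_diagnostics, multirate_bm,
                       varrates_mcmc)
from .habitat import (cwm_regression, cwm_table, habitat_pgls,
                      read_ascii_grid, read_segments_csv, segment_coverage,
                      species_habitat)
from .simulate import SimConfig, emit_fixture_dir

logger = logging.getLogger(__name__)

ALL_STAGES = ("data", "means", "allometry", "pgls", "signal", "varrates",
              "habitat")


@dataclass
class RunConfig:
    """Pipeline settings; see also :class:`eyevol.simulate.SimConfig`."""

    outdir: str = "eyevol_out"
    seed: int = 0
    synthetic: bool = True
    sim: dict = field(default_factory=dict)     # SimConfig overrides
    # input paths (used when synthetic is False)
    tree_path: str | None = None
    traits_path: str | None = None
    posterior_path: str | None = None
    raster_path: str | None = None
    segments_path: str | None = None
    occurrences_path: str | None = None
    stages: tuple = ALL_STAGES
    n_posterior_sample: int = 50    # trees used in the sensitivity sweep
    mcmc: dict = field(default_factory=dict)    # VarRatesConfig overrides
    marginal_k: int = 8
    marginal_iterations: int = 4000
    multirate_lambdas: tuple = (0.1, 1.0, 10.0, 50.0)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _florify(obj):
    """JSON-safe conversion of numpy scalars/arrays and pandas objects."""
    if isinstance(obj, dict):
        return {str(k): _florify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_florify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _florify(obj.to_dict())
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict.

    The summary (also written to ``summary.json``) has one block per
    executed stage; the seed, package version, and wall times are recorded.
    Identical config + seed reproduces identical results (timestamps aside).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    summary: dict = {"meta": {
        "version": __version__, "seed": config.seed,
        "python": platform.python_version(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }}
    t_wall = {}
    state: dict = {}

    def run_stage(name, fn):
        if name not in stages:
            logger.info("stage %s skipped", name)
            return
        t0 = time.time()
        try:
            block = fn()
        except Exception:
            logger.error("pipeline halted at stage %r", name)
            _write_summary(summary, out)
            raise
        t_wall[name] = round(time.time() - t0, 3)
        summary[name] = _florify(block)
        _write_summary(summary, out)

    # ------------------------------------------------------------------ #
    def stage_data():
        if config.synthetic:
            sim = SimConfig(seed=config.seed, **config.sim)
            state["sim"] = sim
            fixture = emit_fixture_dir(sim, out / "synthetic")
            state.update(fixture)
            state["records"] = add_log10(state["records"])
        else:
            state["tree"] = read_newick_file(config.tree_path)
            state["records"] = load_traits(config.traits_path,
                                           tree_tips=state["tree"].tips)
            if config.posterior_path:
                state["posterior"] = read_posterior_trees(config.posterior_path)
            if config.raster_path:
                state["raster"] = read_ascii_grid(config.raster_path)
                state["segments"] = read_segments_csv(config.segments_path)
                state["occurrences"] = pd.read_csv(config.occurrences_path)
        rec = state["records"]
        return {"n_records": len(rec), "n_species": rec["species"].nunique(),
                "n_tips": state["tree"].n_tips, "synthetic": config.synthetic}

    def stage_means():
        means = species_means(state["records"])
        keep = [t for t in state["tree"].tips if t in set(means["species"])]
        state["tree"] = prune_to_taxa(state["tree"], keep)
        state["means"] = means[means["species"].isin(keep)].reset_index(drop=True)
        state["C"] = vcv_matrix(state["tree"])
        state["means"].to_csv(out / "species_means.csv", index=False)
        return {"n_species": len(state["means"])}

    def stage_allometry():
        rec, tree = state["records"], state["tree"]
        fams = rec["family"].unique()
        block, rows = {}, []
        for formula in FORMULAS:
            fit = fit_pglmm(rec, tree, formula)
            rows.append({"formula": formula, "subset": "all",
                         "aic": fit.aic, "loglik": fit.loglik,
                         **{f"b_{k}": v for k, v in fit.fixed_effects.items()}})
            block[formula] = {"aic": fit.aic,
                              "coefficients": fit.fixed_effects}
            if formula == "wing":
                state["fit_global"] = fit
        if "Hesperiidae" in fams:
            sub = rec[rec["family"] != "Hesperiidae"]
            fit = fit_pglmm(sub, prune_to_taxa(tree, sub["species"].unique()),
                            "wing")
            rows.append({"formula": "wing", "subset": "no_hesperiidae",
                         "aic": fit.aic, "loglik": fit.loglik,
                         **{f"b_{k}": v for k, v in fit.fixed_effects.items()}})
            block["wing_no_hesperiidae"] = {
                "aic": fit.aic, "coefficients": fit.fixed_effects}
        # phylogeny R2: global phylogenetic fit vs plain (glm-style) OLS
        fit_np = fit_lm(rec, "wing")
        part = r2_phylo(state["fit_global"], fit_np)
        block["r2_phylo"] = part.r2_phylo_contribution
        pd.DataFrame(rows).to_csv(out / "allometry_models.csv", index=False)
        return block

    def stage_pgls():
        means, C = state["means"], state["C"]
        fits = {}
        for kind in ("BM", "lambda", "OU"):
            fits[kind] = fit_pgls(means, C, StructureParams(kind),
                                  profile=(kind != "BM"))
        fits["nonphylo"] = fit_pgls(means, C, StructureParams("lambda", lam=0.0))
        p_bm_lambda = lrt(fits["lambda"], fits["BM"], df=1)
        resid = residuals_relative_size(fits["BM"])
        state["residuals"] = resid
        resid.rename("residual").to_csv(out / "eye_size_residuals.csv")
        rows = [{"structure": k, "aic": f.aic, "loglik": f.loglik,
                 "slope": f.coefficients.get("mean_log10_wing", np.nan)}
                for k, f in fits.items()]
        pd.DataFrame(rows).to_csv(out / "pgls_structures.csv", index=False)
        return {
            "slope_bm": fits["BM"].coefficients["mean_log10_wing"],
            "lambda_hat": fits["lambda"].structure.lam,
            "aic": {k: f.aic for k, f in fits.items()},
            "lrt_bm_vs_lambda_p": p_bm_lambda,
        }

    def stage_signal():
        resid, tree = state["residuals"], state["tree"]
        sig = pagel_lambda(resid, tree)
        sig.profile_csv(out / "lambda_profile.csv")
        fits = [fit_continuous(resid, tree, m) for m in MODELS]
        aicc_weights(fits)
        tab = fits_table(fits)
        tab.to_csv(out / "evo_models.csv", index=False)
        block = {"lambda_hat": sig.lambda_hat, "p_vs_zero": sig.p_vs_zero,
                 "weights": {f.model: f.weight for f in fits},
                 "best_model": tab.loc[tab["aicc"].idxmin(), "model"]}
        if "posterior" in state:
            sample = state["posterior"][: config.n_posterior_sample]
            sens = posterior_sensitivity(resid, sample, op="lambda")
            block["posterior_lambda"] = {
                "median": sens["median"], "q025": sens["q025"],
                "q975": sens["q975"], "n_trees": len(sample)}
        return block

    def stage_varrates():
        means, tree = state["means"], state["tree"]
        cfg = VarRatesConfig(seed=config.seed, **config.mcmc)
        post = varrates_mcmc(means, tree, cfg)
        post.to_table(out / "varrates_samples.tsv")
        diag = mcmc_diagnostics(post)
        diag.to_csv(out / "varrates_diagnostics.csv", index=False)
        summary_rates = post.branch_rate_summary()
        summary_rates.to_csv(out / "branch_rates.csv", index=False)
        cons = consensus_scaled_tree(post)
        (out / "consensus_scaled.nwk").write_text(write_newick(cons) + "\n")
        logml_var = marginal_likelihood(
            means, tree, cfg, K=config.marginal_k,
            rung_iterations=config.marginal_iterations,
            rung_burnin=config.marginal_iterations // 5)
        cfg_h = VarRatesConfig(seed=cfg.seed + 1, rj_enabled=False,
                               **config.mcmc)
        logml_hom = marginal_likelihood(
            means, tree, cfg_h, K=config.marginal_k,
            rung_iterations=config.marginal_iterations,
            rung_burnin=config.marginal_iterations // 5)
        bf = bayes_factor(logml_var, logml_hom)
        mrows = []
        if "residuals" in state:
            for lp in config.multirate_lambdas:
                fit = multirate_bm(state["residuals"], tree, lp)
                for node, s2 in zip(fit.edge_nodes, fit.branch_sigma2):
                    mrows.append({"lambda_pen": lp, "edge_node": int(node),
                                  "sigma2": float(s2)})
            pd.DataFrame(mrows).to_csv(out / "multirate_bm.csv", index=False)
        return {
            "median_lambda": float(post.stacked()["lam"].median()),
            "median_n_shifts": float(post.stacked()["n_shifts"].median()),
            "frac_branches_r_near_1": float(
                np.mean(np.abs(summary_rates["median_r"] - 1.0) < 0.05)),
            "log_marginal_variable": logml_var,
            "log_marginal_homogeneous": logml_hom,
            "bayes_factor": bf,
            "diagnostics": diag.to_dict(orient="list"),
        }

    def stage_habitat():
        means, C = state["means"], state["C"]
        habs = [segment_coverage(s, state["raster"])
                for s in state["segments"]]
        occ = state["occurrences"]
        sp_hab = species_habitat(occ, habs)
        sp_hab.drop(columns="values").to_csv(out / "species_habitat.csv",
                                             index=False)
        fit_rel = habitat_pgls(means, sp_hab, C, include_wing=True)
        fit_abs = habitat_pgls(means, sp_hab, C, include_wing=False)
        block = {
            "n_species": len(sp_hab),
            "relative": {"estimate": fit_rel.coefficients["habitat_z"],
                         "p": fit_rel.pvalues["habitat_z"]},
            "absolute": {"estimate": fit_abs.coefficients["habitat_z"],
                         "p": fit_abs.pvalues["habitat_z"]},
        }
        if "Nymphalidae" in set(means["family"]):
            try:
                fit_nym = habitat_pgls(means, sp_hab, C, include_wing=True,
                                       families=["Nymphalidae"])
                block["nymphalidae"] = {
                    "estimate": fit_nym.coefficients["habitat_z"],
                    "p": fit_nym.pvalues["habitat_z"]}
            except ValueError:
                block["nymphalidae"] = "too few species"
        # community-weighted means for eye size and residuals
        trait_eye = means.set_index("species")["mean_log10_eye"]
        cwm = cwm_table(occ, trait_eye, habs)
        cwm.to_csv(out / "cwm_eye.csv", index=False)
        block["cwm_eye"] = cwm_regression(cwm["cwm"], cwm["cover"])
        if "residuals" in state:
            cwm_r = cwm_table(occ, state["residuals"], habs)
            block["cwm_residuals"] = cwm_regression(cwm_r["cwm"],
                                                    cwm_r["cover"])
        return block

    run_stage("data", stage_data)
    run_stage("means", stage_means)
    run_stage("allometry", stage_allometry)
    run_stage("pgls", stage_pgls)
    if "signal" in stages and "residuals" not in state:
        raise ValueError("signal stage requires the pgls stage")
    run_stage("signal", stage_signal)
    run_stage("varrates", stage_varrates)
    if "habitat" in stages and "raster" not in state:
        logger.info("habitat stage skipped: no monitoring inputs")
    else:
        run_stage("habitat", stage_habitat)
    summary["meta"]["wall_seconds"] = t_wall
    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(_florify(summary), fh, indent=2, default=str)
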