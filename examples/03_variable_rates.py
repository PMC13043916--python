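"""Reversible-jump variable-rates regression: find the fast clade.

The synthetic radiation carries one early-diverging clade (the skipper
analogue) whose eye-size deviation evolves at 10x the background Brownian
rate.  A short rjMCMC run recovers branch rate scalars r: r = 1 means the
background rate, r > 1 a faster branch.  The Bayes factor compares the
variable-rates model to the homogeneous-rate one via stepping-stone
marginal likelihoods.
"""

import numpy as np

from eyevol.simulate import SimConfig, simulate_traits, simulate_tree
from eyevol.traits import add_log10, species_means
from eyevol.varrates import (VarRatesConfig, bayes_factor, marginal_likelihood,
                             mcmc_diagnostics, varrates_mcmc, _TreeMachinery)

cfg = SimConfig(seed=0)
tree = simulate_tree(cfg)
records, truth = simulate_traits(tree, cfg)
means = species_means(add_log10(records))

# a reduced run for the example; the desk-scale default is 3 x 200k
vcfg = VarRatesConfig(seed=7, n_chains=2, n_iterations=40_000,
                      burnin=8_000, thinning=20)
post = varrates_mcmc(means, tree, vcfg)
print(mcmc_diagnostics(post).to_string(index=False))

summ = post.branch_rate_summary()
mach = _TreeMachinery(tree)
clade = mach.clade_edges[truth["shifted_clade_node"]]
R = post.edge_rate_matrix()
print(f"\nbranches at background rate (median r ~ 1): "
      f"{np.mean(np.abs(summ['median_r'] - 1) < 0.05):.0%}")
print(f"fast clade ({len(truth['shifted_clade_tips'])} tips) "
      f"median rate scalar: {np.median(R[:, clade]):.1f}  (true rate 10x)")

logml_var = marginal_likelihood(means, tree, vcfg, K=6,
                                rung_iterations=4000, rung_burnin=1000)
logml_hom = marginal_likelihood(
    means, tree, VarRatesConfig(seed=8, rj_enabled=False), K=6,
    rung_iterations=4000, rung_burnin=1000)
bf = bayes_factor(logml_var, logml_hom)
print(f"\nBayes factor (variable vs homogeneous rates): {bf:.1f}")
print("-> BF > 2 supports rate heterogeneity; these data contain a true "
      "10x clade, so a clearly positive BF is the correct answer.")
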