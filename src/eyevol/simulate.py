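"""Synthetic datasets with known ground truth for the full pipeline.

The generators emulate the statistical structure of a temperate-butterfly
eye-size study: a 59-species ultrametric pure-birth phylogeny with one
designated fast-evolving clade (a skipper/Hesperiidae analogue with
superposition eyes), individual-level log10 eye-area and forewing-length
measurements following a phylogenetic allometry with a male-female offset,
a 500-tree posterior set with jittered branch lengths, and transect
monitoring records over a spatially autocorrelated tree-cover raster whose
species-trait coupling strength is a tunable parameter (zero by default —
the no-habitat-effect regime).

Everything is driven by one integer seed; a given config reproduces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .phylo import Phylogeny, write_newick, write_posterior_trees
from .habitat import (RasterGrid, TransectSegment, write_ascii_grid,
                      write_segments_csv)

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_bm",
    "simulate_traits",
    "simulate_posterior_trees",
    "simulate_raster",
    "simulate_transects",
    "simulate_occurrences",
    "simulate_monitoring",
    "emit_fixture_dir",
]

FAMILY_POOL = ("Nymphalidae", "Lycaenidae", "Pieridae", "Papilionidae",
               "Riodinidae", "Zygaenidae")


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study.

    Trait units are log10 mm (wing) and log10 mm^2 (eye).  The defaults are
    the study conditions: 59 species, ~443 individuals, allometric slope
    0.55, male offset 0.11, strong species-level phylogenetic variance, one
    clade with a 10x Brownian rate, and no trait-habitat coupling.
    """

    seed: int = 0
    n_species: int = 59
    n_per_species: tuple = (6, 9)   # ~443 individuals over 59 species
    allometric_slope: float = 0.55
    allometric_intercept: float = -0.30
    sex_offset: float = 0.11            # male - female, log10 scale
    wing_root: float = 1.30             # log10 mm at the root
    sigma2_wing: float = 0.03           # BM rate of log10 wing
    sigma2_phylo: float = 0.02          # BM rate of the eye-size deviation
    sigma2_resid: float = 0.002         # within-species residual variance
    sigma2_wing_resid: float = 0.002    # within-species wing variance
                                        # (log10 SD ~0.045, i.e. ~10% of
                                        # wing length between individuals)
    shifted_clade_size: int = 8         # target tip count of the fast clade
    shifted_clade_rate: float = 10.0    # rate multiplier inside it
    n_posterior_trees: int = 500
    bl_jitter: float = 0.1              # log-normal SD of branch jitter
    # monitoring / habitat
    habitat_effect: float = 0.0         # trait-habitat coupling in [0, 1]
    n_transects: int = 30
    segments_per_transect: int = 8
    segment_length: float = 50.0        # meters
    raster_n: int = 120                 # cells per side
    raster_cell: float = 10.0           # meters
    cover_smooth_sigma: float = 6.0     # cells; spatial autocorrelation
    occupancy_width: float = 25.0       # %-cover niche width
    occupancy_pmax: float = 0.5
    mean_abundance: float = 3.0
    n_withheld_species: int = 2         # emulates the 59 -> 57 mismatch

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# ---------------------------------------------------------------------- #
# tree
# ---------------------------------------------------------------------- #

def simulate_tree(config: SimConfig) -> Phylogeny:
    """Seeded pure-birth (Yule) tree, depth normalized to 1.

    Tips are labeled sp01..spNN in preorder.  One internal clade whose size
    is closest to ``shifted_clade_size`` is designated the fast
    "Hesperiidae" analogue; remaining tips get family labels by cutting the
    tree near the root, the largest family being Nymphalidae.  Family
    membership is returned via :func:`family_assignments`.
    """
    n = config.n_species
    if n < 4:
        raise ValueError("need at least 4 species")
    rng = config.rng(1)
    # grow: active lineages as (parent_node, birth_time); the root splits
    # at time 0 so the tree is binary throughout
    parent = [-1]
    length = [0.0]
    active = [(0, 0.0), (0, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        pnode, t0 = active.pop(i)
        node = len(parent)
        parent.append(pnode)
        length.append(t - t0)
        active.insert(i, (node, t))
        active.insert(i + 1, (node, t))
    t_end = t + rng.exponential(1.0 / n)
    tip_parents = []
    for pnode, t0 in active:
        tip_parents.append((pnode, t_end - t0))

    # assemble preorder arrays: children recorded in creation order
    children: dict[int, list] = {}
    for i in range(1, len(parent)):
        children.setdefault(parent[i], []).append(("int", i))
    for j, (pnode, bl) in enumerate(tip_parents):
        children.setdefault(pnode, []).append(("tip", j))
    order, par_arr, len_arr, lab_arr = [], [], [], []

    def emit(kind, idx, new_parent):
        me = len(par_arr)
        par_arr.append(new_parent)
        if kind == "int":
            len_arr.append(length[idx])
            lab_arr.append("")
            for k, i2 in children.get(idx, []):
                emit(k, i2, me)
        else:
            len_arr.append(tip_parents[idx][1])
            lab_arr.append(f"tip{idx}")

    par_arr.append(-1)
    len_arr.append(0.0)
    lab_arr.append("")
    for k, i2 in children.get(0, []):
        emit(k, i2, 0)

    depth_norm = t_end
    tree = Phylogeny(np.array(par_arr), np.array(len_arr) / depth_norm, lab_arr)
    # relabel tips in preorder as sp01..spNN
    labels = list(tree.label)
    counter = 1
    for i in range(tree.n_nodes):
        if not tree.children(i):
            labels[i] = f"sp{counter:02d}"
            counter += 1
    return Phylogeny(tree.parent, tree.length, labels)


def shifted_clade_node(tree: Phylogeny, target_size: int) -> int:
    """Designate the fast-clade analogue: the most stem-isolated clade
    whose size is near ``target_size``.

    Among internal non-root nodes holding between ``target_size - 2`` and
    ``target_size + 4`` tips (at least 5), the one with the longest stem
    branch is chosen — mirroring the empirical system, where the skippers
    are a moderately sized, early-diverging family on a long stem rather
    than a shallow radiation.  Falls back to the closest-size clade if the
    window is empty.
    """
    M = tree.tip_mask_below()
    sizes = M.sum(axis=1)
    internal = [i for i in range(1, tree.n_nodes) if tree.children(i)]
    lo, hi = max(5, target_size - 2), target_size + 4
    window = [i for i in internal if lo <= sizes[i] <= hi]
    if window:
        return max(window, key=lambda i: (tree.length[i], -i))
    return min(internal, key=lambda i: (abs(int(sizes[i]) - target_size), i))


def family_assignments(tree: Phylogeny, config: SimConfig,
                       n_families: int = 6) -> pd.Series:
    """Clade-consistent family labels; the shifted clade is Hesperiidae.

    The remaining tips are partitioned by repeatedly splitting the largest
    remaining clade (never the shifted one) until ~``n_families`` groups
    exist; the largest is named Nymphalidae, mirroring its dominance in the
    empirical system.
    """
    shift_node = shifted_clade_node(tree, config.shifted_clade_size)
    shift_tips = set(tree.clade_tips(shift_node))
    M = tree.tip_mask_below()
    sizes = M.sum(axis=1)
    groups = list(tree.children(0))
    while len(groups) < n_families:
        splittable = [v for v in groups if v != shift_node and tree.children(v)]
        if not splittable:
            break
        big = max(splittable, key=lambda v: sizes[v])
        groups.remove(big)
        groups.extend(tree.children(big))
    named = []
    for v in sorted(groups):
        g = [t for t, m in zip(tree.tips, M[v]) if m and t not in shift_tips]
        if g:
            named.append(g)
    named.sort(key=len, reverse=True)
    out = {}
    pool = list(FAMILY_POOL)
    for i, g in enumerate(named):
        name = pool[i] if i < len(pool) else f"Family{i}"
        for t in g:
            out[t] = name
    for t in shift_tips:
        out[t] = "Hesperiidae"
    return pd.Series(out).loc[tree.tips]


# ---------------------------------------------------------------------- #
# traits
# ---------------------------------------------------------------------- #

def simulate_bm(tree: Phylogeny, rate, rng, root_value: float = 0.0) -> pd.Series:
    """Brownian motion on the tree; ``rate`` is scalar or per-edge
    (indexed by child-node preorder position 1..n_nodes-1)."""
    rate_arr = np.broadcast_to(np.asarray(rate, dtype=float),
                               (tree.n_nodes - 1,))
    vals = np.zeros(tree.n_nodes)
    vals[0] = root_value
    for i in range(1, tree.n_nodes):
        sd = np.sqrt(rate_arr[i - 1] * tree.length[i])
        vals[i] = vals[tree.parent[i]] + rng.normal(0.0, sd)
    tips = [i for i in range(tree.n_nodes) if not tree.children(i)]
    return pd.Series(vals[tips], index=[tree.label[i] for i in tips])


def simulate_traits(tree: Phylogeny, config: SimConfig):
    """Individual-level trait table plus ground truth.

    Species log10 wing evolves by BM; species log10 eye is
    ``intercept + slope * wing + deviation`` with the deviation a BM whose
    rate is multiplied inside the shifted clade (stem included).
    Individuals add the male sex offset and i.i.d. measurement noise.

    Returns ``(records, truth)``: a raw trait table in the loader's format
    and a dict holding the species-level values and the clade membership.
    """
    rng = config.rng(2)
    shift_node = shifted_clade_node(tree, config.shifted_clade_size)
    M = tree.tip_mask_below()
    edge_in_clade = np.array(
        [not (M[i] & ~M[shift_node]).any() for i in range(1, tree.n_nodes)]
    )
    wing_sp = simulate_bm(tree, config.sigma2_wing, rng,
                          root_value=config.wing_root)
    dev_rate = np.where(edge_in_clade,
                        config.sigma2_phylo * config.shifted_clade_rate,
                        config.sigma2_phylo)
    dev_sp = simulate_bm(tree, dev_rate, rng)
    eye_sp = (config.allometric_intercept
              + config.allometric_slope * wing_sp + dev_sp)
    fams = family_assignments(tree, config)

    lo, hi = config.n_per_species
    rows = []
    for sp in tree.tips:
        n_i = int(rng.integers(lo, hi + 1))
        sexes = ["male", "female"] * (n_i // 2 + 1)
        for j in range(n_i):
            sex = sexes[j]
            # allometry operates at the individual level: an individual's
            # eye tracks its own wing length, plus the species' heritable
            # deviation, the sex offset, and measurement noise
            wing_log = wing_sp[sp] + rng.normal(
                0.0, np.sqrt(config.sigma2_wing_resid))
            eye_log = (config.allometric_intercept
                       + config.allometric_slope * wing_log
                       + dev_sp[sp]
                       + (config.sex_offset if sex == "male" else 0.0)
                       + rng.normal(0.0, np.sqrt(config.sigma2_resid)))
            rows.append({
                "individual_id": f"{sp}_{j:02d}",
                "species": sp,
                "sex": sex,
                "family": fams[sp],
                "eye_area": 10.0 ** eye_log,
                "forewing_length": 10.0 ** wing_log,
            })
    records = pd.DataFrame(rows)
    truth = {
        "wing_species": wing_sp,
        "deviation_species": dev_sp,
        "eye_species": eye_sp,
        "families": fams,
        "shifted_clade_node": shift_node,
        "shifted_clade_tips": tree.clade_tips(shift_node),
        "slope": config.allometric_slope,
        "sex_offset": config.sex_offset,
    }
    return records, truth


def simulate_posterior_trees(tree: Phylogeny, config: SimConfig) -> list:
    """Posterior-like tree set: fixed topology, branch lengths multiplied by
    i.i.d. log-normal(0, bl_jitter) factors."""
    if config.bl_jitter < 0:
        raise ValueError("bl_jitter must be >= 0")
    rng = config.rng(3)
    out = []
    for _ in range(config.n_posterior_trees):
        f = rng.lognormal(0.0, config.bl_jitter, size=tree.n_nodes - 1)
        new_len = tree.length.copy()
        new_len[1:] *= f
        out.append(Phylogeny(tree.parent.copy(), new_len, list(tree.label)))
    return out


# ---------------------------------------------------------------------- #
# monitoring
# ---------------------------------------------------------------------- #

def simulate_raster(config: SimConfig) -> RasterGrid:
    """Spatially autocorrelated percent tree cover: Gaussian-filtered white
    noise, rescaled to mean 50 / SD 30 and clipped to [0, 100]."""
    rng = config.rng(4)
    z = rng.normal(size=(config.raster_n, config.raster_n))
    z = gaussian_filter(z, sigma=config.cover_smooth_sigma, mode="reflect")
    z = (z - z.mean()) / z.std()
    cover = np.clip(50.0 + 30.0 * z, 0.0, 100.0)
    return RasterGrid(origin=(0.0, 0.0), cell_size=config.raster_cell,
                      values=np.round(cover, 2))


def simulate_transects(config: SimConfig) -> list:
    """Straight transects across the raster, split into equal segments."""
    rng = config.rng(5)
    side = config.raster_n * config.raster_cell
    total_len = config.segments_per_transect * config.segment_length
    margin = total_len + 2 * 10.0
    segs = []
    for t in range(config.n_transects):
        x = rng.uniform(margin * 0.1, side - margin * 0.1)
        y = rng.uniform(margin * 0.1, side - margin * 0.1)
        theta = rng.uniform(0, 2 * np.pi)
        dx, dy = np.cos(theta), np.sin(theta)
        # keep the whole transect inside the raster by reflecting direction
        end_x, end_y = x + dx * total_len, y + dy * total_len
        if not (0 < end_x < side):
            dx = -dx
        if not (0 < end_y < side):
            dy = -dy
        for s in range(config.segments_per_transect):
            p0 = (x + dx * s * config.segment_length,
                  y + dy * s * config.segment_length)
            p1 = (x + dx * (s + 1) * config.segment_length,
                  y + dy * (s + 1) * config.segment_length)
            segs.append(TransectSegment(f"T{t:03d}", f"S{s:02d}", [p0, p1]))
    return segs


def species_optima(tree: Phylogeny, deviation: pd.Series,
                   config: SimConfig) -> pd.Series:
    """Each species' preferred percent tree cover.

    With ``habitat_effect`` = h, the latent preference is
    ``h * z(deviation) + sqrt(1-h^2) * noise`` so h = 0 decouples habitat
    from relative eye size entirely and h = 1 ties them deterministically.
    """
    rng = config.rng(6)
    h = float(np.clip(config.habitat_effect, -1.0, 1.0))
    z = (deviation - deviation.mean()) / max(deviation.std(ddof=0), 1e-12)
    eps = rng.normal(size=len(z))
    latent = h * z.to_numpy() + np.sqrt(max(1.0 - h * h, 0.0)) * eps
    return pd.Series(np.clip(50.0 + 30.0 * latent, 0.0, 100.0),
                     index=deviation.index)


def simulate_occurrences(optima: pd.Series, segment_covers: pd.DataFrame,
                         config: SimConfig, rng=None) -> pd.DataFrame:
    """Presence/abundance records per (segment, species).

    Presence is Bernoulli with a Gaussian niche response
    ``pmax * exp(-(cover - optimum)^2 / (2 width^2))``; abundance given
    presence is 1 + Poisson(mean_abundance).  ``segment_covers`` needs
    columns transect_id, segment_id, cover.
    """
    rng = rng if rng is not None else config.rng(7)
    width, pmax = config.occupancy_width, config.occupancy_pmax
    withheld = set(
        pd.Index(optima.index)[
            rng.choice(len(optima), size=config.n_withheld_species,
                       replace=False)
        ]
    )
    rows = []
    cov = segment_covers["cover"].to_numpy(float)
    for sp, opt in optima.items():
        if sp in withheld:
            continue
        p = pmax * np.exp(-((cov - opt) ** 2) / (2.0 * width**2))
        present = rng.random(len(cov)) < p
        counts = 1 + rng.poisson(config.mean_abundance, size=len(cov))
        for idx in np.nonzero(present)[0]:
            rows.append({
                "transect_id": segment_covers["transect_id"].iloc[idx],
                "segment_id": segment_covers["segment_id"].iloc[idx],
                "species": sp,
                "abundance": float(counts[idx]),
            })
    return pd.DataFrame(rows)


def simulate_monitoring(tree: Phylogeny, truth: dict, config: SimConfig):
    """Full monitoring bundle: raster, segments, and occurrence records.

    Returns ``(raster, segments, occurrences, optima)``.  Species optima
    couple to the ground-truth eye-size deviation with strength
    ``config.habitat_effect`` (0 = the no-association regime).
    """
    from .habitat import segment_coverage

    raster = simulate_raster(config)
    segments = simulate_transects(config)
    habs = [segment_coverage(s, raster) for s in segments]
    covers = pd.DataFrame(
        [{"transect_id": h.transect_id, "segment_id": h.segment_id,
          "cover": h.weighted_mean_cover} for h in habs if h.ok]
    )
    optima = species_optima(tree, truth["deviation_species"], config)
    occ = simulate_occurrences(optima, covers, config)
    return raster, segments, occ, optima


# ---------------------------------------------------------------------- #
# fixture emission
# ---------------------------------------------------------------------- #

def emit_fixture_dir(config: SimConfig, outdir) -> dict:
    """Write a complete, loader-compatible fixture directory.

    Emits tree.nwk, traits.csv, posterior.nwk (multi-newick), raster.asc,
    segments.csv and occurrences.csv; returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    records, truth = simulate_traits(tree, config)
    post = simulate_posterior_trees(tree, config)
    raster, segments, occ, optima = simulate_monitoring(tree, truth, config)

    (outdir / "tree.nwk").write_text(write_newick(tree) + "\n")
    records.to_csv(outdir / "traits.csv", index=False)
    write_posterior_trees(post, outdir / "posterior.nwk")
    write_ascii_grid(raster, outdir / "raster.asc")
    write_segments_csv(segments, outdir / "segments.csv")
    occ.to_csv(outdir / "occurrences.csv", index=False)
    return {"tree": tree, "records": records, "truth": truth,
            "posterior": post, "raster": raster, "segments": segments,
            "occurrences": occ, "optima": optima}
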