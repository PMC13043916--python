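"""Species habitat from transect monitoring and a tree-cover raster;
community-weighted means and habitat-effect regressions.

A transect segment is buffered (default 10 m each side, rounded caps) and
intersected with the tree-cover-density raster; the segment's habitat value
is the coverage-fraction-weighted mean of intersected cell values, with
cells overlapping less than 0.002 of their area excluded.  Every species
recorded on a segment inherits that segment's value, giving a per-species
distribution of tree-cover values whose *median* is the species' habitat
metric.  Community-weighted means (CWM) average species trait values per
segment weighted by mean abundance.

Geometry is planar (projected meters).  Cell coverage fractions are exact
polygon/cell intersection areas computed with shapely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .phylo import PhyloCovariance, StructureParams
from .regression import GlsFit, fit_pgls

logger = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "TransectSegment",
    "SegmentHabitat",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_segments_csv",
    "write_segments_csv",
    "segment_coverage",
    "species_habitat",
    "community_weighted_mean",
    "cwm_table",
    "habitat_pgls",
    "cwm_regression",
]

MIN_COVERAGE_FRACTION = 0.002


@dataclass
class RasterGrid:
    """Regular percent-cover grid; row 0 is the northernmost row (ESRI
    ASCII-grid convention), ``origin`` the lower-left corner in meters."""

    origin: tuple
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        valid = self.values != self.nodata
        v = self.values[valid]
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("tree-cover values must lie in [0, 100]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_bounds(self, row: int, col: int) -> tuple:
        x0 = self.origin[0] + col * self.cell_size
        y0 = self.origin[1] + (self.n_rows - 1 - row) * self.cell_size
        return (x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    @property
    def extent(self) -> tuple:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size,
                y0 + self.n_rows * self.cell_size)


@dataclass
class TransectSegment:
    transect_id: str
    segment_id: str
    polyline: list          # ordered (x, y) vertices, meters
    buffer_m: float = 10.0

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ValueError(f"segment {self.segment_id}: need >= 2 vertices")
        if self.length <= 0:
            raise ValueError(f"segment {self.segment_id}: zero length")

    @property
    def length(self) -> float:
        return LineString(self.polyline).length

    @property
    def key(self) -> tuple:
        return (self.transect_id, self.segment_id)


@dataclass
class SegmentHabitat:
    transect_id: str
    segment_id: str
    weighted_mean_cover: float
    n_cells_used: int
    coverage_fractions: np.ndarray
    ok: bool = True

    @property
    def key(self) -> tuple:
        return (self.transect_id, self.segment_id)


# ---------------------------------------------------------------------- #
# raster / segment I/O (plain text)
# ---------------------------------------------------------------------- #

def read_ascii_grid(path) -> RasterGrid:
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()[:2]
        header[k.lower()] = float(v)
        i += 1
    for need in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if need not in header:
            raise ValueError(f"ASCII grid missing header field {need}")
    vals = np.loadtxt(lines[i:], ndmin=2)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return RasterGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=vals,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"nodata_value {raster.nodata:g}\n")
        np.savetxt(fh, raster.values, fmt="%.4f")


def read_segments_csv(path, buffer_m: float = 10.0) -> list:
    """Segments CSV: transect_id, segment_id, vertex_index, x, y."""
    df = pd.read_csv(path)
    out = []
    for (tid, sid), g in df.groupby(["transect_id", "segment_id"], sort=True):
        g = g.sort_values("vertex_index")
        out.append(TransectSegment(str(tid), str(sid),
                                   list(zip(g["x"], g["y"])), buffer_m))
    return out


def write_segments_csv(segments, path) -> None:
    rows = []
    for seg in segments:
        for i, (x, y) in enumerate(seg.polyline):
            rows.append({"transect_id": seg.transect_id,
                         "segment_id": seg.segment_id,
                         "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# coverage extraction
# ---------------------------------------------------------------------- #

def segment_coverage(segment: TransectSegment, raster: RasterGrid,
                     min_fraction: float = MIN_COVERAGE_FRACTION) -> SegmentHabitat:
    """Coverage-fraction-weighted mean tree cover inside a buffered segment.

    The buffer is a capsule around the polyline (rounded caps and joins).
    For every raster cell intersecting the buffer, the coverage fraction is
    the exact fraction of the *cell's* area inside the buffer; cells under
    ``min_fraction`` or holding the missing-data marker are excluded from
    numerator and denominator alike.
    """
    poly = LineString(segment.polyline).buffer(segment.buffer_m,
                                               quad_segs=16)
    minx, miny, maxx, maxy = poly.bounds
    ex = raster.extent
    if minx < ex[0] or miny < ex[1] or maxx > ex[2] or maxy > ex[3]:
        logger.warning("segment %s extends beyond the raster; using overlap",
                       segment.segment_id)
    cs = raster.cell_size
    col_lo = max(int(math.floor((minx - ex[0]) / cs)), 0)
    col_hi = min(int(math.ceil((maxx - ex[0]) / cs)), raster.n_cols)
    row_top = max(int(math.floor((ex[3] - maxy) / cs)), 0)
    row_bot = min(int(math.ceil((ex[3] - miny) / cs)), raster.n_rows)

    cell_area = cs * cs
    fracs, vals = [], []
    for row in range(row_top, row_bot):
        for col in range(col_lo, col_hi):
            v = raster.values[row, col]
            if v == raster.nodata:
                continue
            cell = box(*raster.cell_bounds(row, col))
            a = poly.intersection(cell).area
            f = a / cell_area
            if f >= min_fraction:
                fracs.append(f)
                vals.append(v)
    fracs = np.asarray(fracs)
    vals = np.asarray(vals)
    if len(fracs) == 0:
        logger.warning("segment %s has no retained raster cells; flagged",
                       segment.segment_id)
        return SegmentHabitat(segment.transect_id, segment.segment_id,
                              float("nan"), 0, fracs, ok=False)
    wm = float(np.sum(fracs * vals) / np.sum(fracs))
    return SegmentHabitat(segment.transect_id, segment.segment_id, wm,
                          len(fracs), fracs)


# ---------------------------------------------------------------------- #
# species habitat and community-weighted means
# ---------------------------------------------------------------------- #

def species_habitat(occurrences: pd.DataFrame, habitats) -> pd.DataFrame:
    """Per-species habitat distribution and its median.

    ``occurrences`` needs columns transect_id, segment_id, species (and
    abundance, unused here: habitat assignment is presence-based — each
    species gets one value per distinct segment where it was recorded).
    Species whose segments all failed coverage extraction are excluded with
    a log entry.  Returns columns species, n_segments, median_cover plus a
    ``values`` column holding the per-segment arrays.
    """
    hab = {h.key: h for h in habitats}
    occ = occurrences.copy()
    occ["transect_id"] = occ["transect_id"].astype(str)
    occ["segment_id"] = occ["segment_id"].astype(str)
    unknown = [k for k in occ[["transect_id", "segment_id"]]
               .drop_duplicates().itertuples(index=False)
               if tuple(k) not in hab]
    if unknown:
        raise KeyError(f"occurrence rows reference unknown segments: {unknown[:5]}")
    rows = []
    for sp, g in occ.groupby("species", sort=True):
        segs = {tuple(k) for k in
                g[["transect_id", "segment_id"]].itertuples(index=False)}
        vals = np.array([hab[k].weighted_mean_cover for k in sorted(segs)
                         if hab[k].ok])
        if len(vals) == 0:
            logger.warning("species %s has no segment with usable habitat; "
                           "excluded", sp)
            continue
        rows.append({"species": sp, "n_segments": len(vals),
                     "median_cover": float(np.median(vals)), "values": vals})
    return pd.DataFrame(rows)


def community_weighted_mean(abundances, traits) -> float:
    """Abundance-weighted mean trait at one segment: sum(a t) / sum(a)."""
    a = np.asarray(abundances, dtype=float)
    t = np.asarray(traits, dtype=float)
    if a.shape != t.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("need matched 1-D abundance and trait vectors")
    if np.any(a < 0):
        raise ValueError("abundances must be >= 0")
    if a.sum() == 0:
        raise ValueError("all-zero abundance at segment")
    return float(np.sum(a * t) / np.sum(a))


def cwm_table(occurrences: pd.DataFrame, trait: pd.Series,
              habitats=None) -> pd.DataFrame:
    """Per-segment community-weighted mean of ``trait`` (indexed by species).

    Abundance is averaged over duplicate rows of a (segment, species) pair
    first (years collapse to their mean).  Species lacking a trait value are
    dropped from the community.  If ``habitats`` is given, the segment's
    weighted mean cover is joined in.
    """
    occ = occurrences.copy()
    occ["transect_id"] = occ["transect_id"].astype(str)
    occ["segment_id"] = occ["segment_id"].astype(str)
    agg = (occ.groupby(["transect_id", "segment_id", "species"], sort=True)
           ["abundance"].mean().reset_index())
    agg = agg[agg["species"].isin(trait.index)]
    rows = []
    for (tid, sid), g in agg.groupby(["transect_id", "segment_id"], sort=True):
        a = g["abundance"].to_numpy(float)
        if a.sum() == 0:
            continue
        t = trait.loc[g["species"]].to_numpy(float)
        rows.append({"transect_id": tid, "segment_id": sid,
                     "cwm": community_weighted_mean(a, t),
                     "n_species": len(g)})
    out = pd.DataFrame(rows)
    if habitats is not None:
        hab = pd.DataFrame(
            [{"transect_id": h.transect_id, "segment_id": h.segment_id,
              "cover": h.weighted_mean_cover} for h in habitats if h.ok]
        )
        out = out.merge(hab, on=["transect_id", "segment_id"], how="inner")
    return out


# ---------------------------------------------------------------------- #
# habitat-effect regressions
# ---------------------------------------------------------------------- #

def habitat_pgls(
    means: pd.DataFrame,
    habitat: pd.DataFrame,
    C: PhyloCovariance,
    include_wing: bool = True,
    structure: StructureParams | None = None,
    families: list | None = None,
) -> GlsFit:
    """PGLS of species-mean eye size on median tree cover.

    The habitat predictor (and, when included, the forewing-length
    covariate) is standardized to mean 0, SD 1 over the analyzed species.
    ``families`` restricts the analysis (e.g. Nymphalidae-only).  The
    covariance is subset to the intersection of species present in all
    inputs; an intersection under 4 species raises.

    By default the correlation structure is Pagel's lambda profiled by ML,
    and — when the means table carries ``var_log10_eye``/``n_individuals``
    columns — the known sampling variance of each species mean enters the
    covariance diagonal (measurement-error PGLS).  Both guard the habitat
    test's calibration on trees with short terminal branches.
    """
    profile = structure is None
    structure = structure or StructureParams("lambda")
    df = means.merge(habitat[["species", "median_cover"]], on="species")
    if families is not None:
        df = df[df["family"].isin(families)]
    keep = [t for t in C.taxa if t in set(df["species"])]
    if len(keep) < 4:
        raise ValueError(f"only {len(keep)} species shared among means, "
                         "habitat and tree")
    df = df.set_index("species").loc[keep].reset_index()

    def zscore(x):
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("constant predictor cannot be standardized")
        return (x - x.mean()) / sd

    df["habitat_z"] = zscore(df["median_cover"])
    predictors = ["habitat_z"]
    if include_wing:
        df["wing_z"] = zscore(df["mean_log10_wing"])
        predictors = ["wing_z", "habitat_z"]
    meas_var = None
    if {"var_log10_eye", "n_individuals"} <= set(df.columns):
        df["mean_sampling_var"] = (df["var_log10_eye"]
                                   / df["n_individuals"].clip(lower=1))
        meas_var = "mean_sampling_var"
    return fit_pgls(df, C.subset(keep), structure, predictors=predictors,
                    profile=profile, meas_var=meas_var)


def cwm_regression(cwm_values, segment_covers) -> dict:
    """OLS of per-segment CWM on segment tree cover: slope, SE, p, 95% CI."""
    import statsmodels.api as sm

    y = np.asarray(cwm_values, dtype=float)
    x = np.asarray(segment_covers, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 segments")
    if np.ptp(x) == 0:
        raise ValueError("constant tree-cover covariate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int()[1]
    return {
        "slope": float(res.params[1]),
        "se": float(res.bse[1]),
        "p": float(res.pvalues[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "r2": float(res.rsquared),
        "n": int(res.nobs),
    }
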