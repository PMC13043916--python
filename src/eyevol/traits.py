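"""Individual-level trait tables: loading, log10 transform, species means.

The measurement table holds one row per scanned individual: species, sex,
family, eye surface area (mm^2) and forewing length (mm).  All comparative
analyses run on log10-transformed values; the transform is applied exactly
once and guarded by a column flag so a double transform raises instead of
silently corrupting the scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "species", "sex", "family",
                    "eye_area", "forewing_length")
SEXES = ("male", "female")

LOG_FLAG = "log10_applied"


def load_traits(path, tree_tips=None) -> pd.DataFrame:
    """Load and validate an individual-level trait CSV.

    Rows with non-positive measurements, missing species, or an unknown sex
    code are dropped and logged with the reason.  If ``tree_tips`` is given,
    species absent from the tree are *flagged* (column ``on_tree``), never
    silently dropped.

    Returns a DataFrame with log10 columns ``log10_eye`` and ``log10_wing``
    added and ``attrs[LOG_FLAG]`` set.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait CSV missing required columns: {missing}")
    n_in = len(df)
    if n_in == 0:
        raise ValueError("no records in trait file")

    reasons = pd.Series("", index=df.index)
    bad = df["species"].isna() | (df["species"].astype(str).str.strip() == "")
    reasons[bad] = "missing species"
    for col in ("eye_area", "forewing_length"):
        nonpos = ~(pd.to_numeric(df[col], errors="coerce") > 0)
        reasons[nonpos & (reasons == "")] = f"non-positive {col}"
    badsex = ~df["sex"].isin(SEXES)
    reasons[badsex & (reasons == "")] = "unknown sex code"

    dropped = df[reasons != ""]
    for idx, why in reasons[reasons != ""].items():
        logger.warning("dropping row %s (%s): %s",
                       idx, df.loc[idx, "individual_id"], why)
    df = df[reasons == ""].copy()
    if df.empty:
        raise ValueError("no valid records after validation")
    logger.info("loaded %d of %d trait records (%d species)",
                len(df), n_in, df["species"].nunique())

    df = add_log10(df)
    if tree_tips is not None:
        df["on_tree"] = df["species"].isin(set(tree_tips))
    df.attrs["n_dropped"] = len(dropped)
    return df.reset_index(drop=True)


def add_log10(df: pd.DataFrame) -> pd.DataFrame:
    """Add log10 trait columns; raises if the transform was already applied."""
    if df.attrs.get(LOG_FLAG, False) or "log10_eye" in df.columns:
        raise ValueError("log10 transform already applied to this table")
    df = df.copy()
    df["log10_eye"] = np.log10(df["eye_area"].astype(float))
    df["log10_wing"] = np.log10(df["forewing_length"].astype(float))
    df.attrs[LOG_FLAG] = True
    return df


def species_means(records: pd.DataFrame) -> pd.DataFrame:
    """Species-averaged log10 traits, sexes pooled, sorted by label.

    Means are arithmetic means of the per-individual log10 values (the
    transform precedes averaging).  Returns columns ``species``, ``family``,
    ``mean_log10_eye``, ``mean_log10_wing``, ``n_individuals``.
    """
    if not records.attrs.get(LOG_FLAG, False) and "log10_eye" not in records.columns:
        records = add_log10(records)
    out = (
        records.groupby("species", sort=True)
        .agg(
            family=("family", "first"),
            mean_log10_eye=("log10_eye", "mean"),
            mean_log10_wing=("log10_wing", "mean"),
            var_log10_eye=("log10_eye", "var"),
            var_log10_wing=("log10_wing", "var"),
            n_individuals=("log10_eye", "size"),
        )
        .reset_index()
    )
    # sampling variance of each species mean (for measurement-error PGLS);
    # singletons get the across-species median as a fallback
    for col in ("var_log10_eye", "var_log10_wing"):
        med = out[col].median()
        out[col] = out[col].fillna(0.0 if np.isnan(med) else med)
    return out


def repeatability_r2(x, y) -> float:
    """Repeatability of paired re-measurements as regression R^2.

    Ordinary least-squares regression of the repeat measurement on the
    original (with intercept); returns the squared Pearson correlation,
    which equals the regression R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class RepeatabilityReport:
    """Tidy bundle of repeatability checks, exportable to CSV."""

    rows: list

    def add(self, name: str, x, y) -> float:
        r2 = repeatability_r2(x, y)
        self.rows.append({"comparison": name, "n": len(x), "r2": r2})
        return r2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)
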