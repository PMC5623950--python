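"""Per-tree canopy temperature via circular-buffer zonal statistics.

After segmentation nulls out soil and weed, each tree's canopy
temperature T_c is the mean of the remaining pixels whose centers fall
within a circular buffer (default radius 0.40 m, conservative for a
1-m within-row spacing) around the surveyed tree center.  Genotypic
summaries average alive trees with a defined T_c; genotypes need a
minimum replicate count in both treatments to enter the statistical
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RadiometricMosaic

__all__ = ["CanopyTemperatureRecord", "buffer_mean", "extract_tc",
           "summarize_genotypes", "filter_replicates"]

DEFAULT_BUFFER_RADIUS = 0.40  # m


@dataclass(frozen=True)
class CanopyTemperatureRecord:
    tree_id: int
    tc: float          # NaN when the buffer holds no valid pixel
    n_pixels: int
    empty: bool


def buffer_mean(mosaic: RadiometricMosaic, center_xy,
                radius: float = DEFAULT_BUFFER_RADIUS,
                tree_id: int = -1) -> CanopyTemperatureRecord:
    """Mean temperature over valid pixels whose centers lie within ``radius``.

    Pixels nulled by segmentation (NaN) are excluded; a tree whose buffer
    contains no valid pixel is flagged ``empty`` (its T_c is NaN, not 0).
    Raises if the center lies outside the raster extent.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x, y = center_xy
    nrows, ncols = mosaic.shape
    col_c, row_c = mosaic.transform.world_to_pixel(x, y)
    if not (-0.5 <= col_c <= ncols - 0.5 and -0.5 <= row_c <= nrows - 0.5):
        raise ValueError(f"tree center ({x}, {y}) lies outside the mosaic")
    w = int(np.ceil(radius / mosaic.pixel_size)) + 1
    r_lo = max(0, int(np.floor(row_c)) - w)
    r_hi = min(nrows, int(np.ceil(row_c)) + w + 1)
    c_lo = max(0, int(np.floor(col_c)) - w)
    c_hi = min(ncols, int(np.ceil(col_c)) + w + 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                         indexing="ij")
    xs, ys = mosaic.transform(cc, rr)
    inside = (xs - x) ** 2 + (ys - y) ** 2 <= radius**2
    patch = mosaic.values[r_lo:r_hi, c_lo:c_hi]
    vals = patch[inside & np.isfinite(patch)]
    if vals.size == 0:
        return CanopyTemperatureRecord(tree_id, float("nan"), 0, True)
    return CanopyTemperatureRecord(tree_id, float(vals.mean()), int(vals.size),
                                   False)


def extract_tc(mosaic: RadiometricMosaic, trees: pd.DataFrame,
               radius: float = DEFAULT_BUFFER_RADIUS) -> pd.DataFrame:
    """Buffer means for every tree in the table.

    Returns a frame with columns ``tree_id, tc, n_pixels`` (``tc`` is NaN
    for empty buffers, e.g. dead trees whose canopy was fully nulled).
    """
    records = []
    for tree_id, x, y in trees[["tree_id", "x_m", "y_m"]].itertuples(index=False):
        rec = buffer_mean(mosaic, (x, y), radius, tree_id=int(tree_id))
        records.append((rec.tree_id, rec.tc, rec.n_pixels))
    return pd.DataFrame(records, columns=["tree_id", "tc", "n_pixels"])


def summarize_genotypes(records: pd.DataFrame,
                        trees: pd.DataFrame) -> pd.DataFrame:
    """Genotypic mean T_c, standard error and replicate count per treatment.

    Only alive trees with a defined T_c contribute.  SE is the sample
    SD / sqrt(n) (NaN for n < 2).  Raises on tree ids absent from the
    tree table.
    """
    unknown = set(records["tree_id"]) - set(trees["tree_id"])
    if unknown:
        raise ValueError(f"records reference unknown tree ids: {sorted(unknown)[:5]}")
    if "border" in trees.columns:  # guard trees never enter statistics
        trees = trees[~trees["border"]]
        records = records[records["tree_id"].isin(trees["tree_id"])]
    merged = records.merge(
        trees[["tree_id", "genotype_id", "treatment", "alive"]],
        on="tree_id", how="left")
    usable = merged[merged["alive"] & merged["tc"].notna()]
    grouped = usable.groupby(["genotype_id", "treatment"], sort=True)["tc"]
    out = grouped.agg(mean_tc="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["genotype_id", "treatment", "mean_tc", "se", "n"]]


def filter_replicates(summaries: pd.DataFrame, min_reps: int = 3) -> pd.DataFrame:
    """Keep genotypes with at least ``min_reps`` replicates in BOTH treatments."""
    if summaries.empty:
        return summaries.copy()
    counts = summaries.pivot_table(index="genotype_id", columns="treatment",
                                   values="n", aggfunc="sum", fill_value=0)
    for tr in ("WW", "mDr"):
        if tr not in counts.columns:
            counts[tr] = 0
    keep = counts.index[(counts["WW"] >= min_reps) & (counts["mDr"] >= min_reps)]
    return summaries[summaries["genotype_id"].isin(keep)].reset_index(drop=True)
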