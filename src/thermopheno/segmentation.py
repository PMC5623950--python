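"""Canopy/soil/weed segmentation of thermal mosaics.

Two independent routes to a canopy mask:

* multilevel Otsu histogram thresholding — partition the temperature
  histogram into K classes maximizing between-class variance (dynamic
  programming over cumulative moments), then keep the quantization levels
  whose mean temperature falls inside the treatment's canopy band;
* bottom-up region merging — pairwise merging of 4-connected regions
  under the multiresolution heterogeneity criterion (colour + shape with
  compactness/smoothness mixing), stopped by a scale parameter, followed
  by the same classify-segments-by-mean-temperature step.

Classes follow the field convention: "Poplar" inside the canopy band,
"Soil" above it, "Weed" below it; Soil and Weed pixels are discarded
(set to nodata) before zonal temperature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RadiometricMosaic

__all__ = [
    "TemperatureHistogram", "SegmentationResult", "CanopyBand",
    "build_histogram", "otsu_thresholds", "classify_otsu_levels",
    "region_merge_segmentation", "classify_segments", "apply_canopy_mask",
    "CANOPY_BANDS",
]

POPLAR, SOIL, WEED = "Poplar", "Soil", "Weed"


@dataclass(frozen=True)
class CanopyBand:
    """Inclusive temperature band (°C) considered canopy for a treatment."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("band lower bound must be below upper bound")

    def classify(self, mean_tc: float) -> str:
        if mean_tc < self.lower:
            return WEED
        if mean_tc > self.upper:
            return SOIL
        return POPLAR


#: per-treatment canopy bands used in the study design
CANOPY_BANDS = {"WW": CanopyBand(15.0, 27.0), "mDr": CanopyBand(14.0, 28.0)}


@dataclass
class TemperatureHistogram:
    edges: np.ndarray    # length n_bins + 1, strictly increasing
    counts: np.ndarray   # length n_bins, >= 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SegmentationResult:
    """Label map (0 = nodata) with per-label statistics and classes."""

    labels: np.ndarray           # int32, same shape as mosaic
    table: pd.DataFrame          # columns label, n_pixels, mean_tc[, class]

    @property
    def canopy_mask(self) -> np.ndarray:
        if "class" not in self.table.columns:
            raise ValueError("segments are not classified yet")
        keep = set(self.table.loc[self.table["class"] == POPLAR, "label"])
        return np.isin(self.labels, list(keep)) if keep else np.zeros_like(
            self.labels, dtype=bool)

    @property
    def n_segments(self) -> int:
        return len(self.table)


def build_histogram(mosaic: RadiometricMosaic, n_bins: int = 256) -> TemperatureHistogram:
    """Equal-width histogram over [min, max] of valid pixels."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    vals = mosaic.valid_values()
    if vals.size == 0:
        raise ValueError("mosaic has no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:  # degenerate: a single occupied bin around the value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return TemperatureHistogram(edges=edges, counts=counts)


def otsu_thresholds(hist: TemperatureHistogram, n_classes: int):
    """Optimal multilevel Otsu thresholds by dynamic programming.

    Maximizes the between-class variance sum_k w_k (mu_k - mu)^2 over all
    partitions of the occupied histogram bins into ``n_classes`` contiguous
    non-empty groups; O(n_classes * n_bins^2) over cumulative zeroth/first
    moments.  Returns ``(thresholds, eta)`` where ``thresholds`` are the
    ``n_classes - 1`` cut temperatures and ``eta`` in [0, 1] is the
    separability criterion (between-class over total variance).  Ties are
    broken toward the lexicographically smallest threshold set.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    occ = np.flatnonzero(hist.counts > 0)
    if occ.size < n_classes:
        raise ValueError(
            f"histogram has {occ.size} occupied bins, fewer than {n_classes} classes")
    w = hist.counts[occ].astype(np.float64)
    v = hist.centers[occ]
    B = occ.size
    W = np.concatenate([[0.0], np.cumsum(w)])
    M = np.concatenate([[0.0], np.cumsum(w * v)])

    def seg_score(i, j):
        # vectorized over i: class spanning occupied bins i..j
        s = W[j + 1] - W[i]
        m = M[j + 1] - M[i]
        return m * m / s

    # dp[k][j]: best score using k+1 classes for bins 0..j
    dp = np.full((n_classes, B), -np.inf)
    arg = np.zeros((n_classes, B), dtype=np.int64)
    dp[0] = [seg_score(np.array([0]), j)[0] for j in range(B)]
    for k in range(1, n_classes):
        for j in range(k, B):
            i = np.arange(k, j + 1)   # start of last class
            cand = dp[k - 1][i - 1] + seg_score(i, j)
            best = int(np.argmax(cand))  # first max -> smallest start index
            dp[k][j] = cand[best]
            arg[k][j] = i[best]

    # backtrack cut positions (index of first occupied bin of each class)
    cuts = []
    j = B - 1
    for k in range(n_classes - 1, 0, -1):
        i = int(arg[k][j])
        cuts.append(i)
        j = i - 1
    cuts = cuts[::-1]

    # threshold between occupied bin i-1 and i: midpoint of the gap between
    # the original bins' facing edges (equals the shared edge when adjacent)
    thresholds = np.array([
        0.5 * (hist.edges[occ[i - 1] + 1] + hist.edges[occ[i]]) for i in cuts])

    n = W[-1]
    mu = M[-1] / n
    total_var = float(np.sum(w * (v - mu) ** 2) / n)
    between = float(dp[n_classes - 1][B - 1] / n - mu * mu)
    eta = 1.0 if total_var == 0 else min(1.0, max(0.0, between / total_var))
    return thresholds, eta


def classify_otsu_levels(mosaic: RadiometricMosaic, thresholds,
                         band: CanopyBand, mode: str = "level") -> SegmentationResult:
    """Quantize by thresholds and classify levels against the canopy band.

    ``mode="level"`` (default): a whole quantization level is Poplar iff
    its pixel-mean temperature lies inside the band (inclusive).
    ``mode="pixel"``: raw pixels are retained iff their own temperature
    lies in the band; level statistics are still reported.
    """
    if mode not in {"level", "pixel"}:
        raise ValueError("mode must be 'level' or 'pixel'")
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    valid = mosaic.mask
    levels = np.digitize(mosaic.values, thresholds)  # 0..K-1, NaN -> K
    labels = np.where(valid, levels + 1, 0).astype(np.int32)

    rows = []
    for lab in np.unique(labels[valid]):
        sel = (labels == lab) & valid
        mean_tc = float(mosaic.values[sel].mean())
        rows.append((int(lab), int(sel.sum()), mean_tc, band.classify(mean_tc)))
    table = pd.DataFrame(rows, columns=["label", "n_pixels", "mean_tc", "class"])
    result = SegmentationResult(labels, table)
    if mode == "pixel":
        in_band = valid & (mosaic.values >= band.lower) & (mosaic.values <= band.upper)
        result = SegmentationResult(labels, table)
        result._pixel_mask = in_band  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# region merging


def region_merge_segmentation(mosaic: RadiometricMosaic, scale: float = 10.0,
                              shape: float = 0.1,
                              compactness: float = 0.5) -> SegmentationResult:
    """Bottom-up region merging with the multiresolution heterogeneity cost.

    Starting from single-pixel regions on the 4-connected valid-pixel
    graph, repeatedly merge locally mutual-best region pairs while the
    fusion cost

        f = (1 - shape) * dh_color + shape * dh_shape

    stays below ``scale**2``, where the colour term is the increase of
    n*sigma on merging and the shape term mixes compactness (l/sqrt(n))
    and smoothness (l/b) heterogeneity, each weighted by region area
    (l = perimeter, n = area, b = bounding-box perimeter).  Deterministic:
    ties resolve toward the smallest region label.

    Returns an unclassified :class:`SegmentationResult`; apply
    :func:`classify_segments` to obtain the canopy mask.
    """
    if not (0.0 <= shape <= 1.0 and 0.0 <= compactness <= 1.0):
        raise ValueError("shape and compactness must lie in [0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    valid = mosaic.mask
    vals = mosaic.values
    if not np.all(np.isfinite(vals[valid])):
        raise ValueError("non-finite pixels inside the valid mask")
    nrows, ncols = vals.shape
    idx_map = np.full(vals.shape, -1, dtype=np.int64)
    flat = np.flatnonzero(valid.ravel())
    n_regions = flat.size
    if n_regions == 0:
        raise ValueError("mosaic has no valid pixels")
    idx_map.ravel()[flat] = np.arange(n_regions)

    pv = vals.ravel()[flat].astype(np.float64)
    n = np.ones(n_regions)
    s = pv.copy()
    s2 = pv * pv
    l = np.full(n_regions, 4.0)
    rows_px, cols_px = np.divmod(flat, ncols)
    rmin = rows_px.astype(np.float64); rmax = rows_px.astype(np.float64)
    cmin = cols_px.astype(np.float64); cmax = cols_px.astype(np.float64)

    # 4-connectivity edges between valid pixels
    ea, eb = [], []
    right = valid[:, :-1] & valid[:, 1:]
    ea.append(idx_map[:, :-1][right]); eb.append(idx_map[:, 1:][right])
    down = valid[:-1, :] & valid[1:, :]
    ea.append(idx_map[:-1, :][down]); eb.append(idx_map[1:, :][down])
    ea = np.concatenate(ea); eb = np.concatenate(eb)
    ew = np.ones(ea.size)

    threshold = scale * scale
    w_color = 1.0 - shape

    def region_h(nn, ss, ss2, ll, bb):
        var = np.maximum(ss2 / nn - (ss / nn) ** 2, 0.0)
        sigma = np.sqrt(var)
        h_color = nn * sigma
        h_cmpct = ll * np.sqrt(nn)        # n * (l / sqrt(n))
        h_smooth = nn * ll / bb           # n * (l / b)
        return h_color, compactness * h_cmpct + (1.0 - compactness) * h_smooth

    while ea.size:
        bbox_a = 2.0 * ((cmax[ea] - cmin[ea] + 1) + (rmax[ea] - rmin[ea] + 1))
        bbox_b = 2.0 * ((cmax[eb] - cmin[eb] + 1) + (rmax[eb] - rmin[eb] + 1))
        hc_a, hs_a = region_h(n[ea], s[ea], s2[ea], l[ea], bbox_a)
        hc_b, hs_b = region_h(n[eb], s[eb], s2[eb], l[eb], bbox_b)
        nm = n[ea] + n[eb]
        sm = s[ea] + s[eb]
        s2m = s2[ea] + s2[eb]
        lm = l[ea] + l[eb] - 2.0 * ew
        bm = 2.0 * ((np.maximum(cmax[ea], cmax[eb]) - np.minimum(cmin[ea], cmin[eb]) + 1)
                    + (np.maximum(rmax[ea], rmax[eb]) - np.minimum(rmin[ea], rmin[eb]) + 1))
        hc_m, hs_m = region_h(nm, sm, s2m, lm, bm)
        f = w_color * (hc_m - hc_a - hc_b) + shape * (hs_m - hs_a - hs_b)

        # best neighbour per region over directed edges, ties -> smallest id
        da = np.concatenate([ea, eb])
        db = np.concatenate([eb, ea])
        df = np.concatenate([f, f])
        dw = np.concatenate([ew, ew])
        order = np.lexsort((db, df, da))
        da_s = da[order]
        first = np.r_[True, da_s[1:] != da_s[:-1]]
        sel = order[first]
        best_nb = np.full(n_regions, -1, dtype=np.int64)
        best_f = np.full(n_regions, np.inf)
        best_w = np.zeros(n_regions)
        best_nb[da_s[first]] = db[sel]
        best_f[da_s[first]] = df[sel]
        best_w[da_s[first]] = dw[sel]

        a_ids = np.flatnonzero(best_nb >= 0)
        b_ids = best_nb[a_ids]
        mutual = (best_nb[b_ids] == a_ids) & (best_f[a_ids] < threshold) & (a_ids < b_ids)
        pa = a_ids[mutual]
        pb = b_ids[mutual]
        if pa.size == 0:
            break

        # merge pb into pa (pa < pb keeps the smallest label deterministic)
        l[pa] = l[pa] + l[pb] - 2.0 * best_w[pa]
        n[pa] += n[pb]
        s[pa] += s[pb]
        s2[pa] += s2[pb]
        rmin[pa] = np.minimum(rmin[pa], rmin[pb])
        rmax[pa] = np.maximum(rmax[pa], rmax[pb])
        cmin[pa] = np.minimum(cmin[pa], cmin[pb])
        cmax[pa] = np.maximum(cmax[pa], cmax[pb])

        parent = np.arange(n_regions)
        parent[pb] = pa
        ea = parent[ea]
        eb = parent[eb]
        keep = ea != eb
        ea, eb, ew = ea[keep], eb[keep], ew[keep]
        lo = np.minimum(ea, eb)
        hi = np.maximum(ea, eb)
        key = lo * n_regions + hi
        uniq, inv = np.unique(key, return_inverse=True)
        ew = np.bincount(inv, weights=ew)
        ea = (uniq // n_regions)
        eb = (uniq % n_regions)

        # propagate merged ids into the label image lazily via parent chain
        idx_map_flat = idx_map.ravel()
        idx_map_flat[flat] = parent[idx_map_flat[flat]]

    live = np.flatnonzero(n > 0)
    # compact relabel to 1..R in increasing old-id order
    remap = np.zeros(n_regions, dtype=np.int32)
    final_ids = np.unique(idx_map.ravel()[flat])
    remap[final_ids] = np.arange(1, final_ids.size + 1, dtype=np.int32)
    labels = np.zeros(vals.shape, dtype=np.int32)
    labels.ravel()[flat] = remap[idx_map.ravel()[flat]]

    table = pd.DataFrame({
        "label": remap[final_ids].astype(int),
        "n_pixels": n[final_ids].astype(int),
        "mean_tc": s[final_ids] / n[final_ids],
    })
    return SegmentationResult(labels, table)


def classify_segments(result: SegmentationResult, band: CanopyBand) -> SegmentationResult:
    """Assign Poplar/Soil/Weed per segment from its mean temperature."""
    table = result.table.copy()
    table["class"] = [band.classify(m) for m in table["mean_tc"]]
    return SegmentationResult(result.labels, table)


def apply_canopy_mask(mosaic: RadiometricMosaic,
                      result: SegmentationResult) -> RadiometricMosaic:
    """Null out non-canopy pixels: Soil/Weed become nodata in the mosaic."""
    if hasattr(result, "_pixel_mask"):
        keep = result._pixel_mask  # type: ignore[attr-defined]
    else:
        keep = result.canopy_mask
    values = np.where(keep, mosaic.values, np.nan).astype(np.float32)
    return RadiometricMosaic(values, mosaic.transform)
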