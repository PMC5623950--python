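"""Synthetic thermal-trial generator.

Emulates a two-plot short-rotation-coppice drought trial: a well-watered
(WW) and a moderate-drought (mDr) plot of clonally replicated genotypes on
a 2.5 m × 1 m planting grid, imaged by a thermal camera at 6-cm pixels.
Per-tree true canopy temperatures follow the variance-component model

    T_c(i, t, b) = mu_t + g_i + (g×t)_it + block_bt + eps,

with genotype, genotype-by-treatment, block-within-plot and residual
effects drawn from independent normals.  Crowns render as disks of the
true temperature plus sensor noise against a hot-soil background with
cooler weed patches, so segmentation by temperature is well posed.

All randomness flows from ``SyntheticConfig.seed`` through named
sub-streams (layout, effects, render-WW, render-mDr, gs), so every product
is bit-reproducible and tests can pin individual stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Affine, RadiometricMosaic

__all__ = ["SyntheticConfig", "TrueState", "make_layout", "draw_true_tc",
           "render_mosaic", "draw_gs", "TREATMENTS"]

TREATMENTS = ("WW", "mDr")

# sub-stream ids for SeedSequence(seed, stream)
_STREAMS = {"layout": 1, "effects": 2, "render_WW": 3, "render_mDr": 4, "gs": 5}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic trial.

    Defaults mirror the field experiment being emulated: 503 genotypes in
    four randomized complete blocks per plot, 12.7% mortality, 2.5 m × 1 m
    spacing, 6-cm pixels, population mean canopy temperatures 19.55 °C (WW)
    and 21.60 °C (mDr), air temperature 28.75 °C at flight time, and a
    camera with <0.05 °C thermal sensitivity.
    """

    seed: int = 0
    n_genotypes: int = 503
    n_blocks: int = 4
    reps_per_block: int = 1
    mortality_rate: float = 0.127
    row_spacing_m: float = 2.5
    within_row_spacing_m: float = 1.0
    pixel_size_m: float = 0.06
    mu_WW: float = 19.55
    mu_mDr: float = 21.60
    sigma_G: float = 1.2
    sigma_GT: float = 0.3
    sigma_block: float = 0.2
    sigma_eps: float = 0.9
    crown_radius_m: float = 0.45
    crown_radius_sd_m: float = 0.05
    soil_temp_mean: float = 40.0
    soil_temp_sd: float = 4.0
    weed_temp_mean: float = 12.0
    weed_temp_sd: float = 1.0
    weed_fraction: float = 0.05
    sensor_noise_sd: float = 0.05
    gs_slope: float = -80.0
    gs_intercept: float = -170.0
    gs_noise_sd: float = 60.0
    air_temperature: float = 28.75
    margin_m: float = 1.5
    border_rows: int = 0  # non-genotyped guard rows ringing each plot
    # truncation bounds keeping background outside the canopy temperature band
    canopy_band_low: float = 14.0
    canopy_band_high: float = 28.0

    def __post_init__(self):
        if self.n_genotypes < 1 or self.n_blocks < 1 or self.reps_per_block < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError("mortality_rate must lie in [0, 1]")
        if min(self.row_spacing_m, self.within_row_spacing_m,
               self.pixel_size_m) <= 0:
            raise ValueError("spacings and pixel size must be positive")
        for name in ("sigma_G", "sigma_GT", "sigma_block", "sigma_eps",
                     "crown_radius_sd_m", "soil_temp_sd", "weed_temp_sd",
                     "sensor_noise_sd", "gs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        band = (min(self.mu_WW, self.mu_mDr), max(self.mu_WW, self.mu_mDr))
        if self.soil_temp_mean <= band[1]:
            raise ValueError("soil mean temperature must exceed the canopy band")
        if self.weed_temp_mean >= band[0]:
            raise ValueError("weed mean temperature must lie below the canopy band")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived RNG sub-stream (deterministic per config seed)."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STREAMS[stream])))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueState:
    """Ground truth behind a rendered trial: effects and per-tree temperatures."""

    genotype_effects: pd.Series          # g_i, indexed by genotype_id
    gxt_effects: pd.DataFrame            # (g×t)_it, index genotype_id, cols treatment
    block_effects: pd.DataFrame          # block_bt, index block, cols treatment
    trees: pd.DataFrame                  # layout + residual + true_tc per tree


def make_layout(config: SyntheticConfig) -> pd.DataFrame:
    """Plant both plots: one tree per genotype × block × rep × treatment.

    Each plot is a randomized complete block design; genotype×rep order is
    shuffled independently within each block.  Rows run north-south with
    ``row_spacing_m`` between rows and ``within_row_spacing_m`` within a
    row; blocks stack along the rows; the mDr plot is offset east of the
    WW plot.  Each tree is independently dead with ``mortality_rate``.

    Returns a tree table with columns
    ``tree_id, genotype_id, block, treatment, x_m, y_m, alive``.
    """
    rng = config.rng("layout")
    n_pos = config.n_genotypes * config.reps_per_block
    # roughly square blocks in metres
    trees_per_row = max(1, round(np.sqrt(n_pos * config.row_spacing_m
                                         / config.within_row_spacing_m)))
    n_rows = int(np.ceil(n_pos / trees_per_row))
    block_height = trees_per_row * config.within_row_spacing_m
    plot_width = n_rows * config.row_spacing_m
    plot_gap = plot_width + 4 * config.row_spacing_m

    records = []
    tree_id = 0
    genotypes = np.repeat(np.arange(config.n_genotypes), config.reps_per_block)
    for t_idx, treatment in enumerate(TREATMENTS):
        x_off = t_idx * plot_gap
        for block in range(config.n_blocks):
            order = rng.permutation(n_pos)
            y_off = block * (block_height + config.within_row_spacing_m)
            for pos, gidx in enumerate(genotypes[order]):
                row = pos // trees_per_row
                within = pos % trees_per_row
                records.append((
                    tree_id,
                    f"G{gidx:04d}",
                    block + 1,
                    treatment,
                    x_off + row * config.row_spacing_m,
                    y_off + within * config.within_row_spacing_m,
                ))
                tree_id += 1
    layout = pd.DataFrame.from_records(
        records, columns=["tree_id", "genotype_id", "block", "treatment",
                          "x_m", "y_m"])
    layout["alive"] = rng.random(len(layout)) >= config.mortality_rate
    if config.border_rows > 0:
        layout["border"] = False
        border = _border_trees(config, layout, rng)
        layout = pd.concat([layout, border], ignore_index=True)
    return layout


def _border_trees(config: SyntheticConfig, layout: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Guard rings around each plot: rendered like trees, never analysed.

    Border trees carry genotype_id "BORDER", block 0 and border=True; they
    draw no genotype or interaction effect.
    """
    records = []
    tree_id = int(layout["tree_id"].max()) + 1
    for treatment, plot in layout.groupby("treatment"):
        x0, x1 = plot["x_m"].min(), plot["x_m"].max()
        y0, y1 = plot["y_m"].min(), plot["y_m"].max()
        for k in range(1, config.border_rows + 1):
            dx = k * config.row_spacing_m
            dy = k * config.within_row_spacing_m
            ys = np.arange(y0 - dy, y1 + dy + 1e-9,
                           config.within_row_spacing_m)
            ring = [(x0 - dx, y) for y in ys] + [(x1 + dx, y) for y in ys]
            xs = np.arange(x0, x1 + 1e-9, config.row_spacing_m)
            ring += [(x, y0 - dy) for x in xs] + [(x, y1 + dy) for x in xs]
            for x, y in ring:
                records.append((tree_id, "BORDER", 0, treatment, x, y))
                tree_id += 1
    border = pd.DataFrame.from_records(
        records, columns=["tree_id", "genotype_id", "block", "treatment",
                          "x_m", "y_m"])
    border["alive"] = rng.random(len(border)) >= config.mortality_rate
    border["border"] = True
    return border


def draw_true_tc(config: SyntheticConfig, layout: pd.DataFrame) -> TrueState:
    """Draw variance-component effects and per-tree true canopy temperatures.

    Effects are drawn once per level (genotype, genotype×treatment,
    block×plot) and reused across replicates; residuals are per tree.
    With all SDs zero every tree's true T_c equals its treatment mean.
    """
    rng = config.rng("effects")
    genotype_ids = [f"G{i:04d}" for i in range(config.n_genotypes)]
    g = pd.Series(rng.normal(0.0, config.sigma_G, config.n_genotypes),
                  index=genotype_ids, name="g")
    gxt = pd.DataFrame(
        rng.normal(0.0, config.sigma_GT, (config.n_genotypes, len(TREATMENTS))),
        index=genotype_ids, columns=list(TREATMENTS))
    blk = pd.DataFrame(
        rng.normal(0.0, config.sigma_block, (config.n_blocks, len(TREATMENTS))),
        index=np.arange(1, config.n_blocks + 1), columns=list(TREATMENTS))

    trees = layout.copy()
    mu = trees["treatment"].map({"WW": config.mu_WW, "mDr": config.mu_mDr})
    # border guard trees (genotype "BORDER", block 0) draw no level effects
    g_t = trees["genotype_id"].map(g).fillna(0.0).to_numpy()
    gxt_t = np.array([gxt.at[gid, tr] if gid in gxt.index else 0.0
                      for gid, tr in zip(trees["genotype_id"],
                                         trees["treatment"])])
    blk_t = np.array([blk.at[b, tr] if b in blk.index else 0.0
                      for b, tr in zip(trees["block"], trees["treatment"])])
    eps = rng.normal(0.0, config.sigma_eps, len(trees))
    trees["residual"] = eps
    trees["true_tc"] = mu.to_numpy() + g_t + gxt_t + blk_t + eps
    return TrueState(g, gxt, blk, trees)


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, size=None):
    if sd == 0:
        return np.full(size, float(np.clip(mean, low, high)))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def render_mosaic(config: SyntheticConfig, layout: pd.DataFrame,
                  true_state: TrueState, treatment: str) -> RadiometricMosaic:
    """Render one plot's thermal mosaic.

    Background is hot soil (truncated above the canopy band) with cooler
    weed patches (truncated below it).  Alive trees render as disk crowns
    of per-tree radius filled with true T_c plus per-pixel sensor noise;
    where crowns overlap, a pixel takes the temperature of the nearest
    tree center.  Dead trees leave bare background.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if config.pixel_size_m <= 0:
        raise ValueError("pixel size must be positive")
    rng = config.rng(f"render_{treatment}")
    trees = true_state.trees
    plot = trees[trees["treatment"] == treatment]

    px = config.pixel_size_m
    m = config.margin_m
    x0, x1 = plot["x_m"].min() - m, plot["x_m"].max() + m
    y0, y1 = plot["y_m"].min() - m, plot["y_m"].max() + m
    ncols = int(np.ceil((x1 - x0) / px))
    nrows = int(np.ceil((y1 - y0) / px))
    transform = Affine.north_up(x0 + px / 2.0, y1 - px / 2.0, px)

    values = _truncated_normal(rng, config.soil_temp_mean, config.soil_temp_sd,
                               low=config.canopy_band_high,
                               size=(nrows, ncols)).astype(np.float32)

    # weed patches: random disks until the requested background fraction
    if config.weed_fraction > 0:
        patch_radius_m = 0.3
        patch_area_px = np.pi * (patch_radius_m / px) ** 2
        n_patches = int(round(config.weed_fraction * values.size / patch_area_px))
        pr = int(np.ceil(patch_radius_m / px))
        for _ in range(n_patches):
            cr = rng.integers(0, nrows)
            cc = rng.integers(0, ncols)
            r_lo, r_hi = max(0, cr - pr), min(nrows, cr + pr + 1)
            c_lo, c_hi = max(0, cc - pr), min(ncols, cc + pr + 1)
            rr, cc_ = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                                  indexing="ij")
            inside = ((rr - cr) ** 2 + (cc_ - cc) ** 2) * px**2 <= patch_radius_m**2
            n_in = int(inside.sum())
            if n_in:
                values[r_lo:r_hi, c_lo:c_hi][inside] = _truncated_normal(
                    rng, config.weed_temp_mean, config.weed_temp_sd,
                    high=config.canopy_band_low, size=n_in)

    # crowns: nearest-center rule on overlap
    alive = plot[plot["alive"]]
    radii = _truncated_normal(rng, config.crown_radius_m,
                              config.crown_radius_sd_m, low=0.05,
                              size=len(alive))
    dist_best = np.full((nrows, ncols), np.inf, dtype=np.float32)
    owner_tc = np.full((nrows, ncols), np.nan, dtype=np.float32)
    inv = transform.inverse()
    for (x, y, tc), radius in zip(alive[["x_m", "y_m", "true_tc"]].to_numpy(),
                                  radii):
        c_ctr, r_ctr = inv(x, y)
        w = int(np.ceil(radius / px)) + 1
        r_lo = max(0, int(np.floor(r_ctr)) - w)
        r_hi = min(nrows, int(np.ceil(r_ctr)) + w + 1)
        c_lo = max(0, int(np.floor(c_ctr)) - w)
        c_hi = min(ncols, int(np.ceil(c_ctr)) + w + 1)
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                             indexing="ij")
        xs, ys = transform(cc, rr)
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        take = (d2 <= radius**2) & (d2 < dist_best[r_lo:r_hi, c_lo:c_hi])
        dist_best[r_lo:r_hi, c_lo:c_hi][take] = d2[take]
        owner_tc[r_lo:r_hi, c_lo:c_hi][take] = tc

    crown = np.isfinite(owner_tc)
    noise = rng.normal(0.0, config.sensor_noise_sd, int(crown.sum())) \
        if config.sensor_noise_sd > 0 else 0.0
    values[crown] = owner_tc[crown] + noise
    return RadiometricMosaic(values, transform)


def draw_gs(true_state: TrueState, config: SyntheticConfig,
            trees: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-tree stomatal conductance from the linear gs–(T_c − T_a) relation.

    gs = intercept + slope · (T_c − T_a) + noise, floored at zero
    (mmol m⁻² s⁻¹).  Uses true per-tree canopy temperatures of alive trees.
    """
    rng = config.rng("gs")
    src = true_state.trees if trees is None else trees
    src = src[src["alive"]]
    delta = src["true_tc"].to_numpy() - config.air_temperature
    gs = config.gs_intercept + config.gs_slope * delta
    if config.gs_noise_sd > 0:
        gs = gs + rng.normal(0.0, config.gs_noise_sd, len(src))
    out = src[["tree_id", "genotype_id", "treatment"]].copy()
    out["tc_minus_ta"] = delta
    out["gs"] = np.maximum(np.asarray(gs, dtype=float), 0.0)
    return out.reset_index(drop=True)
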