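"""End-to-end orchestration: mosaics + tree table → statistics and SSI.

``run_pipeline`` realizes the full analysis: segmentation (multilevel
Otsu and/or region merging), canopy-buffer temperature extraction,
genotypic summaries with replicate filtering, block adjustment, the
ANOVA/REML/heritability battery, cross-method agreement tests, the SSI
selection, and (optionally) the stomatal-conductance validation
regression.  All products are written as CSV/JSON plus a plain-text
report; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drought_index import PopulationReference, compute_ssi_table, select_tolerant
from .extraction import extract_tc, filter_replicates, summarize_genotypes
from .phenostats import (anova_two_way, bartlett_test, block_adjust, boxcox_fit,
                         gs_regression, paired_t, reml_components, shape_stats,
                         spearman_rho)
from .raster import read_mosaic, write_mosaic
from .segmentation import (CANOPY_BANDS, CanopyBand, apply_canopy_mask,
                           build_histogram, classify_otsu_levels,
                           classify_segments, otsu_thresholds,
                           region_merge_segmentation)
from .synthetic import (SyntheticConfig, TREATMENTS, draw_gs, draw_true_tc,
                        make_layout, render_mosaic)

log = logging.getLogger("thermopheno")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_bundle",
           "segment_mosaic", "analyze_method"]


@dataclass
class PipelineConfig:
    """Inputs and options of one pipeline run."""

    mosaics: dict                      # treatment -> raster path
    tree_table: str
    out_dir: str = "thermopheno_out"
    gs_table: str | None = None
    method: str = "both"               # otsu | region_merge | both
    bands: dict = field(default_factory=lambda: {
        "WW": (15.0, 27.0), "mDr": (14.0, 28.0)})
    buffer_radius: float = 0.40
    min_reps: int = 3
    otsu_classes: int = 9
    otsu_bins: int = 256
    otsu_mode: str = "level"
    rm_scale: float = 10.0
    rm_shape: float = 0.1
    rm_compactness: float = 0.5
    ss_type: int = 1
    paired: bool = True
    boxcox: str = "auto"               # auto (gate on Bartlett) | always | never
    block_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.method not in {"otsu", "region_merge", "both"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.buffer_radius <= 0:
            raise ValueError("buffer radius must be positive")
        for tr, band in self.bands.items():
            lo, hi = band
            if not lo < hi:
                raise ValueError(f"invalid band for {tr}: {band}")
        if self.boxcox not in {"auto", "always", "never"}:
            raise ValueError("boxcox must be auto, always or never")

    def validate_paths(self):
        missing = [p for p in [*self.mosaics.values(), self.tree_table]
                   if not Path(p).exists()]
        if self.gs_table and not Path(self.gs_table).exists():
            missing.append(self.gs_table)
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def segment_mosaic(mosaic, treatment: str, method: str, config: PipelineConfig):
    """Run one segmentation route and return the canopy-masked mosaic."""
    lo, hi = config.bands[treatment]
    band = CanopyBand(lo, hi)
    if method == "otsu":
        hist = build_histogram(mosaic, config.otsu_bins)
        thresholds, eta = otsu_thresholds(hist, config.otsu_classes)
        seg = classify_otsu_levels(mosaic, thresholds, band,
                                   mode=config.otsu_mode)
        log.info("otsu %s: eta=%.4f, %d levels", treatment, eta,
                 seg.n_segments)
    elif method == "region_merge":
        seg = region_merge_segmentation(mosaic, scale=config.rm_scale,
                                        shape=config.rm_shape,
                                        compactness=config.rm_compactness)
        seg = classify_segments(seg, band)
        log.info("region_merge %s: %d segments", treatment, seg.n_segments)
    else:
        raise ValueError(f"unknown method {method!r}")
    return apply_canopy_mask(mosaic, seg), seg


def analyze_method(mosaics: dict, trees: pd.DataFrame, method: str,
                   config: PipelineConfig) -> dict:
    """Segment, extract and run the statistical battery for one method."""
    records = []
    for treatment, mosaic in mosaics.items():
        masked, _seg = segment_mosaic(mosaic, treatment, method, config)
        plot_trees = trees[trees["treatment"] == treatment]
        rec = extract_tc(masked, plot_trees, config.buffer_radius)
        records.append(rec)
    tree_tc = pd.concat(records, ignore_index=True)

    merged = tree_tc.merge(trees, on="tree_id")
    usable = merged[merged["alive"] & merged["tc"].notna()].copy()

    # block adjustment, gated per plot on a one-way block ANOVA
    from scipy import stats as sps
    adjusted = usable["tc"].to_numpy().copy()
    block_ps = {}
    for treatment, plot_df in usable.groupby("treatment"):
        groups = [g["tc"].to_numpy() for _, g in plot_df.groupby("block")
                  if len(g) >= 2]
        p = float(sps.f_oneway(*groups).pvalue) if len(groups) >= 2 else 1.0
        block_ps[treatment] = p
        if p <= config.block_alpha:
            idx = usable.index.get_indexer(plot_df.index)
            adjusted[idx] = block_adjust(plot_df["tc"].to_numpy(),
                                         plot_df["block"].to_numpy())
    usable["tc_adj"] = adjusted

    summaries = summarize_genotypes(
        usable[["tree_id", "tc_adj", "n_pixels"]].rename(
            columns={"tc_adj": "tc"}), trees)
    retained = filter_replicates(summaries, config.min_reps)
    keep_ids = set(retained["genotype_id"])
    analysis = usable[usable["genotype_id"].isin(keep_ids)]

    out = {"tree_tc": tree_tc, "summaries": summaries, "retained": retained,
           "block_p": block_ps}
    if len(keep_ids) >= 2:
        groups = [g["tc_adj"].to_numpy()
                  for _, g in analysis.groupby("treatment")]
        bart = bartlett_test(*groups)
        y = analysis["tc_adj"].to_numpy()
        transform = None
        if config.boxcox == "always" or (config.boxcox == "auto"
                                         and bart.p_value <= 0.05):
            spec, y = boxcox_fit(y, analysis["genotype_id"].to_numpy(),
                                 analysis["treatment"].to_numpy())
            transform = spec
        anova = anova_two_way(analysis["genotype_id"], analysis["treatment"],
                              y, ss_type=config.ss_type)
        comps = reml_components(analysis["genotype_id"],
                                analysis["treatment"], y)
        shape = {tr: shape_stats(df["mean_tc"])
                 for tr, df in retained.groupby("treatment")}
        pop = PopulationReference.from_summaries(retained)
        ssi_table = compute_ssi_table(retained, pop)
        out.update({
            "bartlett": bart, "boxcox": transform, "anova": anova,
            "components": comps, "h2_within": comps.h2_within(),
            "h2_combined": comps.h2_combined(), "shape": shape,
            "population": pop, "ssi": ssi_table,
            "selection": select_tolerant(ssi_table, pop),
        })
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per ``config`` and write all outputs."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trees = pd.read_csv(config.tree_table)
    mosaics = {tr: read_mosaic(path) for tr, path in config.mosaics.items()}

    methods = ["otsu", "region_merge"] if config.method == "both" \
        else [config.method]
    results = {}
    for method in methods:
        try:
            results[method] = analyze_method(mosaics, trees, method, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{method}' failed: {exc}") from exc
        _write_method_outputs(out_dir / method, results[method])

    cross = {}
    if len(methods) == 2:
        cross = _cross_method(results["otsu"], results["region_merge"],
                              config.paired)
        with open(out_dir / "cross_method.json", "w") as fh:
            json.dump(cross, fh, indent=2, sort_keys=True)

    if config.gs_table:
        gs_df = pd.read_csv(config.gs_table)
        fit = gs_regression(gs_df["gs"], gs_df["tc_minus_ta"])
        results["gs_fit"] = fit
        with open(out_dir / "gs_regression.json", "w") as fh:
            json.dump(dataclasses.asdict(fit), fh, indent=2, sort_keys=True)

    _write_report(out_dir / "report.txt", config, results, cross)
    results["cross_method"] = cross
    return results


def _cross_method(a: dict, b: dict, paired: bool) -> dict:
    out = {}
    for treatment in TREATMENTS:
        wa = a["retained"].query("treatment == @treatment") \
            .set_index("genotype_id")["mean_tc"]
        wb = b["retained"].query("treatment == @treatment") \
            .set_index("genotype_id")["mean_tc"]
        common = wa.index.intersection(wb.index)
        if len(common) < 3:
            continue
        rho = spearman_rho(wa[common], wb[common])
        tt = paired_t(wa[common], wb[common], paired=paired)
        out[treatment] = {"spearman_rho": rho.statistic,
                          "spearman_p": rho.p_value,
                          "t_statistic": tt.statistic, "t_p": tt.p_value,
                          "n": int(len(common))}
    return out


def _write_method_outputs(path: Path, res: dict) -> None:
    path.mkdir(parents=True, exist_ok=True)
    res["tree_tc"].to_csv(path / "tree_tc.csv", index=False,
                          float_format="%.6f")
    res["summaries"].to_csv(path / "genotype_summary.csv", index=False,
                            float_format="%.6f")
    res["retained"].to_csv(path / "genotype_summary_retained.csv", index=False,
                           float_format="%.6f")
    if "anova" in res:
        res["anova"].to_csv(path / "anova.csv", float_format="%.6g")
        res["ssi"].to_csv(path / "ssi.csv", index=False, float_format="%.6f")
        comps = res["components"]
        payload = {
            "sigma2_G": comps.sigma2_G, "sigma2_GT": comps.sigma2_GT,
            "sigma2_eps": comps.sigma2_eps, "r_within": comps.r_within,
            "r_experiment": comps.r_experiment,
            "n_treatments": comps.n_treatments,
            "H2_within": res["h2_within"], "H2_combined": res["h2_combined"],
        }
        with open(path / "variance_components.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        with open(path / "selection.json", "w") as fh:
            json.dump(res["selection"], fh, indent=2, sort_keys=True)


def _write_report(path: Path, config: PipelineConfig, results: dict,
                  cross: dict) -> None:
    lines = [f"thermopheno {__version__}", "", "configuration:"]
    lines += [f"  {k}: {v}" for k, v in sorted(config.to_dict().items())]
    for method, res in results.items():
        if not isinstance(res, dict) or "summaries" not in res:
            continue
        lines += ["", f"[{method}]",
                  f"  genotypes retained: {res['retained']['genotype_id'].nunique()}"]
        if "anova" in res:
            comps = res["components"]
            lines += [
                f"  block ANOVA p: {res['block_p']}",
                f"  Bartlett: chi2={res['bartlett'].statistic:.4g} "
                f"p={res['bartlett'].p_value:.4g}",
                f"  variance components: G={comps.sigma2_G:.5g} "
                f"GxT={comps.sigma2_GT:.5g} eps={comps.sigma2_eps:.5g}",
                f"  H2 within={res['h2_within']:.4f} "
                f"combined={res['h2_combined']:.4f}",
                f"  tolerant fraction: {res['selection']['fraction_tolerant']:.4f}",
            ]
    if cross:
        lines += ["", "[cross-method agreement]"]
        for tr, d in cross.items():
            lines.append(f"  {tr}: rho={d['spearman_rho']:.4f} "
                         f"t={d['t_statistic']:.4f} (p={d['t_p']:.3g})")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# simulation bundle


def simulate_bundle(config: SyntheticConfig, out_dir,
                    raster_format: str = "asc") -> dict:
    """Generate a full synthetic trial on disk.

    Writes one mosaic per treatment, the tree table, the per-tree gs
    table and the generator config; returns the paths plus the in-memory
    truth for testing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = make_layout(config)
    true_state = draw_true_tc(config, layout)
    paths = {"mosaics": {}}
    for treatment in TREATMENTS:
        mosaic = render_mosaic(config, layout, true_state, treatment)
        p = out_dir / f"mosaic_{treatment}.{raster_format}"
        write_mosaic(mosaic, p)
        paths["mosaics"][treatment] = str(p)
    tree_path = out_dir / "trees.csv"
    layout.to_csv(tree_path, index=False)
    gs = draw_gs(true_state, config)
    gs_path = out_dir / "gs.csv"
    gs.to_csv(gs_path, index=False, float_format="%.6f")
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    paths.update({"tree_table": str(tree_path), "gs_table": str(gs_path),
                  "config": str(cfg_path), "layout": layout,
                  "true_state": true_state})
    return paths
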