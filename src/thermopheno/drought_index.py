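"""Stress Susceptibility Index and drought-tolerance selection.

For each genotype with mean canopy temperatures T_c under well-watered
(WW) and moderate-drought (mDr) regimes, the Stress Susceptibility
Index is

    SSI = [1 - T_c_mDr / T_c_WW] / [1 - T̄_c_mDr / T̄_c_WW],

where the bars denote population means over the analysed cohort.
SSI = 0 means the genotype's temperature did not change under drought;
SSI = 1 means it changed exactly like the population; SSI in (0, 1)
means a smaller-than-average relative increase, the putatively
drought-tolerant band.

Genotypes are also placed in the biplot quadrants of
X = T_c_mDr − T_c_WW versus Y = T_c_mDr − T̄_c_mDr; putative tolerance
requires the fourth quadrant (hotter under drought, but cooler than the
population under drought) together with SSI strictly inside (0, 1).
Temperatures are used on the °C scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PopulationReference", "tc_ratio", "ssi", "quadrant_classify",
           "compute_ssi_table", "select_tolerant"]


@dataclass(frozen=True)
class PopulationReference:
    """Population mean T_c per treatment over the analysed genotype set."""

    mean_ww: float
    mean_mdr: float
    mean_ratio: float = float("nan")  # mean of per-genotype ratios, if known

    @property
    def ratio(self) -> float:
        if self.mean_ww == 0:
            raise ZeroDivisionError("population WW mean is zero")
        return self.mean_mdr / self.mean_ww

    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame) -> "PopulationReference":
        """Build from a genotype summary table (genotype_id, treatment, mean_tc)."""
        wide = summaries.pivot(index="genotype_id", columns="treatment",
                               values="mean_tc").dropna()
        return cls(mean_ww=float(wide["WW"].mean()),
                   mean_mdr=float(wide["mDr"].mean()),
                   mean_ratio=float((wide["mDr"] / wide["WW"]).mean()))


def tc_ratio(tc_mdr: float, tc_ww: float) -> float:
    """Plain quotient T_c_mDr / T_c_WW on the °C scale."""
    if tc_ww == 0:
        raise ZeroDivisionError("T_c under WW is zero")
    return tc_mdr / tc_ww


def ssi(tc_mdr: float, tc_ww: float, pop: PopulationReference,
        use_mean_of_ratios: bool = False) -> float:
    """Stress Susceptibility Index of one genotype.

    The denominator uses the ratio of population mean temperatures by
    default; ``use_mean_of_ratios`` switches to the population mean of
    per-genotype ratios.
    """
    pop_ratio = pop.mean_ratio if use_mean_of_ratios else pop.ratio
    if pop_ratio == 1.0 or not np.isfinite(pop_ratio):
        raise ZeroDivisionError(
            "SSI undefined: population mDr/WW temperature ratio equals 1")
    return (1.0 - tc_ratio(tc_mdr, tc_ww)) / (1.0 - pop_ratio)


def quadrant_classify(tc_mdr: float, tc_ww: float,
                      pop: PopulationReference) -> str:
    """Biplot quadrant of X = T_c_mDr − T_c_WW, Y = T_c_mDr − T̄_c_mDr.

    Q1: X>0,Y>0; Q2: X<0,Y>0; Q3: X<0,Y<0; Q4: X>0,Y<0.  Points on an
    axis go to the lower-numbered adjacent quadrant (deterministic,
    measure-zero in practice).
    """
    x = tc_mdr - tc_ww
    y = tc_mdr - pop.mean_mdr
    if y >= 0:
        return "Q1" if x >= 0 else "Q2"
    return "Q3" if x <= 0 else "Q4"


def compute_ssi_table(summaries: pd.DataFrame,
                      pop: PopulationReference | None = None,
                      use_mean_of_ratios: bool = False) -> pd.DataFrame:
    """Per-genotype ratio, SSI, quadrant and tolerant flag.

    ``summaries`` is a tidy genotype summary (genotype_id, treatment,
    mean_tc); only genotypes present in both treatments are scored.  The
    population reference defaults to the means over that same cohort.
    """
    wide = summaries.pivot(index="genotype_id", columns="treatment",
                           values="mean_tc").dropna()
    if pop is None:
        pop = PopulationReference(float(wide["WW"].mean()),
                                  float(wide["mDr"].mean()),
                                  float((wide["mDr"] / wide["WW"]).mean()))
    rows = []
    for gid, rec in wide.iterrows():
        tc_ww, tc_mdr = float(rec["WW"]), float(rec["mDr"])
        ratio = tc_ratio(tc_mdr, tc_ww)
        value = ssi(tc_mdr, tc_ww, pop, use_mean_of_ratios)
        quad = quadrant_classify(tc_mdr, tc_ww, pop)
        rows.append((gid, tc_ww, tc_mdr, ratio, value, quad,
                     quad == "Q4" and 0.0 < value < 1.0))
    return pd.DataFrame(rows, columns=["genotype_id", "tc_ww", "tc_mdr",
                                       "ratio", "ssi", "quadrant", "tolerant"])


def select_tolerant(records: pd.DataFrame,
                    pop: PopulationReference | None = None) -> dict:
    """Tolerant genotype set plus descriptive population fractions.

    Tolerant ⟺ quadrant Q4 and 0 < SSI < 1 (strict).  Also reports the
    share of genotypes above each population mean temperature, the share
    of mDr/WW ratios above the population mean ratio, and the shares with
    ratios in (1, mean_ratio] and in [0.79, 1].
    """
    if pop is None:
        pop = PopulationReference(float(records["tc_ww"].mean()),
                                  float(records["tc_mdr"].mean()),
                                  float(records["ratio"].mean()))
    n = len(records)
    tolerant = records[records["tolerant"]]
    mean_ratio = (pop.mean_ratio if np.isfinite(pop.mean_ratio)
                  else float(records["ratio"].mean()))
    quad_counts = records["quadrant"].value_counts().to_dict()
    return {
        "tolerant_genotypes": sorted(tolerant["genotype_id"].tolist()),
        "n_genotypes": n,
        "fraction_tolerant": len(tolerant) / n if n else float("nan"),
        "fraction_above_mean_ww": float((records["tc_ww"] > pop.mean_ww).mean()),
        "fraction_above_mean_mdr": float((records["tc_mdr"] > pop.mean_mdr).mean()),
        "fraction_ratio_above_mean": float((records["ratio"] > mean_ratio).mean()),
        "fraction_ratio_1_to_mean": float(
            ((records["ratio"] > 1.0) & (records["ratio"] <= mean_ratio)).mean()),
        "fraction_ratio_079_to_1": float(
            ((records["ratio"] >= 0.79) & (records["ratio"] <= 1.0)).mean()),
        "quadrant_counts": {q: int(quad_counts.get(q, 0))
                            for q in ("Q1", "Q2", "Q3", "Q4")},
    }
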