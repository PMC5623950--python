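"""Small published reference datasets shipped with the package.

``parental_phenotypes`` holds the printed mean phenotypes of the four
parental poplar genotypes (Poli, 58-861, P36, P64) under the two water
treatments: ground-truth stomatal conductance (gs, mmol m⁻² s⁻¹) and
canopy-minus-air temperature (T_c − T_a, °C) extracted by the two
segmentation routes.  These eight genotype × treatment means anchor the
gs validation regression (R² ≈ 0.49, negative slope).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["parental_phenotypes", "AIR_TEMPERATURE_C"]

#: air temperature (°C) at the time of the thermal survey
AIR_TEMPERATURE_C = 28.75

_ROWS = [
    # genotype, treatment, gs, gs_se, dT_region_merge, se, dT_otsu, se
    ("Poli",   "WW",  700, 60,  -7.86, 1.33, -7.86, 1.33),
    ("58-861", "WW",  422, 32,  -9.48, 1.25, -9.29, 1.44),
    ("P36",    "WW",  631, 95,  -9.25, 0.80, -9.05, 0.99),
    ("P64",    "WW",  639, 120, -9.66, 0.69, -9.66, 0.69),
    ("Poli",   "mDr", 434, 16,  -7.08, 0.73, -7.08, 0.70),
    ("58-861", "mDr", 154, 6,   -5.77, 0.36, -5.95, 0.18),
    ("P36",    "mDr", 414, 215, -7.82, 1.50, -7.82, 1.49),
    ("P64",    "mDr", 366, 45,  -5.96, 1.21, -5.99, 1.17),
]


def parental_phenotypes() -> pd.DataFrame:
    """Parental genotype × treatment means (8 rows).

    Columns: ``genotype, treatment, gs, gs_se,
    tc_minus_ta_region_merge, tc_minus_ta_region_merge_se,
    tc_minus_ta_otsu, tc_minus_ta_otsu_se``.
    """
    return pd.DataFrame(_ROWS, columns=[
        "genotype", "treatment", "gs", "gs_se",
        "tc_minus_ta_region_merge", "tc_minus_ta_region_merge_se",
        "tc_minus_ta_otsu", "tc_minus_ta_otsu_se"])
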