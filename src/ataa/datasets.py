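"""Bundled reference data.

A ten-mouse cohort (ascending-aorta elastic modulus, unloaded wall
thickness, lifespan with right-censoring at 25 months, and tortuosity
index) used in examples, the acceptance report, and regression tests.
Two animals lack mechanical data; their modulus and thickness are imputed
with the mean of the other eight (``modulus_imputed`` marks them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import CohortTable

__all__ = [
    "reference_cohort",
    "imputation_modulus",
    "rcr_outlet_parameters",
    "BIOMARKER_RANGES",
]

_ROWS = [
    # subject_id, sex, E [MPa] (None = imputed), h [mm], lifespan [mo], ATI
    ("15469_3", "F", None, None, 12.4, 35.4),
    ("15398_3", "M", 0.47, 0.142, 13.3, 52.0),
    ("15392_1", "M", 2.23, 0.129, 17.8, 45.3),
    ("15392_2", "M", 1.16, 0.122, 18.2, 59.5),
    ("15466_1", "F", 0.88, 0.125, 21.9, 53.6),
    ("15398_1", "M", 1.22, 0.140, 22.4, 37.9),
    ("15466_3", "F", 1.59, 0.122, 25.0, 39.9),
    ("15474_2", "F", 0.93, 0.180, 25.0, 38.8),
    ("15474_3", "F", 0.64, 0.162, 25.0, 22.8),
    ("15389_1", "M", None, None, 25.0, 28.7),
]

CENSOR_LEVEL = 25.0


def reference_cohort(impute: bool = True) -> CohortTable:
    """The bundled ten-subject cohort as a :class:`~ataa.stats.CohortTable`.

    With ``impute=True`` the two missing moduli/thicknesses are filled with
    the mean of the eight measured values (rounded to the printed
    precision: two decimals for the modulus, three for the thickness).
    """
    df = pd.DataFrame(_ROWS, columns=[
        "subject_id", "sex", "elastic_modulus_mpa", "wall_thickness_mm",
        "lifespan_months", "ati"])
    df["modulus_imputed"] = df["elastic_modulus_mpa"].isna()
    if impute:
        e_mean = round(df["elastic_modulus_mpa"].mean(), 2)
        h_mean = round(df["wall_thickness_mm"].mean(), 3)
        df["elastic_modulus_mpa"] = df["elastic_modulus_mpa"].fillna(e_mean)
        df["wall_thickness_mm"] = df["wall_thickness_mm"].fillna(h_mean)
    df["censored"] = np.isclose(df["lifespan_months"], CENSOR_LEVEL)
    return CohortTable(df, censor_level=CENSOR_LEVEL)


def imputation_modulus() -> float:
    """Mean of the eight measured elastic moduli (MPa), the value used to
    impute the two subjects without mechanical data."""
    vals = [r[2] for r in _ROWS if r[2] is not None]
    return float(np.mean(vals))


def rcr_outlet_parameters() -> dict[str, dict[str, float]]:
    """Literature-based three-element Windkessel parameters per outlet.

    Resistances in Pa*s/mm^3, compliance in mm^3/Pa.
    """
    return {
        "left subclavian artery": {"r_p": 19.58, "c_wk": 5.5e-4, "r_d": 286.2},
        "left common carotid": {"r_p": 44.70, "c_wk": 3.23e-4, "r_d": 488.0},
        "brachiocephalic trunk": {"r_p": 21.55, "c_wk": 3.54e-4, "r_d": 443.2},
        "outlet": {"r_p": 10.30, "c_wk": 5.41e-4, "r_d": 443.2},
    }


#: Observed cohort ranges for each biomarker (used by the cohort generator).
BIOMARKER_RANGES: dict[str, tuple[float, float]] = {
    "P_max": (110.0, 172.0),          # mmHg
    "vMs_max": (320.0, 770.0),        # kPa
    "Re_max": (143.0, 227.0),
    "OSI_min": (3.3e-8, 1.2e-5),
    "OSI_mean": (0.17, 0.38),
    "TAWSS_mean": (0.9, 3.42),        # Pa
    "TAWSS_max": (6.1, 11.0),         # Pa
    "TAWSS_min": (0.005, 0.33),       # Pa
    "Wo": (1.1, 2.3),
    "ATI": (22.8, 59.5),
    "D_max": (1.20, 3.30),            # mm
}

#: Observed two-to-six-month absolute-change ranges.
DELTA_RANGES: dict[str, tuple[float, float]] = {
    "P_max": (0.0, 67.5),
    "vMs_max": (10.0, 210.0),
    "Re_max": (18.0, 75.0),
    "OSI_min": (1e-9, 2e-6),
    "OSI_mean": (0.012, 0.063),
    "TAWSS_mean": (0.09, 4.3),
    "TAWSS_max": (0.064, 2.3),
    "Wo": (0.07, 1.2),
    "D_max": (0.01, 0.73),
}
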