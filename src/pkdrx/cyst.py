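"""Quantification of the 3D cyst-swelling assay downstream of imaging.

Wells of a 384-well plate carry gel-embedded renal epithelial cysts
co-exposed to forskolin (swelling inducer) and a test compound, in
quadruplicate.  Imaging yields per-well mean object (cyst) area, mean
nuclei area and roundness, and nuclei counts with/without an actin signal.
This module implements the readout math only: control-anchored percentage
cyst area, the apoptotic-nuclei fraction, and a z-score toxicity flag
against vehicle wells.  Segmentation is upstream and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CystError(ValueError):
    pass


WELL_COLUMNS = [
    "plate_id", "well_id", "compound", "concentration_um", "role",
    "mean_object_area", "mean_nuclei_area", "mean_nuclei_roundness",
    "nuclei_total", "nuclei_without_actin",
]

# staurosporin-like cytotoxicity: shrunken, fragmented (less round) nuclei
# and loss of the actin signal.  Sign is the direction of the toxic shift.
TOXIC_DIRECTIONS = {
    "mean_nuclei_area": -1,
    "mean_nuclei_roundness": -1,
    "fraction_apoptotic": +1,
}


def normalize_cyst_area(
    wells: pd.DataFrame,
    positive_role: str = "positive_control",
    negative_role: str = "negative_control",
) -> pd.Series:
    """Per-well cyst area as a percentage between the control anchors.

    The positive control (forskolin-only, maximal swelling) anchors 100%,
    the negative control 0%:  pct = (x - mean_neg) / (mean_pos - mean_neg)
    * 100.  Which well class anchors 100% is configurable via the role
    arguments.
    """
    pos = wells.loc[wells["role"] == positive_role, "mean_object_area"]
    neg = wells.loc[wells["role"] == negative_role, "mean_object_area"]
    if pos.empty or neg.empty:
        raise CystError("need at least one positive and one negative control well")
    mp, mn = float(pos.mean()), float(neg.mean())
    if mp == mn:
        raise CystError("positive and negative control means are equal; anchors undefined")
    pct = (wells["mean_object_area"] - mn) / (mp - mn) * 100.0
    pct.name = "cyst_area_pct"
    return pct


def fraction_apoptotic(nuclei_without_actin: int, nuclei_total: int) -> float:
    """Fraction of nuclei lacking an actin signal (apoptosis proxy)."""
    if nuclei_total <= 0:
        raise CystError("nuclei_total must be positive")
    if nuclei_without_actin < 0 or nuclei_without_actin > nuclei_total:
        raise CystError("nuclei_without_actin must lie in [0, nuclei_total]")
    return nuclei_without_actin / nuclei_total


def _well_metrics(wells: pd.DataFrame) -> pd.DataFrame:
    out = wells.copy()
    out["fraction_apoptotic"] = [
        fraction_apoptotic(int(w), int(t))
        for w, t in zip(wells["nuclei_without_actin"], wells["nuclei_total"])
    ]
    return out


def toxicity_flag(
    test_wells: pd.DataFrame,
    vehicle_wells: pd.DataFrame,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Flag conditions whose nuclei phenotype deviates toward toxicity.

    Each (compound, concentration) condition is flagged toxic iff any of
    nuclei area, nuclei roundness or apoptotic fraction lies more than
    ``z_threshold`` vehicle standard deviations from the vehicle mean in
    the staurosporin-like direction (smaller fragmented nuclei, more
    actin-negative nuclei).  Metrics with zero vehicle variance are skipped
    with a warning.
    """
    if len(vehicle_wells) < 3:
        raise CystError("need >= 3 vehicle wells to estimate the null distribution")
    veh = _well_metrics(vehicle_wells)
    tst = _well_metrics(test_wells)
    mu = {m: float(veh[m].mean()) for m in TOXIC_DIRECTIONS}
    sd = {m: float(veh[m].std(ddof=1)) for m in TOXIC_DIRECTIONS}
    rows = []
    for (compound, conc), sub in tst.groupby(["compound", "concentration_um"], sort=True):
        flagged = False
        worst = {}
        for metric, sign in TOXIC_DIRECTIONS.items():
            if sd[metric] == 0:
                warnings.warn(f"vehicle variance is zero for {metric}; metric skipped")
                continue
            z = sign * (float(sub[metric].mean()) - mu[metric]) / sd[metric]
            worst[metric] = z
            if z > z_threshold:
                flagged = True
        rows.append({"compound": compound, "concentration_um": conc, "toxic": flagged, **worst})
    return pd.DataFrame(rows)


def summarize_conditions(wells: pd.DataFrame, **norm_kwargs) -> pd.DataFrame:
    """Mean control-normalized cyst area per (compound, concentration)."""
    pct = normalize_cyst_area(wells, **norm_kwargs)
    tab = wells.assign(cyst_area_pct=pct)
    grp = (
        tab[tab["role"] == "test"]
        .groupby(["compound", "concentration_um"], sort=True)["cyst_area_pct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return grp.rename(columns={"mean": "cyst_area_pct", "std": "sd", "count": "n_wells"})
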