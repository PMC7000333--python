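#!/usr/bin/env python
"""Quantify a synthetic 3D cyst-assay plate: control-anchored cyst area per
condition and nuclei-based toxicity flags against vehicle wells."""

import numpy as np
import pandas as pd
from common import SEED, outdir

from pkdrx import cyst


def synthetic_plate(seed: int) -> pd.DataFrame:
    """Quadruplicate wells: forskolin-only swelling controls, rapamycin
    suppression controls, a vehicle row, an effective compound, an
    ineffective compound and a staurosporin-like toxic compound."""
    rng = np.random.default_rng(seed)
    rows = []

    def wells(compound, conc, role, area, na=100.0, nr=0.90, frac_apop=0.05):
        for i in range(4):
            nt = int(rng.integers(180, 220))
            rows.append(
                {
                    "plate_id": "P1", "well_id": f"{compound}_{conc}_{i}", "compound": compound,
                    "concentration_um": conc, "role": role,
                    "mean_object_area": float(area * rng.normal(1, 0.05)),
                    "mean_nuclei_area": float(na * rng.normal(1, 0.03)),
                    "mean_nuclei_roundness": float(nr * rng.normal(1, 0.01)),
                    "nuclei_total": nt,
                    "nuclei_without_actin": int(round(frac_apop * nt)),
                }
            )

    wells("forskolin", 5.0, "positive_control", 1000.0)
    wells("forskolin+rapamycin", 5.0, "negative_control", 250.0)
    wells("vehicle", 0.0, "test", 980.0)
    for conc, area in [(10.0, 900.0), (50.0, 600.0), (100.0, 400.0)]:
        wells("effective-drug", conc, "test", area)
    for conc in (10.0, 100.0):
        wells("ineffective-drug", conc, "test", 990.0)
    wells("staurosporin", 0.25, "toxic_control", 300.0, na=45.0, nr=0.55, frac_apop=0.55)
    return pd.DataFrame(rows)


def main() -> None:
    plate = synthetic_plate(SEED)
    summary = cyst.summarize_conditions(plate)
    print("cyst area, % of forskolin-only control (0% = suppressed):")
    print(summary.round(1).to_string(index=False))

    vehicle = plate[(plate["compound"] == "vehicle")]
    test = plate[plate["role"].isin(["test", "toxic_control"]) & (plate["compound"] != "vehicle")]
    tox = cyst.toxicity_flag(test, vehicle, z_threshold=3.0)
    print("toxicity flags (z > 3 vs vehicle on nuclei area/roundness/apoptotic fraction):")
    print(tox.round(2).to_string(index=False))

    out = outdir()
    summary.to_csv(out / "cyst_area_summary.tsv", sep="\t", index=False)
    tox.to_csv(out / "cyst_toxicity.tsv", sep="\t", index=False)
    print(f"wrote cyst_area_summary.tsv, cyst_toxicity.tsv -> {out}")


if __name__ == "__main__":
    main()
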