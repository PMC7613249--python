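"""Lipid preprocessing demonstration on a clinically scaled table.

Maps the synthetic LDL trait onto a mg/dl scale, derives LDL by the
Friedewald equation where no direct assay exists (TG <= 155 mg/dl),
applies the x1.43 statin adjustment and the +15 mm Hg antihypertensive
SBP correction, and writes the processed table with provenance columns.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lipidmr.preprocess import process_phenotypes
from lipidmr.simulate import SyntheticCohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", default="results/data")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    cohort = SyntheticCohort.read(Path(args.data_dir) / "ldl_cohort")
    rng = np.random.default_rng(cohort.params.seed + 100)
    n = cohort.n

    # clinical scale: measured LDL centred at 138 mg/dl, SD 34 mg/dl
    x = cohort.exposure_measured
    ldl_mgdl = (138.0 + 34.0 * (x - x.mean()) / x.std()).clip(min=30.0)
    tg = np.exp(rng.normal(np.log(140), 0.35, n))
    hdl = rng.normal(55, 12, n).clip(20)
    raw = pd.DataFrame({
        "total_chol": ldl_mgdl + hdl + tg / 5.0,
        "hdl": hdl,
        "triglycerides": tg,
        # 70% of participants have a direct assay; rest rely on Friedewald
        "ldl_direct": np.where(rng.random(n) < 0.7, ldl_mgdl, np.nan),
        "on_statin": cohort.on_statin,
        "sbp": cohort.covariates["sbp"],
        "on_antihypertensive": cohort.covariates["on_antihypertensive"].astype(bool),
    })
    processed = process_phenotypes(raw)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    processed.to_csv(out / "processed_phenotypes.csv", index=False)

    counts = processed["ldl_source"].value_counts()
    print("LDL provenance:", dict(counts))
    print(f"statin-adjusted values: {int(processed['ldl_statin_adjusted'].sum())}")
    print(f"missing LDL (TG above ceiling, no direct assay): "
          f"{int((processed['ldl_source'] == 'missing').sum())}")


if __name__ == "__main__":
    main()
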