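"""Observational comparator: covariate-adjusted OLS of the outcome on the
measured exposure, percentile-group descriptive table with trend tests,
and the side-by-side discordance with the MR estimate.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lipidmr.observational import (chi2_trend, cuzick_trend,
                                   multivariable_ols, percentile_grouping)
from lipidmr.preprocess import bsa_dubois
from lipidmr.simulate import SyntheticCohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", default="results/data")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    cohort = SyntheticCohort.read(Path(args.data_dir) / "ldl_cohort")
    exposure = np.where(cohort.on_statin,
                        cohort.exposure_measured * cohort.params.ldl_reduction_factor,
                        cohort.exposure_measured)
    cov = cohort.covariates
    bsa = np.array([bsa_dubois(h, w) for h, w in zip(cov["height"], cov["weight"])])
    C = np.column_stack([cov["age"], cov["sex"], np.log(cov["bmi"]), bsa,
                         cov["sbp"], np.log(cov["hba1c"]), cov["cvd_present"]])

    obs = multivariable_ols(cohort.outcome, exposure, C)
    print(f"observational beta = {obs.beta:.3f} "
          f"(95% CI {obs.ci_low:.3f} to {obs.ci_high:.3f}, p = {obs.p:.2g}) "
          f"vs causal truth {cohort.params.causal_beta} -- "
          f"{'SIGN-FLIPPED' if np.sign(obs.beta) != np.sign(cohort.params.causal_beta) else 'concordant'}")

    groups = percentile_grouping(exposure)
    order = ["0-50%", "51-75%", "76-90%", "91-95%", "96-100%"]
    rows = []
    for var, vals in [("age", cov["age"].to_numpy()),
                      ("sbp", cov["sbp"].to_numpy()),
                      ("outcome", cohort.outcome)]:
        trend = cuzick_trend(vals, groups, order)
        rec = {"variable": var, "p_trend": trend.p}
        for g in order:
            sub = vals[groups == g]
            rec[g] = f"{sub.mean():.1f} ± {sub.std():.1f}"
        rows.append(rec)
    statin_counts = [int(cohort.on_statin[groups == g].sum()) for g in order]
    sizes = [int((groups == g).sum()) for g in order]
    ct = chi2_trend(statin_counts, sizes)
    rows.append({"variable": "on_statin (n)", "p_trend": ct.p,
                 **{g: f"{c} ({c / s:.1%})" for g, c, s in zip(order, statin_counts, sizes)}})

    table = pd.DataFrame(rows)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "table1_percentile_groups.csv", index=False)
    print(table.to_string(index=False))
    print(f"group sizes {sizes} sum to n = {sum(sizes)}")
    print("statin use rises across genetic-LDL percentiles "
          f"(chi-square trend p = {ct.p:.2g})")


if __name__ == "__main__":
    main()
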