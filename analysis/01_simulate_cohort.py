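"""Generate the synthetic study data: an individual-level cohort of
~17,000 participants with ~101 instrument variants per lipid, plus
non-overlapping two-sample GWAS summary statistics.

Writes cohort CSVs (phenotypes, dosages, variants, truth sidecar) and
exposure/outcome summary TSVs under results/data/.
"""

import argparse
from pathlib import Path

from lipidmr.simulate import (SimulationParams, simulate_cohort,
                              simulate_two_sample, write_gwas_summary)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/data")
    ap.add_argument("--n", type=int, default=17000)
    ap.add_argument("--n-variants", type=int, default=101)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = SimulationParams(n_individuals=args.n, n_variants=args.n_variants,
                              causal_beta=0.5, target_r2=0.108, seed=args.seed)
    cohort = simulate_cohort(params)
    cohort.write(out / "ldl_cohort")
    print(f"cohort: n = {cohort.n}, variants = {len(cohort.variants)}, "
          f"statin users = {int(cohort.on_statin.sum())} "
          f"({cohort.on_statin.mean():.1%})")

    exp_sum, out_sum, _ = simulate_two_sample(
        params, seeds=(args.seed + 1, args.seed + 2))
    write_gwas_summary(exp_sum, out / "ldl_exposure_gwas.tsv")
    write_gwas_summary(out_sum, out / "lv_outcome_gwas.tsv")
    print(f"two-sample summaries: exposure n = {int(exp_sum['n'].iloc[0]):,}, "
          f"outcome n = {int(out_sum['n'].iloc[0]):,}")


if __name__ == "__main__":
    main()
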