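"""End-to-end orchestration: simulate -> preprocess -> GRS -> one-sample MR
-> two-sample MR -> observational, with the joint-significance rule.

A causal claim is flagged significant only when both the one-sample and
the two-sample MR support it at the configured alpha (strict inequality,
default 0.05).  The emitted tables mirror the layout of a clinical MR
report: one row per lipid-phenotype pair with observational and MR
effect sizes, confidence intervals, Durbin-Wu-Hausman p and instrument F
("table2"), and the summary-level IVW and Egger-intercept columns
("table3"), plus a diagnostics block (MR-PRESSO, Steiger, power).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from . import observational as obs_mod
from . import onesample, twosample
from .exceptions import ConfigError
from .simulate import SimulationParams, simulate_cohort, simulate_two_sample

DEFAULT_THRESHOLDS = {
    "p_gws": 5e-8,        # genome-wide significance for instrument selection
    "r2_clump": 0.01,     # LD clumping ceiling
    "egger_alpha": 0.10,  # Egger-intercept pleiotropy flag
    "joint_alpha": 0.05,  # joint one-/two-sample significance rule
    "weak_f": 10.0,       # weak-instrument F threshold
}

DEFAULT_LIPIDS = {
    # target_r2 mirrors the variance the three lipid scores explain
    "ldl": {"target_r2": 0.108, "causal_beta": 0.5},
    "hdl": {"target_r2": 0.073, "causal_beta": 0.0},
    "triglycerides": {"target_r2": 0.050, "causal_beta": 0.5},
}

DEFAULT_PHENOTYPES = ("lvedv", "lvef", "lv_mass")


@dataclass
class AnalysisConfig:
    """Serializable configuration for one full pipeline run."""
    n_individuals: int = 17000
    n_variants: int = 101
    n_exposure: int = 188577
    n_outcome: int = 16923
    confounder_loadings: tuple = (1.5, -1.5)
    lipids: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LIPIDS.items()})
    phenotypes: tuple = DEFAULT_PHENOTYPES
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_boot: int = 500
    n_presso_sim: int = 1000
    run_two_sample: bool = True
    run_presso: bool = True
    run_steiger: bool = True
    seed: int = 0

    def validate(self):
        for key in ("egger_alpha", "joint_alpha"):
            if not (0 < self.thresholds[key] < 1):
                raise ConfigError(f"threshold {key} must lie in (0, 1)")
        if not (0 < self.thresholds["p_gws"] < 1):
            raise ConfigError("p_gws must lie in (0, 1)")
        return self

    def to_yaml(self, path=None):
        d = dataclasses.asdict(self)
        d["confounder_loadings"] = list(self.confounder_loadings)
        d["phenotypes"] = list(self.phenotypes)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text):
        text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() else str(path_or_text)
        d = yaml.safe_load(text)
        d["confounder_loadings"] = tuple(d["confounder_loadings"])
        d["phenotypes"] = tuple(d["phenotypes"])
        return cls(**d)

    def config_hash(self):
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    table2: pd.DataFrame
    table3: pd.DataFrame
    diagnostics: dict
    manifest: dict

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table2.to_csv(outdir / "table2_onesample.tsv", sep="\t", index=False)
        if len(self.table3):
            self.table3.to_csv(outdir / "table3_twosample.tsv", sep="\t", index=False)
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(self.diagnostics, fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def joint_significance(one_sample_p: float, two_sample_p: float,
                       alpha: float = 0.05) -> bool:
    """True iff both MR designs support the effect at strictly p < alpha."""
    return (one_sample_p < alpha) and (two_sample_p < alpha)


def _sub_seed(seed, *indices):
    """Deterministic child seed below 2**31 from the master seed."""
    ss = np.random.SeedSequence([int(seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: AnalysisConfig, outdir=None) -> ResultsBundle:
    """Run the full synthetic analysis for every lipid-phenotype pair.

    Deterministic given ``config.seed``: every stage derives its own seed
    from the master via SeedSequence spawning keyed on the (lipid,
    phenotype) indices.
    """
    config.validate()
    th = config.thresholds
    t2_rows, t3_rows = [], []
    diagnostics = {}

    for li, (lipid, spec) in enumerate(sorted(config.lipids.items())):
        for pi, pheno in enumerate(config.phenotypes):
            seed = _sub_seed(config.seed, li, pi)
            params = SimulationParams(
                n_individuals=config.n_individuals,
                n_variants=config.n_variants,
                causal_beta=float(spec["causal_beta"]),
                confounder_loadings=tuple(config.confounder_loadings),
                target_r2=float(spec["target_r2"]),
                seed=seed,
            )
            cohort = simulate_cohort(params)

            # exposure: measured lipid, statin-adjusted back to the lifetime
            # scale (multiplicative inverse of the simulated on-treatment
            # attenuation; same convention as adjust_ldl_for_statin, applied
            # on the synthetic trait scale where values may be negative)
            exposure = np.where(cohort.on_statin,
                                cohort.exposure_measured * params.ldl_reduction_factor,
                                cohort.exposure_measured)

            model = grs_mod.GrsModel(
                variant_ids=cohort.variants["variant_id"].tolist(),
                weights=cohort.variants["gamma"].to_numpy(),
                effect_alleles=cohort.variants["effect_allele"].tolist(),
                provenance={"p_threshold": th["p_gws"], "r2_threshold": th["r2_clump"]})
            score = grs_mod.compute_grs(cohort.dosages, model)
            strength = grs_mod.variance_explained(exposure, score)

            cov = cohort.covariates
            bsa = 0.007184 * cov["height"] ** 0.725 * cov["weight"] ** 0.425
            C = np.column_stack([cov["age"], cov["sex"], bsa]
                                + [cov[f"pc{k}"] for k in range(1, 6)])

            iv = onesample.tsls(cohort.outcome, exposure, score, C)
            obs = obs_mod.multivariable_ols(cohort.outcome, exposure, C)
            dwh = onesample.durbin_wu_hausman(cohort.outcome, exposure, score, C)
            power = onesample.min_detectable_effect(onesample.PowerSpec(
                n=cohort.n, r2_gx=strength.r2,
                sd_exposure=float(np.std(exposure)),
                sd_outcome=float(np.std(cohort.outcome))))

            t2_rows.append({
                "lipid": lipid, "phenotype": pheno,
                "obs_beta": obs.beta, "obs_ci_low": obs.ci_low,
                "obs_ci_high": obs.ci_high, "obs_p": obs.p,
                "mr_beta": iv.beta, "mr_ci_low": iv.ci_low,
                "mr_ci_high": iv.ci_high, "mr_p": iv.p,
                "dwh_p": dwh.p, "f_stat": strength.f_stat,
                "grs_r2": strength.r2, "n": cohort.n,
                "min_detectable_effect": power,
                "true_beta": params.causal_beta, "seed": seed,
            })

            key = f"{lipid}:{pheno}"
            diagnostics[key] = {"weak_instrument": strength.weak_instrument}

            if config.run_two_sample:
                exp_sum, out_sum, _ = simulate_two_sample(
                    params, n_exposure=config.n_exposure,
                    n_outcome=config.n_outcome,
                    seeds=(_sub_seed(seed, 1), _sub_seed(seed, 2)))
                h = twosample.harmonize(exp_sum, out_sum)
                ivw_res = twosample.ivw(h, robust=True, penalized=True)
                egger = twosample.mr_egger(h)
                wmed = twosample.weighted_median(h, n_boot=config.n_boot,
                                                seed=_sub_seed(seed, 3))
                wmode = twosample.weighted_mode(h, n_boot=config.n_boot,
                                               seed=_sub_seed(seed, 4))
                t3_rows.append({
                    "lipid": lipid, "phenotype": pheno,
                    "ivw_beta": ivw_res.beta, "ivw_ci_low": ivw_res.ci_low,
                    "ivw_ci_high": ivw_res.ci_high, "ivw_p": ivw_res.p,
                    "egger_beta": egger.beta, "egger_intercept": egger.extras["egger_intercept"],
                    "egger_intercept_p": egger.extras["egger_intercept_p"],
                    "wmedian_beta": wmed.beta, "wmedian_p": wmed.p,
                    "wmode_beta": wmode.beta, "wmode_p": wmode.p,
                    "n_variants": ivw_res.n_variants,
                    "joint_significant": joint_significance(
                        iv.p, ivw_res.p, th["joint_alpha"]),
                    "true_beta": params.causal_beta,
                })
                if config.run_presso:
                    pres = twosample.mr_presso(h, n_sim=config.n_presso_sim,
                                               seed=_sub_seed(seed, 5))
                    diagnostics[key]["presso"] = {
                        "global_p": pres.global_p,
                        "outlier_ids": pres.outlier_ids,
                        "distortion_p": pres.distortion_p,
                    }
                if config.run_steiger:
                    st = twosample.steiger(
                        h, n_exposure=config.n_exposure,
                        n_outcome=config.n_outcome,
                        var_exposure=float(np.var(cohort.exposure_true)),
                        var_outcome=float(np.var(cohort.outcome)))
                    diagnostics[key]["steiger"] = {
                        "r2_gx": st.r2_gx, "r2_gy": st.r2_gy,
                        "direction_correct": st.direction_correct, "p": st.p,
                    }

    table2 = pd.DataFrame(t2_rows)
    table3 = pd.DataFrame(t3_rows)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_table2_rows": len(table2),
        "n_table3_rows": len(table3),
    }
    bundle = ResultsBundle(table2=table2, table3=table3,
                           diagnostics=diagnostics, manifest=manifest)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
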