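import numpy as np
import pandas as pd
import pytest

from lipidmr.exceptions import (ConfigError, DataError,
                                DegenerateInstrumentError)
from lipidmr.simulate import (SimulationParams, scramble_coding,
                              simulate_summary_stats, simulate_two_sample)
from lipidmr.twosample import (harmonize, ivw, mr_egger, mr_presso, mvmr,
                               scale_per_sd, steiger, wald_ratios,
                               weighted_median, weighted_mode)


def _hset(gamma, Gamma, se_gamma=None, se_Gamma=None, eaf=None):
    j = len(gamma)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(j)],
        "gamma": np.asarray(gamma, dtype=float),
        "se_gamma": np.asarray(se_gamma if se_gamma is not None else np.full(j, 0.01), dtype=float),
        "Gamma": np.asarray(Gamma, dtype=float),
        "se_Gamma": np.asarray(se_Gamma if se_Gamma is not None else np.full(j, 0.02), dtype=float),
        "eaf": np.asarray(eaf if eaf is not None else np.full(j, 0.3), dtype=float),
    })


# ------------------------------------------------------------- harmonization

def _gwas(ids, ea, oa, beta, eaf, se=0.01):
    j = len(ids)
    return pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": np.full(j, se),
        "p": np.full(j, 1e-10), "n": 1000,
    })


def test_harmonize_identical_coding_passthrough():
    e = _gwas(["v1", "v2"], ["A", "C"], ["G", "T"], [0.1, -0.2], [0.3, 0.4])
    o = _gwas(["v1", "v2"], ["A", "C"], ["G", "T"], [0.05, -0.1], [0.31, 0.41])
    h = harmonize(e, o)
    assert not h["sign_flipped"].any()
    assert not h["dropped_palindromic"].any()
    np.testing.assert_allclose(h["Gamma"], [0.05, -0.1])


def test_harmonize_swapped_alleles_flip():
    e = _gwas(["v1"], ["A"], ["G"], [0.1], [0.3])
    o = _gwas(["v1"], ["G"], ["A"], [0.05], [0.7])
    h = harmonize(e, o)
    assert h["sign_flipped"].iloc[0]
    assert h["Gamma"].iloc[0] == pytest.approx(-0.05)
    assert h["eaf_outcome"].iloc[0] == pytest.approx(0.3)


def test_harmonize_strand_flip_resolved():
    # outcome reported on the opposite strand: A/G vs T/C
    e = _gwas(["v1"], ["A"], ["G"], [0.1], [0.3])
    o = _gwas(["v1"], ["T"], ["C"], [0.05], [0.3])
    h = harmonize(e, o)
    assert not h["sign_flipped"].iloc[0]
    assert h["Gamma"].iloc[0] == pytest.approx(0.05)


def test_harmonize_ambiguous_palindrome_dropped():
    e = _gwas(["v1", "v2"], ["A", "A"], ["T", "T"], [0.1, 0.1], [0.5, 0.9])
    o = _gwas(["v1", "v2"], ["A", "A"], ["T", "T"], [0.05, 0.05], [0.5, 0.88])
    h = harmonize(e, o)
    assert h["dropped_palindromic"].tolist() == [True, False]


def test_harmonize_palindrome_aligned_by_frequency():
    # eaf on opposite sides of 0.5 implies opposite allele labelling
    e = _gwas(["v1"], ["A"], ["T"], [0.1], [0.8])
    o = _gwas(["v1"], ["A"], ["T"], [0.05], [0.2])
    h = harmonize(e, o)
    assert h["sign_flipped"].iloc[0]
    assert h["Gamma"].iloc[0] == pytest.approx(-0.05)


def test_harmonize_scrambled_round_trip(two_sample_sets):
    """Scrambled allele coding harmonizes back to the unscrambled ratios."""
    exp_sum, out_sum, _, _ = two_sample_sets
    h_ref = harmonize(exp_sum, out_sum)
    scr = scramble_coding(out_sum, seed=31)
    h_scr = harmonize(exp_sum, scr)
    r_ref = wald_ratios(h_ref).set_index("variant_id")["ratio"]
    r_scr = wald_ratios(h_scr).set_index("variant_id")["ratio"]
    np.testing.assert_allclose(r_scr, r_ref.loc[r_scr.index], rtol=1e-12)


def test_harmonize_disjoint_ids_errors():
    e = _gwas(["v1"], ["A"], ["G"], [0.1], [0.3])
    o = _gwas(["v9"], ["A"], ["G"], [0.1], [0.3])
    with pytest.raises(DataError):
        harmonize(e, o)


# -------------------------------------------------------------- wald ratios

def test_wald_ratio_formulas():
    h = _hset([0.1], [0.2], se_Gamma=[0.05])
    wr = wald_ratios(h)
    assert wr["ratio"].iloc[0] == pytest.approx(2.0)
    assert wr["se"].iloc[0] == pytest.approx(0.5)


def test_wald_ratio_zero_gamma_excluded():
    h = _hset([0.1, 0.0], [0.2, 0.3])
    assert len(wald_ratios(h)) == 1


# ---------------------------------------------------------------------- IVW

def test_ivw_degenerate_consensus():
    g = np.array([0.05, 0.1, 0.2, 0.4])
    h = _hset(g, 0.7 * g)
    for kwargs in ({}, {"mode": "fixed"}, {"robust": True},
                   {"penalized": True}, {"robust": True, "penalized": True}):
        res = ivw(h, **kwargs)
        assert res.beta == pytest.approx(0.7, abs=1e-9)
    assert ivw(h).heterogeneity_q == pytest.approx(0.0, abs=1e-18)


def test_ivw_matches_weighted_mean_of_ratios_oracle(clean_summary):
    res = ivw(clean_summary, mode="fixed")
    ratio = clean_summary["Gamma"] / clean_summary["gamma"]
    w = clean_summary["gamma"] ** 2 / clean_summary["se_Gamma"] ** 2
    oracle = np.sum(w * ratio) / np.sum(w)
    assert res.beta == pytest.approx(oracle, abs=1e-10)


def test_ivw_scale_equivariance(clean_summary):
    c = 3.0
    scaled = clean_summary.copy()
    scaled["gamma"] *= c
    scaled["se_gamma"] *= c
    assert ivw(scaled).beta == pytest.approx(ivw(clean_summary).beta / c, rel=1e-10)


def test_ivw_order_invariance(clean_summary):
    shuffled = clean_summary.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert ivw(shuffled).beta == pytest.approx(ivw(clean_summary).beta, abs=1e-12)
    assert (weighted_median(shuffled, n_boot=50, seed=2).beta
            == pytest.approx(weighted_median(clean_summary, n_boot=50, seed=2).beta, abs=1e-12))


def test_ivw_method_minimum():
    h = _hset([0.1], [0.05])
    with pytest.raises(DegenerateInstrumentError):
        ivw(h)
    with pytest.raises(ConfigError):
        ivw(_hset([0.1, 0.2], [0.05, 0.1]), mode="bogus")


# ------------------------------------------------------------------- Egger

def test_egger_exact_line_through_origin():
    g = np.array([-0.2, 0.05, 0.1, 0.3])
    res = mr_egger(_hset(g, 0.6 * g))
    assert abs(res.extras["egger_intercept"]) < 1e-10
    assert res.beta == pytest.approx(0.6, abs=1e-10)


def test_egger_recovers_directional_pleiotropy():
    """Mean estimated intercept tracks the injected pleiotropy mean."""
    intercepts = []
    for seed in range(100):
        h = simulate_summary_stats(n_variants=50, causal_beta=0.5,
                                   fraction_invalid=1.0,
                                   pleiotropy_mean=0.05, pleiotropy_sd=0.005,
                                   seed=seed)
        intercepts.append(mr_egger(h).extras["egger_intercept"])
    assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)


def test_egger_method_minimum():
    with pytest.raises(DegenerateInstrumentError):
        mr_egger(_hset([0.1, 0.2], [0.05, 0.1]))


# ---------------------------------------------------------- median and mode

def test_weighted_median_equal_weights_is_sample_median():
    g = np.ones(5)
    ratios = np.array([0.1, 0.4, 0.5, 0.6, 0.9])
    h = _hset(g, ratios * g, se_Gamma=np.full(5, 0.02))
    res = weighted_median(h, n_boot=50, seed=0)
    assert res.beta == pytest.approx(np.median(ratios), abs=1e-12)


def test_weighted_median_duplication_invariance():
    h = simulate_summary_stats(n_variants=21, seed=3)
    doubled = pd.concat([h, h]).reset_index(drop=True)
    doubled["variant_id"] = [f"v{i}" for i in range(len(doubled))]
    a = weighted_median(h, n_boot=10, seed=1).beta
    b = weighted_median(doubled, n_boot=10, seed=1).beta
    assert a == pytest.approx(b, abs=1e-12)


def test_weighted_mode_consensus_and_bandwidth_stability():
    g = np.ones(5)
    h = _hset(g, 0.5 * g)
    assert weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(0.5, abs=1e-9)

    # two well-separated clusters, the valid one measured far more
    # precisely: doubling the bandwidth keeps the argmax in the same basin
    g = np.ones(10)
    ratios = np.array([0.45, 0.48, 0.5, 0.52, 0.55, 0.5, 4.9, 5.0, 5.1, 5.0])
    se_G = np.array([0.02] * 6 + [0.2] * 4)
    h2 = _hset(g, ratios * g, se_Gamma=se_G)
    m1 = weighted_mode(h2, bandwidth_factor=1.0, n_boot=10, seed=0).beta
    m2 = weighted_mode(h2, bandwidth_factor=2.0, n_boot=10, seed=0).beta
    assert abs(m1 - 0.5) < 0.1 and abs(m2 - 0.5) < 0.1


# -------------------------------------------------------------------- MVMR

def test_mvmr_k1_equals_fixed_ivw(clean_summary):
    res_ivw = ivw(clean_summary, mode="fixed")
    res_mv = mvmr(clean_summary["Gamma"], clean_summary["se_Gamma"],
                  clean_summary["gamma"].to_numpy())[0]
    assert res_mv.beta == pytest.approx(res_ivw.beta, abs=1e-12)
    assert res_mv.se == pytest.approx(res_ivw.se, abs=1e-12)


def test_mvmr_joint_recovery():
    rng = np.random.default_rng(23)
    j = 80
    g1 = rng.normal(0.1, 0.03, j)
    g2 = 0.4 * g1 + rng.normal(0.08, 0.03, j)  # correlated instruments
    se_G = 0.01
    Gamma = 0.5 * g1 + 0.0 * g2 + rng.normal(0, se_G, j)
    res = mvmr(Gamma, np.full(j, se_G), np.column_stack([g1, g2]),
               exposure_names=["ldl", "hdl"])
    assert abs(res[0].beta - 0.5) < 3 * res[0].se
    assert abs(res[1].beta - 0.0) < 3 * res[1].se


def test_mvmr_zero_column_errors():
    g = np.random.default_rng(0).normal(0.1, 0.02, 10)
    with pytest.raises(DataError):
        mvmr(0.5 * g, np.full(10, 0.01), np.column_stack([g, np.zeros(10)]))


# ----------------------------------------------------------------- PRESSO

def test_presso_detects_gross_outlier():
    h = simulate_summary_stats(n_variants=25, causal_beta=0.5, seed=5)
    h.loc[3, "Gamma"] += 0.5  # gross pleiotropic outlier
    res = mr_presso(h, n_sim=500, seed=9)
    assert res.global_p < 0.05
    assert h.loc[3, "variant_id"] in res.outlier_ids
    assert res.beta_outlier_corrected is not None
    assert abs(res.beta_outlier_corrected - 0.5) < abs(res.beta_raw - 0.5)
    assert res.distortion_p is not None


def test_presso_clean_set_no_outliers():
    h = simulate_summary_stats(n_variants=25, causal_beta=0.5, seed=6)
    res = mr_presso(h, n_sim=300, seed=1)
    assert res.outlier_ids == []
    assert res.beta_outlier_corrected is None
    assert res.distortion_p is None


def test_presso_method_minimum():
    with pytest.raises(DegenerateInstrumentError):
        mr_presso(_hset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15]))


# ----------------------------------------------------------------- Steiger

def test_steiger_antisymmetry():
    h = simulate_summary_stats(n_variants=30, causal_beta=0.5, seed=8)
    fwd = steiger(h, 10000, 10000)
    swapped = h.rename(columns={"gamma": "Gamma", "Gamma": "gamma",
                                "se_gamma": "se_Gamma", "se_Gamma": "se_gamma"})
    rev = steiger(swapped, 10000, 10000)
    assert fwd.direction_correct != rev.direction_correct
    assert fwd.p == pytest.approx(rev.p, abs=1e-12)


def test_steiger_equal_r2_boundary():
    h = _hset([0.1, 0.2], [0.1, 0.2])
    res = steiger(h, 1000, 1000)
    assert res.direction_correct is None
    assert res.p == pytest.approx(1.0)


# -------------------------------------------------- noiseless identity, misc

def test_noiseless_identity_all_methods():
    params = SimulationParams(n_variants=20, causal_beta=0.7, seed=2)
    exp_sum, out_sum, _ = simulate_two_sample(params, analytic=True)
    h = harmonize(exp_sum, out_sum)
    assert ivw(h).beta == pytest.approx(0.7, abs=1e-9)
    assert ivw(h).heterogeneity_q == pytest.approx(0.0, abs=1e-6)
    assert mr_egger(h).beta == pytest.approx(0.7, abs=1e-6)
    assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.7, abs=1e-9)
    assert weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(0.7, abs=1e-3)


def test_scale_per_sd():
    h = simulate_summary_stats(n_variants=20, seed=4)
    res = ivw(h)
    sd = 34.0  # LDL SD in mg/dl
    scaled = scale_per_sd(res, sd)
    assert scaled.beta == pytest.approx(res.beta * sd)
    assert scaled.se == pytest.approx(res.se * sd)
    assert scaled.p == res.p
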