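import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from lipidmr.exceptions import (DataError, DegenerateInstrumentError)
from lipidmr.grs import (GrsModel, clump_variants, compute_grs,
                         grs_correlation, restrict_grs, variance_explained)


def _assocs(ids, ps):
    return pd.DataFrame({"variant_id": ids, "p": ps})


def test_clump_identity_ld_keeps_all():
    a = _assocs(list("abcd"), [1e-10, 1e-9, 1e-12, 1e-11])
    got = clump_variants(a, np.eye(4))
    assert sorted(got) == list("abcd")


def test_clump_perfect_proxy_keeps_best():
    a = _assocs(["v1", "v2"], [1e-10, 1e-9])
    ld = np.array([[1.0, 1.0], [1.0, 1.0]])
    assert clump_variants(a, ld) == ["v1"]


def test_clump_drops_nonsignificant():
    a = _assocs(["v1", "v2"], [1e-10, 1e-6])
    assert clump_variants(a, np.eye(2)) == ["v1"]


def _greedy_oracle(assocs, ld, p_thr, r2_thr):
    """Independent re-statement of greedy clumping: explicit loop over
    p-sorted candidates checking LD to every already-kept index."""
    items = [(p, str(v), i) for i, (v, p) in
             enumerate(zip(assocs["variant_id"], assocs["p"])) if p < p_thr]
    kept = []
    for p, v, i in sorted(items):
        if all(ld[i, j] < r2_thr for _, j in kept):
            kept.append((v, i))
    return [v for v, _ in kept]


def test_clump_matches_oracle_on_block_ld():
    rng = np.random.default_rng(0)
    for trial in range(20):
        m = 10
        ids = [f"v{j}" for j in range(m)]
        ps = rng.uniform(1e-12, 1e-9, m)
        # random block structure
        blocks = rng.integers(0, 3, m)
        ld = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                if blocks[i] == blocks[j]:
                    ld[i, j] = ld[j, i] = rng.uniform(0.02, 1.0)
        a = _assocs(ids, ps)
        got = clump_variants(a, ld, 5e-8, 0.01)
        assert got == _greedy_oracle(a, ld, 5e-8, 0.01)


def test_clump_invariant_to_row_order():
    rng = np.random.default_rng(1)
    m = 8
    ids = [f"v{j}" for j in range(m)]
    ps = rng.uniform(1e-12, 1e-9, m)
    ld = np.eye(m)
    ld[0, 1] = ld[1, 0] = 0.5
    ld[2, 3] = ld[3, 2] = 0.9
    a = _assocs(ids, ps)
    perm = rng.permutation(m)
    a2 = a.iloc[perm].reset_index(drop=True)
    ld2 = ld[np.ix_(perm, perm)]
    assert sorted(clump_variants(a, ld)) == sorted(clump_variants(a2, ld2))


def test_clump_rejects_asymmetric_ld():
    a = _assocs(["v1", "v2"], [1e-10, 1e-10])
    ld = np.array([[1.0, 0.2], [0.3, 1.0]])
    with pytest.raises(DataError):
        clump_variants(a, ld)


def test_compute_grs_trivial_and_oracle():
    model = GrsModel(variant_ids=["a", "b", "c"], weights=[0.5, -0.2, 1.0])
    assert np.all(compute_grs(np.zeros((4, 3)), model) == 0)
    single = GrsModel(variant_ids=["a"], weights=[0.7])
    assert compute_grs(np.array([[2.0]]), single)[0] == pytest.approx(1.4)
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, (5, 3)).astype(float)
    got = compute_grs(d, model)
    oracle = [sum(model.weights[j] * d[i, j] for j in range(3)) for i in range(5)]
    np.testing.assert_allclose(got, oracle)


def test_compute_grs_mean_imputation():
    model = GrsModel(variant_ids=["a"], weights=[1.0])
    d = np.array([[0.0], [2.0], [np.nan]])
    got = compute_grs(d, model)
    assert got[2] == pytest.approx(1.0)  # column mean of {0, 2}


def test_compute_grs_shape_mismatch():
    model = GrsModel(variant_ids=["a", "b"], weights=[1.0, 1.0])
    with pytest.raises(DataError):
        compute_grs(np.zeros((3, 3)), model)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(d=hnp.arrays(np.float64, (6, 3), elements=st.integers(0, 2).map(float)),
       w1=hnp.arrays(np.float64, 3, elements=st.floats(-2, 2)),
       w2=hnp.arrays(np.float64, 3, elements=st.floats(-2, 2)))
def test_grs_linearity(d, w1, w2):
    ids = ["a", "b", "c"]
    s12 = compute_grs(d, GrsModel(ids, w1 + w2))
    s1 = compute_grs(d, GrsModel(ids, w1))
    s2 = compute_grs(d, GrsModel(ids, w2))
    np.testing.assert_allclose(s12, s1 + s2, atol=1e-9)


def test_variance_explained_perfect_and_formula():
    x = np.arange(10, dtype=float)
    res = variance_explained(x, x)
    assert res.r2 == pytest.approx(1.0)
    assert math.isinf(res.f_stat)

    # orthogonal construction with exact R^2 = 0.5 at n = 102 -> F = 100
    n = 102
    rng = np.random.default_rng(0)
    s = rng.normal(0, 1, n)
    s -= s.mean()
    u = rng.normal(0, 1, n)
    u -= u.mean()
    u -= (u @ s) / (s @ s) * s                    # orthogonal to the score
    u *= np.linalg.norm(s) / np.linalg.norm(u)    # equal signal/noise norms
    res = variance_explained(s + u, s)
    assert res.r2 == pytest.approx(0.5, abs=1e-12)
    assert res.f_stat == pytest.approx(100.0, abs=1e-9)
    assert not res.weak_instrument


def test_variance_explained_monte_carlo_target():
    """Triglyceride anchor: target R^2 = 5.0% recovered within the
    tolerance band across seeds."""
    from lipidmr.simulate import SimulationParams, simulate_cohort
    for seed in range(20):
        params = SimulationParams(n_individuals=17000, n_variants=73,
                                  target_r2=0.050, seed=seed)
        cohort = simulate_cohort(params)
        res = variance_explained(cohort.exposure_true, cohort.true_score())
        assert 0.04 <= res.r2 <= 0.06


def test_variance_explained_affine_invariance():
    rng = np.random.default_rng(5)
    s = rng.normal(0, 1, 500)
    x = s + rng.normal(0, 1, 500)
    r_a = variance_explained(x, s).r2
    r_b = variance_explained(x, 3.5 * s - 2.0).r2
    assert r_a == pytest.approx(r_b, rel=1e-12)


def test_variance_explained_degenerate():
    with pytest.raises(DegenerateInstrumentError):
        variance_explained(np.arange(5, dtype=float), np.ones(5))


def test_grs_correlation_basics():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 10000)
    b = rng.normal(0, 1, 10000)
    r, p = grs_correlation({"a": a, "b": b})
    assert r.loc["a", "a"] == pytest.approx(1.0)
    assert abs(r.loc["a", "b"]) < 0.05  # independent scores


def test_grs_correlation_matches_covariance_formula():
    x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])
    y = np.array([2, 1, 4, 3, 6, 5, 8, 7, 10, 9.0])
    r, _ = grs_correlation([x, y])
    xc, yc = x - x.mean(), y - y.mean()
    oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert r.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)


def test_grs_correlation_constant_vector_errors():
    with pytest.raises(DegenerateInstrumentError):
        grs_correlation([np.ones(10), np.arange(10, dtype=float)])


def test_restrict_grs():
    m = 101
    model = GrsModel([f"v{j}" for j in range(m)], np.arange(m, dtype=float))
    same = restrict_grs(model, [])
    assert same.variant_ids == model.variant_ids

    excl = [f"v{j}" for j in range(32)]
    restricted = restrict_grs(model, excl)
    assert len(restricted.variant_ids) == 69
    assert restricted.variant_ids == [f"v{j}" for j in range(32, m)]  # order kept
    np.testing.assert_allclose(restricted.weights, np.arange(32, m, dtype=float))
    assert restricted.provenance["excluded_ids"] == sorted(excl)

    with pytest.raises(DegenerateInstrumentError):
        restrict_grs(model, [f"v{j}" for j in range(m - 1)])


def test_grs_model_tsv_round_trip(tmp_path):
    model = GrsModel(["v1", "v2"], [0.5, -0.3], effect_alleles=["A", "G"])
    path = tmp_path / "score.tsv"
    model.to_tsv(path)
    back = GrsModel.from_tsv(path)
    assert back.variant_ids == model.variant_ids
    np.testing.assert_allclose(back.weights, model.weights)
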