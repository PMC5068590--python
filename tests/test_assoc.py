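import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grsvol.assoc import (
    CovariatePolicy,
    fit_increment,
    permutation_p,
    results_frame,
    run_table,
)
from grsvol.exceptions import FitError, ValidationError
from grsvol.io import PhenotypeTable
from grsvol.prs import ScoreProfile


def normal_equations_oracle(y, g, X):
    """Independent fit: explicit normal equations + t distribution."""
    y = (y - y.mean()) / y.std(ddof=1)
    g = (g - g.mean()) / g.std(ddof=1)
    n = len(y)
    F = np.column_stack([np.ones(n), X, g])
    C = np.column_stack([np.ones(n), X])
    bF = np.linalg.solve(F.T @ F, F.T @ y)
    bC = np.linalg.solve(C.T @ C, C.T @ y)
    rssF = np.sum((y - F @ bF) ** 2)
    rssC = np.sum((y - C @ bC) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    df = n - F.shape[1]
    se = np.sqrt(rssF / df * np.linalg.inv(F.T @ F)[-1, -1])
    t = bF[-1] / se
    return {
        "beta": bF[-1],
        "p_nominal": 2 * stats.t.sf(abs(t), df),
        "delta_r2": (1 - rssF / tss) - (1 - rssC / tss),
    }


# fixed 6-sample dataset used for the frozen-oracle check
Y6 = np.array([1720.0, 1650.0, 1788.0, 1705.0, 1601.0, 1740.0])
G6 = np.array([0.3, -1.2, 0.8, 0.1, -0.9, 1.4])
X6 = np.column_stack(
    [
        np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0]),  # sex
        np.array([1.52e6, 1.40e6, 1.61e6, 1.48e6, 1.39e6, 1.55e6]),  # icv
    ]
)


def test_fit_increment_matches_normal_equations_oracle():
    got = fit_increment(Y6, G6, X6)
    exp = normal_equations_oracle(Y6, G6, X6)
    assert got["beta"] == pytest.approx(exp["beta"], abs=1e-10)
    assert got["p_nominal"] == pytest.approx(exp["p_nominal"], abs=1e-10)
    assert got["delta_r2"] == pytest.approx(exp["delta_r2"], abs=1e-10)
    assert got["n_used"] == 6


def test_fit_increment_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    yz = (Y6 - Y6.mean()) / Y6.std(ddof=1)
    gz = (G6 - G6.mean()) / G6.std(ddof=1)
    design = sm.add_constant(np.column_stack([X6, gz]))
    fit = sm.OLS(yz, design).fit()
    got = fit_increment(Y6, G6, X6)
    assert got["beta"] == pytest.approx(fit.params[-1], rel=1e-9)
    assert got["p_nominal"] == pytest.approx(fit.pvalues[-1], rel=1e-6)


def test_fit_increment_perfect_predictor():
    rng = np.random.default_rng(1)
    y = rng.normal(size=50)
    got = fit_increment(y, y, None)
    assert got["beta"] == pytest.approx(1.0, abs=1e-12)
    assert got["delta_r2"] == pytest.approx(1.0, abs=1e-12)
    assert got["p_nominal"] <= 1e-12


def test_fit_increment_null_large_n(rng):
    n = 10000
    X = rng.normal(size=(n, 2))
    y = X @ np.array([1.0, -2.0]) + rng.normal(size=n)
    g = rng.normal(size=n)  # independent of y
    got = fit_increment(y, g, X)
    assert got["delta_r2"] < 0.001


def test_fit_increment_null_p_uniform(rng):
    pvals = []
    for _ in range(200):
        y = rng.normal(size=80)
        g = rng.normal(size=80)
        pvals.append(fit_increment(y, g, None)["p_nominal"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_fit_increment_complete_cases(rng):
    n = 60
    y = rng.normal(size=n)
    g = rng.normal(size=n)
    X = rng.normal(size=(n, 2))
    base = fit_increment(y, g, X)["n_used"]
    y2 = y.copy()
    y2[:7] = np.nan
    assert fit_increment(y2, g, X)["n_used"] == base - 7


def test_fit_increment_rank_deficient(rng):
    n = 30
    y, g = rng.normal(size=n), rng.normal(size=n)
    x = rng.normal(size=n)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(FitError, match="collinear"):
        fit_increment(y, g, X)


def test_fit_increment_too_few_samples():
    with pytest.raises(FitError, match="too few"):
        fit_increment([1.0, 2, 3], [0.1, 0.2, 0.3], None)


def test_delta_r2_exact_identity(rng):
    # with z-scored y and g: delta_r2 = beta^2 * (orthogonal variance fraction of g)
    for _ in range(20):
        n = 150
        X = rng.normal(size=(n, 2))
        y = X @ rng.normal(size=2) + rng.normal(size=n)
        g = rng.normal(size=n) + 0.3 * y
        fit = fit_increment(y, g, X)
        gz = (g - g.mean()) / g.std(ddof=1)
        C = np.column_stack([np.ones(n), X])
        bg = np.linalg.lstsq(C, gz, rcond=None)[0]
        vg = np.sum((gz - C @ bg) ** 2) / np.sum(gz**2)
        assert fit["delta_r2"] == pytest.approx(fit["beta"] ** 2 * vg, abs=1e-10)


def test_beta_squared_equals_delta_r2_without_covariates(rng):
    for _ in range(10):
        y = rng.normal(size=100)
        g = rng.normal(size=100) + 0.4 * y
        fit = fit_increment(y, g, None)
        assert fit["beta"] ** 2 == pytest.approx(fit["delta_r2"], abs=1e-12)


def test_delta_r2_nonnegative(rng):
    for _ in range(30):
        n = 40
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        g = rng.normal(size=n)
        assert fit_increment(y, g, X)["delta_r2"] >= 0.0


# ---------------------------------------------------------------------------
# permutation
# ---------------------------------------------------------------------------

def test_permutation_p_deterministic(rng):
    y = rng.normal(size=100)
    g = rng.normal(size=100) + 0.2 * y
    X = rng.normal(size=(100, 2))
    a = permutation_p(y, g, X, n_perm=500, seed=42)
    b = permutation_p(y, g, X, n_perm=500, seed=42)
    assert a == b
    c = permutation_p(y, g, X, n_perm=500, seed=43)
    assert isinstance(c, float)


def test_permutation_p_zero_for_collinear(rng):
    y = rng.normal(size=300)
    assert permutation_p(y, y, None, n_perm=200, seed=0) == 0.0


def test_permutation_p_near_one_for_worst_fit(rng):
    # g orthogonal to y by construction -> observed p ~ 1, p_perm near 1
    n = 400
    y = rng.normal(size=n)
    g = rng.normal(size=n)
    yz = (y - y.mean()) / y.std(ddof=1)
    g = g - yz * (g @ yz) / (yz @ yz)  # residualize g on y exactly
    obs = fit_increment(y, g, None)
    assert obs["p_nominal"] > 0.999
    pp = permutation_p(y, g, None, n_perm=500, seed=1)
    assert pp > 0.95


def test_permutation_p_matches_nominal_under_null(rng):
    # exchangeable null: p_perm converges to p_nominal
    n = 300
    y = rng.normal(size=n)
    g = rng.normal(size=n)
    obs = fit_increment(y, g, None)["p_nominal"]
    pp = permutation_p(y, g, None, n_perm=4000, seed=7)
    assert pp == pytest.approx(obs, abs=0.04)


def test_permutation_estimators(rng):
    y = rng.normal(size=80)
    g = rng.normal(size=80)
    plain = permutation_p(y, g, None, n_perm=99, seed=5, estimator="plain")
    addone = permutation_p(y, g, None, n_perm=99, seed=5, estimator="add-one")
    assert addone == pytest.approx((plain * 99 + 1) / 100)


def test_permutation_freedman_lane_runs(rng):
    y = rng.normal(size=120)
    g = rng.normal(size=120) + 0.3 * y
    X = rng.normal(size=(120, 2))
    pp = permutation_p(y, g, X, n_perm=300, seed=3, method="freedman-lane")
    assert 0.0 <= pp <= 1.0


def test_permutation_p_granularity(rng):
    y = rng.normal(size=60)
    g = rng.normal(size=60)
    pp = permutation_p(y, g, None, n_perm=250, seed=9)
    assert (pp * 250) == pytest.approx(round(pp * 250))


def test_permutation_bad_args(rng):
    y, g = rng.normal(size=30), rng.normal(size=30)
    with pytest.raises(ValidationError):
        permutation_p(y, g, None, n_perm=0)
    with pytest.raises(ValueError):
        permutation_p(y, g, None, n_perm=10, method="bogus")


# ---------------------------------------------------------------------------
# run_table
# ---------------------------------------------------------------------------

def _toy_inputs(rng, n=120):
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    sex = rng.integers(0, 2, size=n).astype(float)
    icv = rng.normal(1.5e6, 1e5, size=n)
    age = rng.normal(25, 7, size=n)
    g = rng.normal(size=n)
    vol_signal = 1700 - 100 * sex + 5e-4 * icv - 60 * g + rng.normal(0, 50, size=n)
    vol_null = 7000 + 200 * sex + 1e-3 * icv + rng.normal(0, 400, size=n)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"sex": sex, "age": age, "icv": icv, "pallidum": vol_signal, "thalamus": vol_null},
            index=idx,
        ),
        ["pallidum", "thalamus"],
    )
    scores = pd.DataFrame({0.01: g, 0.5: rng.normal(size=n)}, index=idx)
    sp = ScoreProfile(scores, {0.01: 10, 0.5: 50})
    return pheno, {"SCZ&BD": sp}


def test_run_table_shape_and_order(rng):
    pheno, scores = _toy_inputs(rng)
    res = run_table(pheno, scores, n_perm=100, seed=0)
    assert len(res) == 2 * 2  # thresholds x ROIs
    assert [r.p_t for r in res] == [0.01, 0.01, 0.5, 0.5]  # threshold-major
    df = results_frame(res)
    assert set(df["roi"]) == {"pallidum", "thalamus"}


def test_run_table_signal_detected(rng):
    pheno, scores = _toy_inputs(rng)
    res = run_table(pheno, scores, n_perm=200, seed=0)
    by = {(r.roi, r.p_t): r for r in res}
    assert by[("pallidum", 0.01)].p_nominal < 0.05
    assert by[("pallidum", 0.01)].beta < 0
    assert by[("pallidum", 0.01)].p_perm is not None  # significant -> permuted
    assert by[("thalamus", 0.5)].p_perm is None  # null cell skipped by default


def test_run_table_perm_policy_all(rng):
    pheno, scores = _toy_inputs(rng)
    res = run_table(pheno, scores, n_perm=50, perm_policy="all", seed=0)
    assert all(r.p_perm is not None for r in res)
    res_none = run_table(pheno, scores, n_perm=50, perm_policy="none", seed=0)
    assert all(r.p_perm is None for r in res_none)


def test_run_table_deterministic(rng):
    pheno, scores = _toy_inputs(rng)
    r1 = run_table(pheno, scores, n_perm=100, perm_policy="all", seed=11)
    r2 = run_table(pheno, scores, n_perm=100, perm_policy="all", seed=11)
    assert [r.p_perm for r in r1] == [r.p_perm for r in r2]


def test_run_table_missing_roi(rng):
    pheno, scores = _toy_inputs(rng)
    with pytest.raises(ValidationError, match="hippocampus"):
        run_table(pheno, scores, rois=["hippocampus"], n_perm=10)


def test_run_table_all_missing_roi(rng):
    pheno, scores = _toy_inputs(rng)
    pheno.table["pallidum"] = np.nan
    with pytest.raises(ValidationError, match="pallidum"):
        run_table(pheno, scores, n_perm=10)


def test_run_table_empty_roi_list(rng):
    pheno, scores = _toy_inputs(rng)
    assert run_table(pheno, scores, rois=[], n_perm=10) == []


def test_covariate_policy_age():
    pol = CovariatePolicy()
    assert pol.covariates_for("thalamus") == ["sex", "icv"]
    assert pol.covariates_for("lateral_ventricles") == ["sex", "icv", "age"]


def test_run_table_complete_case_isolation(rng):
    # injecting missing volumes in one ROI leaves the other ROI untouched
    pheno, scores = _toy_inputs(rng)
    res_before = run_table(pheno, scores, n_perm=10, perm_policy="none")
    pheno.table.loc[pheno.table.index[:5], "pallidum"] = np.nan
    res_after = run_table(pheno, scores, n_perm=10, perm_policy="none")
    b4 = {(r.roi, r.p_t): r for r in res_before}
    af = {(r.roi, r.p_t): r for r in res_after}
    assert af[("pallidum", 0.01)].n_used == b4[("pallidum", 0.01)].n_used - 5
    assert af[("thalamus", 0.01)].beta == b4[("thalamus", 0.01)].beta
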