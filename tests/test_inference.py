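"""Factor extraction, PLS regression, component selection, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.cross_decomposition import PLSRegression

from neurocx.exceptions import DegenerateBatteryError, EmptyGroupError, SchemaError
from neurocx.inference import (
    AnalysisConfig,
    CVResult,
    PLSModel,
    bootstrap_coefficients,
    cross_validate,
    extract_gf_factor,
    fit_plsr,
    run_group_analysis,
    select_ncomp,
)
from neurocx.schema import TEST_NAMES
from neurocx.synthetic import CohortSpec, generate_feature_table, generate_test_scores


# ---------------------------------------------------------------------------
# gf factor
# ---------------------------------------------------------------------------


def test_identical_columns_give_total_variance(rng):
    base = rng.standard_normal(40)
    battery = pd.DataFrame({t: base + rng.normal(0, 1e-8, 40) for t in TEST_NAMES})
    res = extract_gf_factor(battery)
    assert res.explained_variance_pct == pytest.approx(100.0, abs=0.1)
    assert res.eigenvalue == pytest.approx(6.0, abs=0.01)


def test_independent_columns_give_one_sixth(rng):
    battery = pd.DataFrame(
        {t: rng.standard_normal(10_000) for t in TEST_NAMES}
    )
    res = extract_gf_factor(battery)
    assert res.explained_variance_pct == pytest.approx(100 / 6, abs=2.0)
    assert res.eigenvalue == pytest.approx(1.0, abs=0.12)


def test_single_factor_battery_matches_eigen_oracle(rng):
    """Equal loadings lambda imply a first eigenvalue 1 + 5*lambda^2 of
    the score correlation matrix; lambda = .7356 gives ~61.8%."""
    lam = 0.7356
    gf = rng.standard_normal(20_000)
    battery = generate_test_scores(gf, loadings=(lam,) * 6, seed=4)
    res = extract_gf_factor(battery)
    expected_pct = 100 * (1 + 5 * lam**2) / 6
    assert expected_pct == pytest.approx(61.8, abs=0.1)  # oracle self-check
    assert res.explained_variance_pct == pytest.approx(expected_pct, abs=1.5)


def test_factor_scores_standardized_and_recover_truth(rng):
    gf = rng.standard_normal(119)
    battery = generate_test_scores(gf, seed=8)
    res = extract_gf_factor(battery)
    assert res.scores.mean() == pytest.approx(0.0, abs=1e-10)
    assert res.scores.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    assert np.corrcoef(res.scores, gf)[0, 1] > 0.9


def test_degenerate_battery_rejected(rng):
    battery = pd.DataFrame({t: rng.standard_normal(30) for t in TEST_NAMES})
    battery["Number"] = 5.0
    with pytest.raises(DegenerateBatteryError):
        extract_gf_factor(battery)
    with pytest.raises(DegenerateBatteryError):
        extract_gf_factor(battery.iloc[:5])


# ---------------------------------------------------------------------------
# PLS regression
# ---------------------------------------------------------------------------


def test_single_predictor_single_lv_equals_simple_regression(rng):
    x = rng.standard_normal(40)
    y = 2.0 * x + rng.standard_normal(40)
    res = fit_plsr(x[:, None], y, 1)
    slope = np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1)
    # coefficient is on standardized-x scale
    assert res.coefficients[0] == pytest.approx(slope * x.std(ddof=1), rel=1e-10)
    assert np.allclose(res.predict(), y.mean() + slope * (x - x.mean()), atol=1e-10)


def test_full_rank_pls_equals_least_squares(rng):
    n, p = 30, 6
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    res = fit_plsr(X, y, p)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    beta, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
    assert np.allclose(res.coefficients, beta, atol=1e-8)


@pytest.mark.parametrize("k", [1, 3, 7])
def test_coefficients_match_sklearn(k, rng):
    """Independent cross-check against sklearn's NIPALS implementation."""
    X = rng.standard_normal((50, 12))
    y = X[:, 0] * 0.5 + rng.standard_normal(50)
    res = fit_plsr(X, y, k)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    sk = PLSRegression(n_components=k, scale=False).fit(Xs, y - y.mean())
    assert np.allclose(res.coefficients, sk.coef_.ravel(), atol=1e-10)


def test_orthogonal_response_explains_nothing(rng):
    X = rng.standard_normal((40, 5))
    # project y out of the column space of centered standardized X
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    y = rng.standard_normal(40)
    y = y - Xs @ np.linalg.lstsq(Xs, y, rcond=None)[0]
    res = fit_plsr(X, y, 3)
    assert res.y_variance_explained.sum() < 1e-6


def test_component_request_capped_with_warning(rng):
    X = rng.standard_normal((10, 4))
    y = rng.standard_normal(10)
    with pytest.warns(UserWarning, match="capped"):
        res = fit_plsr(X, y, 50)
    assert res.n_components <= 4


def test_y_variance_components_nonnegative_and_bounded(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    res = model.fit(3)
    assert np.all(res.y_variance_explained >= 0)
    assert res.y_variance_explained.sum() <= 100 + 1e-9


# ---------------------------------------------------------------------------
# cross-validation and component selection
# ---------------------------------------------------------------------------


def test_cv_curve_is_deterministic(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    a = model.cross_validate(4)
    b = model.cross_validate(4)
    assert np.array_equal(a.rmsep, b.rmsep)
    assert len(a) == 5  # components 0..4


def test_cv_zero_component_predicts_training_mean(rng):
    X = rng.standard_normal((12, 3))
    y = rng.standard_normal(12)
    cv = cross_validate(X, y, 2)
    # recompute column 0 by hand
    manual = []
    for i in range(12):
        others = np.delete(y, i)
        manual.append((y[i] - others.mean()) ** 2)
    assert cv.sq_residuals[:, 0] == pytest.approx(manual)


def test_strong_signal_drops_cv_curve(rng):
    X = rng.standard_normal((60, 10))
    y = X[:, 0] - X[:, 1] + 0.3 * rng.standard_normal(60)
    cv = cross_validate(X, y, 4)
    assert cv.rmsep[1] < cv.rmsep[0]
    assert select_ncomp(cv, "local_min") >= 1


@pytest.mark.parametrize(
    "curve, expected",
    [
        ([5, 3, 4, 2], 1),  # first local minimum
        ([9, 8, 7, 6, 5, 4, 3, 2, 1], 8),  # still decreasing at the end
        ([2, 3, 4, 5], 0),  # never improves
    ],
)
def test_local_min_selection(curve, expected):
    assert select_ncomp(np.array(curve, float), "local_min") == expected


def test_flat_curve_selects_zero_with_warning():
    with pytest.warns(UserWarning, match="flat"):
        assert select_ncomp(np.ones(5), "local_min") == 0


@pytest.mark.parametrize("k_star", [1, 2, 3])
def test_selectors_agree_on_sharp_minimum(k_star, rng):
    """On a curve with a single pronounced minimum both criteria choose
    the same component count."""
    n, kmax = 50, 5
    base = np.full(kmax + 1, 3.0)
    base[:k_star] = 6.0 - np.arange(k_star)  # steep descent into k_star
    base[k_star] = 0.5
    base[k_star + 1 :] = 0.9  # clear rise afterwards
    scale = 0.5 + rng.uniform(0, 1, size=n)
    sq = np.outer(scale, base)
    cv = CVResult(rmsep=np.sqrt(sq.mean(axis=0)), sq_residuals=sq)
    assert select_ncomp(cv, "local_min") == k_star
    assert select_ncomp(cv, "randomization", n_perm=500, seed=0) == k_star


def test_randomization_needs_residuals():
    with pytest.raises(ValueError):
        select_ncomp(np.array([3.0, 1.0, 2.0]), "randomization")


# ---------------------------------------------------------------------------
# bootstrap relevance
# ---------------------------------------------------------------------------


def test_bootstrap_requires_multiple_replicates(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    res = model.fit(1)
    with pytest.raises(ValueError):
        res.bootstrap_relevance(n_boot=1)


def test_bootstrap_seed_reproducibility(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    res = model.fit(1)
    a = res.bootstrap_relevance(n_boot=100, seed=5).frame
    b = res.bootstrap_relevance(n_boot=100, seed=5).frame
    pd.testing.assert_frame_equal(a, b)
    assert np.all(a["ci_low"] < a["ci_high"])


def test_strong_predictor_flagged_with_positive_sign(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    res = model.fit(1)
    report = res.bootstrap_relevance(n_boot=400, seed=2)
    row = report.frame.set_index("predictor").loc["AvgEnt_FL-FR"]
    assert row["relevant"] and row["sign"] == 1


def test_bc_intervals_available(small_feature_table):
    model = PLSModel.from_feature_table(small_feature_table)
    res = model.fit(1)
    report = res.bootstrap_relevance(n_boot=200, seed=3, ci_method="bc")
    assert report.ci_method == "bc"
    assert np.all(report.frame["ci_low"] < report.frame["ci_high"])


# ---------------------------------------------------------------------------
# group analysis
# ---------------------------------------------------------------------------


def _cohort_table(n=60, seed=0, beta=None):
    return generate_feature_table(
        CohortSpec(n_subjects=n, true_beta=beta, noise_sd=1.0, seed=seed)
    )


def test_group_analysis_shape_and_summary():
    table = _cohort_table(n=40, seed=1, beta={"AvgEnt_FL-FR": 0.9})
    cfg = AnalysisConfig(n_components=1, n_boot=200, n_perm=200, seed=0)
    out = run_group_analysis(table, "all", cfg)
    assert len(out.report.frame) == 45
    assert out.n_subjects == 40
    text = out.summary()
    assert "latent variables" in text and "relevant" in text


def test_group_filtering_and_empty_group():
    table = _cohort_table(n=24, seed=2)
    cfg = AnalysisConfig(n_components=1, n_boot=100, n_perm=100, seed=0)
    men = run_group_analysis(table, "men", cfg)
    assert men.n_subjects == 12
    table_w = table[table["sex"] == "W"].reset_index(drop=True)
    with pytest.raises(EmptyGroupError):
        run_group_analysis(table_w, "men", cfg)


def test_unknown_sex_codes_rejected():
    table = _cohort_table(n=20, seed=3)
    table.loc[0, "sex"] = "X"
    with pytest.raises(SchemaError):
        run_group_analysis(table, "all", AnalysisConfig(n_components=1, n_boot=50))


def test_exclusion_list_drops_subjects():
    table = _cohort_table(n=30, seed=4)
    cfg = AnalysisConfig(
        n_components=1, n_boot=100, n_perm=100, seed=0,
        exclude_subjects=("S0000", "S0001"),
    )
    out = run_group_analysis(table, "all", cfg)
    assert out.n_subjects == 28


def test_sex_stratified_null_groups_indistinguishable():
    """With no sex effect, men's and women's coefficient distributions
    overlap (rank test across the 45 predictors)."""
    table = _cohort_table(n=160, seed=6)
    cfg = AnalysisConfig(n_components=1, n_boot=100, n_perm=100, seed=1)
    men = run_group_analysis(table, "men", cfg)
    women = run_group_analysis(table, "women", cfg)
    stat = mannwhitneyu(
        men.results.coefficients, women.results.coefficients
    )
    assert stat.pvalue > 0.01
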