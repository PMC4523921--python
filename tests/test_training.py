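"""Regression fitting, AIC stepwise selection, correlations, CV, curation."""

import numpy as np
import pandas as pd
import pytest

from ppaffinity.synthetic import SyntheticDatasetSpec, make_regression_dataset
from ppaffinity.training import (
    AffinityRegressor,
    StepwiseAICRegressor,
    aic_stepwise,
    correlations,
    cross_validate,
    curate,
    fit_linear,
    gaussian_aic,
    grouped_eval,
)

MODEL6_TERMS = ["ICs_charged/charged", "ICs_charged/apolar",
                "ICs_polar/polar", "ICs_polar/apolar",
                "%NIS_apolar", "%NIS_charged"]


def test_noiseless_data_recovers_generator_exactly(noiseless_dataset):
    df, spec = noiseless_dataset
    result = fit_linear(df, list(spec.weights))
    for term, w in spec.weights.items():
        assert result.model.terms_[term] == pytest.approx(w, abs=1e-8)
    assert result.model.intercept_ == pytest.approx(spec.intercept, abs=1e-6)
    assert result.rmse == pytest.approx(0.0, abs=1e-8)
    assert result.r_pearson == pytest.approx(1.0)


def test_noisy_fit_rmse_near_sigma(noisy_dataset):
    df, spec = noisy_dataset
    result = fit_linear(df, list(spec.weights))
    assert 0.8 < result.rmse < 1.2
    assert result.p_value < 1e-6


def test_exact_interpolation_of_minimal_dataset():
    df = pd.DataFrame({"dg_exp": [-5.0, -7.0, -9.0],
                       "ICs_total": [10.0, 20.0, 30.0]})
    result = fit_linear(df, ["ICs_total"])
    assert result.r_pearson == pytest.approx(1.0)
    assert result.rmse == pytest.approx(0.0, abs=1e-10)


def test_too_few_records_rejected():
    df = pd.DataFrame({"dg_exp": [-5.0, -7.0], "ICs_total": [10.0, 20.0]})
    with pytest.raises(ValueError):
        fit_linear(df, ["ICs_total"])


def test_rank_deficient_design_names_collinear_terms(noisy_dataset):
    df, _ = noisy_dataset
    df = df.copy()
    df["BSA_twice"] = 2.0 * df["BSA_total"]
    from ppaffinity.models import PROPERTY_NAMES  # noqa: F401
    with pytest.raises(ValueError, match="collinear"):
        est = AffinityRegressor(terms=["BSA_total", "BSA_twice"])
        est.fit(df, df["dg_exp"])


def test_residuals_orthogonal_to_design(noisy_dataset):
    df, spec = noisy_dataset
    est = AffinityRegressor(terms=list(spec.weights))
    est.fit(df, df["dg_exp"])
    resid = np.abs(df["dg_exp"].to_numpy()) - est.predict(df)
    design = df[list(spec.weights)].to_numpy()
    assert np.max(np.abs(design.T @ resid)) < 1e-6 * len(df)


def test_stepwise_keeps_strong_terms_drops_pure_noise():
    true_w = {"ICs_polar/apolar": 0.3, "%NIS_apolar": -0.25}
    spec = SyntheticDatasetSpec(n=200, weights=true_w, intercept=10.0,
                                noise_sigma=0.5, seed=42)
    df = make_regression_dataset(spec)
    result = aic_stepwise(df, MODEL6_TERMS)
    assert set(true_w) <= set(result.selected_terms)
    assert set(result.selected_terms) <= set(MODEL6_TERMS)


def test_single_null_candidate_dropped_at_large_n():
    spec = SyntheticDatasetSpec(n=2000, weights={"ICs_polar/apolar": 0.3},
                                intercept=10.0, noise_sigma=1.0, seed=3)
    df = make_regression_dataset(spec)
    # ICs_charged/charged has true weight zero here
    result = aic_stepwise(df, ["ICs_charged/charged"])
    assert result.selected_terms == []


def test_empty_candidate_set_gives_intercept_only(noisy_dataset):
    df, _ = noisy_dataset
    result = aic_stepwise(df, [])
    assert result.selected_terms == []
    assert result.model.intercept_ == pytest.approx(
        np.abs(df["dg_exp"]).mean())
    assert result.rmse == pytest.approx(np.abs(df["dg_exp"]).std(ddof=0))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_stepwise_never_increases_aic(seed):
    spec = SyntheticDatasetSpec(n=100, noise_sigma=2.0, seed=seed)
    df = make_regression_dataset(spec)
    result = aic_stepwise(df, MODEL6_TERMS)
    aics = [a for _, _, a in result.aic_trace]
    assert all(b <= a + 1e-12 for a, b in zip(aics, aics[1:]))
    assert result.aic <= aics[0]


def test_stepwise_deterministic():
    spec = SyntheticDatasetSpec(n=150, noise_sigma=1.5, seed=9)
    df = make_regression_dataset(spec)
    r1 = aic_stepwise(df, MODEL6_TERMS)
    r2 = aic_stepwise(df, MODEL6_TERMS)
    assert r1.selected_terms == r2.selected_terms
    assert r1.aic_trace == r2.aic_trace


def test_gaussian_aic_formula():
    # n·ln(RSS/n) + 2(k+1), checked against a hand computation
    assert gaussian_aic(10.0, 20, 3) == pytest.approx(
        20 * np.log(0.5) + 8.0)


def test_perfect_line_correlations():
    x = np.arange(10.0)
    r, s, p = correlations(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert s == pytest.approx(1.0)
    assert p < 1e-10


def test_monotone_decreasing_cubic():
    x = np.linspace(-2, 2, 15)
    r, s, _ = correlations(x, -x ** 3)
    assert r < 0
    assert s == pytest.approx(-1.0)


def test_correlations_match_reference_implementation():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=10), rng.normal(size=10)
    r, s, p = correlations(x, y)
    # independent oracle: covariance formula and rank transform
    r_ref = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert r == pytest.approx(r_ref, abs=1e-12)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    s_ref = ((np.mean(rx * ry) - rx.mean() * ry.mean())
             / (rx.std() * ry.std()))
    assert s == pytest.approx(s_ref, abs=1e-12)


def test_zero_variance_correlation_is_an_error():
    with pytest.raises(ValueError):
        correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlations([1.0, 2.0], [1.0, 2.0])


def test_cv_folds_partition_dataset(noisy_dataset):
    df, spec = noisy_dataset
    report = cross_validate(df, list(spec.weights), k=4, repeats=2, seed=1)
    for rep in range(2):
        held_out = sum(f["n_test"] for f in report.folds
                       if f["repeat"] == rep)
        assert held_out == len(df)
    assert len(report.folds) == 8


def test_cv_deterministic_under_seed(noisy_dataset):
    df, spec = noisy_dataset
    r1 = cross_validate(df, list(spec.weights), repeats=2, seed=7)
    r2 = cross_validate(df, list(spec.weights), repeats=2, seed=7)
    assert r1.to_dict() == r2.to_dict()
    r3 = cross_validate(df, list(spec.weights), repeats=2, seed=8)
    assert r1.folds[0]["rmse"] != r3.folds[0]["rmse"]


def test_cv_noiseless_heldout_error_vanishes(noiseless_dataset):
    df, spec = noiseless_dataset
    report = cross_validate(df, list(spec.weights), repeats=1, seed=0)
    assert all(f["rmse"] < 1e-6 for f in report.folds)


def test_cv_heldout_rmse_tracks_noise():
    spec = SyntheticDatasetSpec(n=100, noise_sigma=1.0, seed=21)
    df = make_regression_dataset(spec)
    report = cross_validate(df, list(spec.weights), k=4, repeats=10, seed=2)
    assert 0.8 < report.mean_rmse < 1.2


def test_cv_rejects_tiny_datasets(noisy_dataset):
    df, spec = noisy_dataset
    with pytest.raises(ValueError):
        cross_validate(df.head(6), list(spec.weights), k=4, seed=0)


def test_rigidity_grouping_boundary():
    df = pd.DataFrame({
        "dg_exp": [-5, -6, -7, -8, -9, -10.0],
        "i_rmsd": [0.5, 1.0, 0.8, 1.5, 2.0, 3.0],
        "ICs_total": [10, 20, 30, 40, 50, 60.0],
    })
    table = grouped_eval(df, "rigidity").set_index("group")
    assert table.loc["rigid", "n"] == 3      # 1.0 Å counts as rigid
    assert table.loc["flexible", "n"] == 3


def test_small_groups_flagged_insufficient():
    df = pd.DataFrame({
        "dg_exp": [-5, -6, -7, -8.0],
        "method": ["SPR", "SPR", "SPR", "ITC"],
        "ICs_total": [10, 20, 30, 40.0],
    })
    table = grouped_eval(df, "method").set_index("group")
    assert not table.loc["ITC", "sufficient"]
    assert np.isnan(table.loc["ITC", "r_pearson"])
    assert table.loc["SPR", "sufficient"]


def test_grouped_eval_unknown_key():
    with pytest.raises(KeyError):
        grouped_eval(pd.DataFrame({"dg_exp": [1.0]}), "rigidity")
    with pytest.raises(KeyError):
        grouped_eval(pd.DataFrame({"dg_exp": [1.0]}), "nope")


def test_curation_filters():
    df = pd.DataFrame({
        "id": ["ok", "ambiguous", "gapped", "inhibition"],
        "dg_exp": [-9.2, "> -14", -10.0, -8.0],
        "method": ["SPR", "ITC", "ITC", "inhibition assay"],
        "interface_gap_excluded": [False, False, True, False],
    })
    basic = curate(df)
    assert list(basic["id"]) == ["ok", "inhibition"]
    reliable = curate(df, reliable_only=True)
    assert list(reliable["id"]) == ["ok"]
    assert reliable["dg_exp"].dtype == float
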