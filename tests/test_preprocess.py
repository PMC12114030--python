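"""Missingness filter, log transform, and two-stage covariate adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from komet.preprocess import (
    BASE_COVARIATES,
    filter_by_missingness,
    log_transform,
    preprocess_metabolites,
    select_covariates,
    stage1_residualize,
    stage2_residualize,
)


def _pheno(n, rng, missing_bmi=0.0):
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(18, 90, n),
            "sex": rng.choice(["F", "M"], n),
            **{f"pc{i}": rng.standard_normal(n) for i in range(1, 11)},
            "bmi": rng.normal(26, 4, n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "education": rng.choice(["basic", "secondary", "higher"], n),
            "season": rng.choice(["winter", "spring", "summer", "autumn"], n),
        }
    )
    if missing_bmi:
        df.loc[rng.random(n) < missing_bmi, "bmi"] = np.nan
    return df


def test_missingness_filter_strict_boundary():
    n = 981
    idx = [f"s{i}" for i in range(n)]
    m = pd.DataFrame(
        {
            "removed": [np.nan] * 933 + [1.0] * (n - 933),  # 95.1% missing
            "kept": [np.nan] * 931 + [1.0] * (n - 931),  # 94.9% missing
        },
        index=idx,
    )
    out = filter_by_missingness(m, max_missing=0.95)
    assert list(out.columns) == ["kept"]
    with pytest.raises(ValueError):
        filter_by_missingness(m, max_missing=1.5)


def test_missingness_filter_reproduces_study_scale_counts(rng):
    """1,505 metabolites with 118 censored above the threshold -> 1,387."""
    n = 200
    over = rng.choice(1505, size=118, replace=False)
    data = np.ones((n, 1505))
    for j in range(1505):
        n_miss = 196 if j in set(over) else int(rng.integers(0, 190))
        data[:n_miss, j] = np.nan
    m = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    assert filter_by_missingness(m, 0.95).shape[1] == 1387


def test_log_transform_values_and_errors():
    m = pd.DataFrame({"a": [1.0, np.e, np.nan]}, index=["s1", "s2", "s3"])
    out = log_transform(m)
    assert out.loc["s1", "a"] == pytest.approx(0.0)
    assert out.loc["s2", "a"] == pytest.approx(1.0)
    assert np.isnan(out.loc["s3", "a"])
    bad = pd.DataFrame({"a": [1.0, 0.0]}, index=["s1", "s2"])
    with pytest.raises(ValueError, match="s2.*a"):
        log_transform(bad)


def test_stage1_matches_hat_matrix_oracle(rng):
    """Textbook projection I - X(X'X)^-1 X' on a 20 x 13 design."""
    n = 20
    pheno = _pheno(n, rng)
    y = rng.standard_normal(n) + 0.5 * pheno["age"].to_numpy()
    logm = pd.DataFrame({"m1": y}, index=pheno["sample_id"])
    got = stage1_residualize(logm, pheno)["m1"].to_numpy()
    X = np.column_stack(
        [np.ones(n), pheno["age"], (pheno["sex"] == "M").astype(float)]
        + [pheno[f"pc{i}"] for i in range(1, 11)]
    )
    H = X @ np.linalg.solve(X.T @ X, X.T)
    want = (np.eye(n) - H) @ y
    assert np.max(np.abs(got - want)) < 1e-10
    # residuals orthogonal to every regressor
    assert np.max(np.abs(X.T @ got)) < 1e-6 * n


def test_stage1_regresses_out_age(rng):
    n = 500
    pheno = _pheno(n, rng)
    y = 2.0 * pheno["age"].to_numpy() + rng.standard_normal(n)
    logm = pd.DataFrame({"m1": y}, index=pheno["sample_id"])
    resid = stage1_residualize(logm, pheno)["m1"]
    assert abs(stats.pearsonr(resid, pheno["age"]).statistic) < 0.05


def test_stage1_constant_metabolite_gives_zero_residuals(rng):
    pheno = _pheno(30, rng)
    logm = pd.DataFrame({"m1": np.full(30, 3.3)}, index=pheno["sample_id"])
    resid = stage1_residualize(logm, pheno)["m1"]
    assert np.allclose(resid, 0.0, atol=1e-10)


def test_covariate_selection_power_and_level(rng):
    """An injected BMI slope of 0.5 SD/SD is essentially always selected;
    a null covariate is selected at about the test level."""
    n, reps = 500, 400
    hits_effect = hits_null = 0
    for _ in range(reps // 10):
        pheno = _pheno(n, rng)
        bmi_z = ((pheno["bmi"] - pheno["bmi"].mean()) / pheno["bmi"].std()).to_numpy()
        resid = pd.DataFrame(
            {"m1": 0.5 * bmi_z + rng.standard_normal(n)}, index=pheno["sample_id"]
        )
        sel = select_covariates(resid, pheno, candidates=["bmi"])
        hits_effect += "bmi" in sel["m1"]
    assert hits_effect == reps // 10  # >99% power regime
    for _ in range(reps):
        pheno = _pheno(120, rng)
        resid = pd.DataFrame(
            {"m1": rng.standard_normal(120)}, index=pheno["sample_id"]
        )
        sel = select_covariates(resid, pheno, candidates=["bmi"])
        hits_null += "bmi" in sel["m1"]
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits_null / reps - 0.05) < 3.5 * se


def test_single_level_candidate_never_selected(rng):
    pheno = _pheno(100, rng)
    pheno["season"] = "winter"
    resid = pd.DataFrame({"m1": rng.standard_normal(100)}, index=pheno["sample_id"])
    assert select_covariates(resid, pheno, candidates=["season"])["m1"] == []


def test_stage2_empty_selection_equals_zscored_stage1(rng):
    pheno = _pheno(80, rng)
    logm = pd.DataFrame(
        {"m1": rng.standard_normal(80) + 12}, index=pheno["sample_id"]
    )
    s1 = stage1_residualize(logm, pheno)["m1"]
    z = (s1 - s1.mean()) / s1.std(ddof=1)
    s2 = stage2_residualize(logm, pheno, {"m1": []}).residuals["m1"]
    assert np.max(np.abs(s2 - z)) < 1e-10


def test_stage2_missingness_is_union_of_sources(rng):
    pheno = _pheno(100, rng, missing_bmi=0.1)
    y = rng.standard_normal(100) + 12
    y[:7] = np.nan
    logm = pd.DataFrame({"m1": y}, index=pheno["sample_id"])
    out = stage2_residualize(logm, pheno, {"m1": ["bmi"]}).residuals["m1"]
    expect_missing = np.isnan(y) | pheno["bmi"].isna().to_numpy()
    assert (out.isna().to_numpy() == expect_missing).all()


def test_stage2_too_few_samples_skips_metabolite(rng):
    pheno = _pheno(12, rng)
    logm = pd.DataFrame({"m1": rng.standard_normal(12)}, index=pheno["sample_id"])
    out = stage2_residualize(logm, pheno, {"m1": []})
    assert out.skipped == ["m1"]
    assert "m1" not in out.residuals.columns


def test_full_two_stage_invariants_and_recovery(small_cohort):
    """Normalization, no-imputation, idempotence, and slope recovery on the
    generated cohort with known covariate effects."""
    b = small_cohort
    res = preprocess_metabolites(b.abundance, b.phenotypes)
    r = res.residuals
    # mean 0 / SD 1 per metabolite over non-missing entries
    assert np.max(np.abs(r.mean(skipna=True))) < 1e-8
    assert np.max(np.abs(r.std(ddof=1, skipna=True) - 1.0)) < 1e-8
    # no imputation: missing wherever the abundance was missing
    assert (r[b.abundance[r.columns].isna()].isna()).all().all()
    # residual-vs-covariate slope consistent with zero after adjustment
    pheno = b.phenotypes.set_index("sample_id")
    for met, pairs in b.truth["covariate_effects"].items():
        if met not in r.columns:
            continue
        for cov, _ in pairs:
            if cov not in ("age", "bmi"):
                continue
            mask = r[met].notna() & pheno[cov].notna()
            fit = stats.linregress(pheno.loc[mask, cov], r.loc[mask, met])
            assert abs(fit.slope) < 2 * fit.stderr + 1e-8
    # idempotence: re-residualizing changes nothing beyond numerics
    sel = {m: res.selected_covariates[m] for m in r.columns}
    again = stage2_residualize(r, b.phenotypes, sel).residuals
    assert np.nanmax(np.abs(again - r)) < 1e-10


def test_base_covariates_must_be_complete(rng):
    pheno = _pheno(30, rng)
    pheno.loc[0, "age"] = np.nan
    logm = pd.DataFrame({"m1": rng.standard_normal(30)}, index=pheno["sample_id"])
    with pytest.raises(ValueError, match="age"):
        stage1_residualize(logm, pheno)
    assert "age" in BASE_COVARIATES and "sex" in BASE_COVARIATES
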