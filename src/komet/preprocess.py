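"""Metabolite preprocessing: missingness filter, log transform, and the
two-stage covariate adjustment yielding normalized residuals.

Raw peak areas with missingness above the filter threshold are dropped
(missing values are treated as below the limit of detection and never
imputed).  Remaining metabolites are natural-log transformed and adjusted
in two stages: stage 1 regresses out the always-observed base covariates
(age, sex, 10 genotype PCs); candidate covariates (BMI by simple linear
regression, smoking/education/season by one-way ANOVA) are then tested
marginally on the stage-1 residuals at p < alpha, and stage 2 refits each
metabolite from the log values on the base covariates plus its selected
candidates, restricted to samples where all of them are observed.  The
final residuals are z-scored per metabolite (mean 0, SD 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_COVARIATES",
    "CANDIDATE_COVARIATES",
    "ResidualMatrix",
    "filter_by_missingness",
    "log_transform",
    "stage1_residualize",
    "select_covariates",
    "stage2_residualize",
    "preprocess_metabolites",
]

BASE_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
CANDIDATE_COVARIATES = ["bmi", "smoking", "education", "season"]
_CATEGORICAL = {"sex", "smoking", "education", "season"}


@dataclass
class ResidualMatrix:
    residuals: pd.DataFrame  # samples x metabolites, z-scored, NaN = excluded
    selected_covariates: dict[str, list[str]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def filter_by_missingness(matrix: pd.DataFrame, max_missing: float = 0.95) -> pd.DataFrame:
    """Drop metabolites missing in strictly more than ``max_missing`` of samples."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing {max_missing} outside [0, 1]")
    if matrix.empty:
        raise ValueError("empty abundance matrix")
    frac = matrix.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing])
    if dropped:
        logger.info(
            "missingness filter removed %d of %d metabolites (> %.0f%% missing)",
            len(dropped), matrix.shape[1], 100 * max_missing,
        )
    return matrix.drop(columns=dropped)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural log, elementwise; missing stays missing; non-positive errors."""
    bad = matrix.le(0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-positive abundance at sample {row}, metabolite {col}")
    return np.log(matrix)


def _design_matrix(pheno: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; categoricals one-hot with first-level reference."""
    cols: list[np.ndarray] = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        if cov in _CATEGORICAL:
            levels = sorted(pd.unique(pheno[cov].dropna()))
            for lev in levels[1:]:
                cols.append((pheno[cov] == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(pheno[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def _ols_residuals(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    # drop constant non-intercept columns (rank deficiency, e.g. one sex)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("dropping constant design columns: %s", dropped)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def stage1_residualize(log_matrix: pd.DataFrame, pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite OLS on the base covariates; unstandardized residuals."""
    pheno = pheno.set_index("sample_id").loc[log_matrix.index]
    for cov in BASE_COVARIATES:
        if pheno[cov].isna().any():
            raise ValueError(f"base covariate {cov} has missing values")
    X_full, names = _design_matrix(pheno, BASE_COVARIATES)
    out = pd.DataFrame(np.nan, index=log_matrix.index, columns=log_matrix.columns)
    for met in log_matrix.columns:
        y = log_matrix[met].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < X_full.shape[1] + 2:
            logger.warning("stage 1: %s has too few observations, skipped", met)
            continue
        out.loc[obs, met] = _ols_residuals(X_full[obs], y[obs], names)
    return out


def select_covariates(
    stage1_residuals: pd.DataFrame,
    pheno: pd.DataFrame,
    alpha: float = 0.05,
    candidates: list[str] | None = None,
) -> dict[str, list[str]]:
    """Marginal candidate-covariate tests per metabolite.

    BMI: simple linear regression of the stage-1 residual on BMI (slope
    t-test).  Categorical candidates: one-way ANOVA across observed levels.
    A candidate is selected when its p-value is below ``alpha``; each test
    uses only samples where that candidate (and the metabolite) is observed.
    """
    candidates = CANDIDATE_COVARIATES if candidates is None else candidates
    pheno = pheno.set_index("sample_id").loc[stage1_residuals.index]
    selected: dict[str, list[str]] = {}
    for met in stage1_residuals.columns:
        resid = stage1_residuals[met]
        chosen = []
        for cov in candidates:
            mask = resid.notna() & pheno[cov].notna()
            if mask.sum() < 3:
                continue
            r = resid[mask].to_numpy(dtype=float)
            c = pheno.loc[mask, cov]
            if cov in _CATEGORICAL:
                groups = [r[(c == lev).to_numpy()] for lev in pd.unique(c)]
                groups = [g for g in groups if g.size > 0]
                if len(groups) < 2:
                    logger.warning("%s: %s has a single observed level, excluded", met, cov)
                    continue
                p = stats.f_oneway(*groups).pvalue
            else:
                x = c.to_numpy(dtype=float)
                if np.ptp(x) == 0:
                    continue
                p = stats.linregress(x, r).pvalue
            if p < alpha:
                chosen.append(cov)
        selected[met] = chosen
    return selected


def stage2_residualize(
    log_matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    selected_covariates: dict[str, list[str]],
) -> ResidualMatrix:
    """Refit each metabolite from log values on base + selected covariates.

    Samples lacking the metabolite or any selected covariate are excluded
    from that metabolite's fit and left missing in the output — selecting
    covariates per metabolite preserves the sample instead of imposing a
    global complete-case restriction.  Residuals are z-scored (mean 0,
    SD 1, ddof=1) per metabolite.
    """
    missing_sel = [m for m in log_matrix.columns if m not in selected_covariates]
    if missing_sel:
        raise KeyError(f"no covariate selection for metabolites: {missing_sel[:5]}")
    ph = pheno.set_index("sample_id").loc[log_matrix.index]
    out = pd.DataFrame(np.nan, index=log_matrix.index, columns=log_matrix.columns)
    skipped = []
    for met in log_matrix.columns:
        covs = BASE_COVARIATES + list(selected_covariates[met])
        y = log_matrix[met].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        for cov in selected_covariates[met]:
            obs &= ph[cov].notna().to_numpy()
        sub = ph.loc[obs]
        X, names = _design_matrix(sub, covs)
        if obs.sum() < X.shape[1] + 2:
            logger.warning("stage 2: %s has too few usable samples, skipped", met)
            skipped.append(met)
            continue
        resid = _ols_residuals(X, y[obs], names)
        sd = resid.std(ddof=1)
        if sd == 0:
            skipped.append(met)
            logger.warning("stage 2: %s residuals are constant, skipped", met)
            continue
        out.loc[obs, met] = (resid - resid.mean()) / sd
    out = out.drop(columns=skipped)
    return ResidualMatrix(residuals=out, selected_covariates=dict(selected_covariates), skipped=skipped)


def preprocess_metabolites(
    abundance: pd.DataFrame,
    pheno: pd.DataFrame,
    max_missing: float = 0.95,
    alpha: float = 0.05,
) -> ResidualMatrix:
    """Full pipeline: filter -> log -> stage 1 -> selection -> stage 2."""
    filtered = filter_by_missingness(abundance, max_missing)
    logm = log_transform(filtered)
    stage1 = stage1_residualize(logm, pheno)
    sel = select_covariates(stage1, pheno, alpha=alpha)
    return stage2_residualize(logm, pheno, sel)
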