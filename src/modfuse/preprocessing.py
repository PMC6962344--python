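"""Train-fold-only preprocessing: covariate residualization and soft-normalization.

Both steps are fit on training subjects only and applied unchanged to
held-out subjects, so no information leaks from the test fold.

*Residualization* removes linear variance of no interest (age, gender,
site) from every feature by ordinary least squares: each feature is
replaced by its residual from a regression on an intercept, age, and
indicator contrasts for gender and site.  Held-out subjects are corrected
with the training coefficients.

*Soft-normalization* robustly standardises each feature by removing the
training median and dividing by the 1%-99% quantile range, so extreme
values compress the scale far less than z-scoring would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modfuse.panel_io import FeatureTable

#: guard against zero quantile range for constant features
SCALE_EPS = 1e-12


def _design_matrix(
    covariates: pd.DataFrame,
    subjects: list[str],
    levels: dict[str, list[str]] | None = None,
) -> tuple[np.ndarray, dict[str, list[str]], list[str]]:
    """Intercept + age + full-rank indicator contrasts for gender and site.

    ``levels`` fixes the category levels (from the training fit); categories
    unseen at fit time raise, since no extrapolation rule is defined.
    """
    cov = covariates.loc[subjects]
    if levels is None:
        levels = {
            "gender": sorted(cov["gender"].unique()),
            "site": sorted(cov["site"].unique()),
        }
    cols = [np.ones(len(cov)), cov["age"].to_numpy(dtype=float)]
    names = ["intercept", "age"]
    for var in ("gender", "site"):
        seen = set(cov[var])
        unseen = seen - set(levels[var])
        if unseen:
            raise ValueError(f"unseen {var} category at apply time: {sorted(unseen)}")
        for level in levels[var][1:]:  # first level is the reference
            cols.append((cov[var] == level).to_numpy(dtype=float))
            names.append(f"{var}[{level}]")
    return np.column_stack(cols), levels, names


@dataclass
class ResidualizerParams:
    """Per-feature OLS coefficients for the nuisance design."""

    feature_ids: list[str]
    coef: np.ndarray  # (n_design_cols, n_features)
    levels: dict[str, list[str]]
    column_names: list[str] = field(default_factory=list)


def fit_residualizer(
    table: FeatureTable,
    covariates: pd.DataFrame,
    fit_subjects: list[str],
) -> ResidualizerParams:
    """OLS fit of every feature on the nuisance design, training subjects only."""
    fit_subjects = [s for s in fit_subjects if s in table.data.index]
    if not set(fit_subjects) <= set(covariates.index):
        missing = set(fit_subjects) - set(covariates.index)
        raise ValueError(f"covariates missing for fit subjects: {sorted(missing)[:5]}")
    D, levels, names = _design_matrix(covariates, fit_subjects)
    X = table.data.loc[fit_subjects].to_numpy()
    # lstsq handles rank deficiency (e.g. a single site collapses its contrast
    # onto the intercept) by the minimum-norm solution
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    if not np.isfinite(coef).all():
        raise ValueError("non-finite residualizer coefficients")
    return ResidualizerParams(table.feature_ids, coef, levels, names)


def apply_residualizer(
    params: ResidualizerParams,
    table: FeatureTable,
    covariates: pd.DataFrame,
) -> FeatureTable:
    """Subtract the nuisance prediction (training coefficients) from every value."""
    if params.feature_ids != table.feature_ids:
        raise ValueError("residualizer was fit on a different feature set")
    subjects = table.subject_ids
    D, _, _ = _design_matrix(covariates, subjects, levels=params.levels)
    resid = table.data.to_numpy() - D @ params.coef
    return FeatureTable(table.name, pd.DataFrame(resid, index=table.data.index, columns=table.data.columns))


@dataclass
class NormalizerParams:
    """Per-feature median and guarded 1%-99% quantile range."""

    feature_ids: list[str]
    median: np.ndarray
    q01: np.ndarray
    q99: np.ndarray

    @property
    def scale(self) -> np.ndarray:
        return np.maximum(self.q99 - self.q01, SCALE_EPS)


def fit_soft_normalizer(table: FeatureTable, fit_subjects: list[str]) -> NormalizerParams:
    """Median and 1%/99% quantiles per feature over training subjects.

    Quantiles use linear interpolation between order statistics.
    """
    fit_subjects = [s for s in fit_subjects if s in table.data.index]
    if len(fit_subjects) < 2:
        raise ValueError("soft-normalization needs at least 2 fit subjects")
    X = table.data.loc[fit_subjects].to_numpy()
    q01, med, q99 = np.quantile(X, [0.01, 0.5, 0.99], axis=0, method="linear")
    return NormalizerParams(table.feature_ids, med, q01, q99)


def apply_soft_normalizer(params: NormalizerParams, table: FeatureTable) -> FeatureTable:
    """(value − median) / quantile range, per feature."""
    if params.feature_ids != table.feature_ids:
        raise ValueError("normalizer was fit on a different feature set")
    out = (table.data.to_numpy() - params.median) / params.scale
    return FeatureTable(table.name, pd.DataFrame(out, index=table.data.index, columns=table.data.columns))
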