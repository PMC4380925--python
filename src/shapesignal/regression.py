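"""Shape-response regression: predicting NF-κB fold change from shape fold changes.

Each condition (cell line × perturbation ± TNFα) is summarized by the
treated/control ratio of well-averaged features.  A three-predictor ordinary
least-squares model

    Δtf_ratio = c0 + c_NF·ΔNF + c_ruffliness·Δruffliness + c_ratio·ΔA_nuc/A_cyto

is fitted with tenfold cross-validation; conditions whose observed NF-κB
fold change falls outside the full fit's 95% prediction interval are flagged
as cases where shape does not explain the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "PREDICTORS",
    "compute_fold_changes",
    "ShapeResponseModel",
    "fit_shape_regression",
    "CrossValidationResult",
    "crossvalidate_and_flag_outliers",
]

PREDICTORS = ["d_nf", "d_ruffliness", "d_anucacyto"]
RESPONSE = "d_tfratio"

_FEATURE_MAP = {
    "neighbor_fraction": "d_nf",
    "ruffliness": "d_ruffliness",
    "a_nuc_a_cyto": "d_anucacyto",
    "tf_ratio": "d_tfratio",
}


def compute_fold_changes(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    match_on: list[str] | None = None,
    condition_col: str = "condition_id",
) -> pd.DataFrame:
    """Treated/control fold change of well-average features per condition.

    ``treated`` and ``control`` are well-profile tables carrying the columns
    in ``match_on`` plus neighbor_fraction, ruffliness, a_nuc_a_cyto and
    tf_ratio.  Every treated condition must have a matched control (error
    naming the condition otherwise); conditions with a zero control mean are
    flagged invalid and excluded with a warning.
    """
    match_on = match_on or [c for c in ("line_id", "medium") if c in treated.columns]
    ctrl = control.set_index(match_on)
    rows, dropped = [], []
    for _, row in treated.iterrows():
        key = tuple(row[c] for c in match_on)
        key = key[0] if len(key) == 1 else key
        if key not in ctrl.index:
            raise ValueError(f"no control matched for condition {row.get(condition_col, key)!r}")
        base = ctrl.loc[key]
        if isinstance(base, pd.DataFrame):
            base = base.iloc[0]
        rec = {condition_col: row.get(condition_col, str(key))}
        valid = True
        for feat, col in _FEATURE_MAP.items():
            denom = float(base[feat])
            if denom == 0:
                valid = False
                break
            rec[col] = float(row[feat]) / denom
        if not valid:
            dropped.append(rec[condition_col])
            continue
        rows.append(rec)
    if dropped:
        warnings.warn(f"conditions with zero control mean excluded: {dropped}")
    return pd.DataFrame(rows)


@dataclass
class ShapeResponseModel:
    """Fitted three-predictor model with diagnostics."""

    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    error_variance: float          # residual mean square, SSR / (n - k)
    f_pvalue: float
    residuals: np.ndarray
    condition_ids: list[str]
    n: int
    condition_number: float
    shapiro_pvalue: float          # residual normality check
    _results: object = field(default=None, repr=False)

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(records[PREDICTORS].to_numpy(dtype=float), has_constant="add")
        return self._results.predict(X)


def fit_shape_regression(records: pd.DataFrame, condition_col: str = "condition_id") -> ShapeResponseModel:
    """OLS fit of the NF-κB fold change on the three shape fold changes.

    Reports R², the residual (error) variance, the overall F-test P value and
    a Shapiro–Wilk residual-normality check.  Warns when the design matrix is
    badly conditioned.
    """
    records = records.dropna(subset=PREDICTORS + [RESPONSE])
    if len(records) < 5:
        raise ValueError(f"need at least 5 valid records, got {len(records)}")
    X = sm.add_constant(records[PREDICTORS].to_numpy(dtype=float), has_constant="add")
    y = records[RESPONSE].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    cond = float(np.linalg.cond(X))
    if cond > 1e4:
        warnings.warn(f"collinear predictors: condition number {cond:.3g}")
    resid = np.asarray(res.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else float("nan")
    ids = (
        records[condition_col].astype(str).tolist()
        if condition_col in records.columns
        else [str(i) for i in records.index]
    )
    return ShapeResponseModel(
        intercept=float(res.params[0]),
        coefficients=dict(zip(PREDICTORS, (float(v) for v in res.params[1:]))),
        r_squared=float(res.rsquared),
        error_variance=float(res.mse_resid),
        f_pvalue=float(res.f_pvalue),
        residuals=resid,
        condition_ids=ids,
        n=len(records),
        condition_number=cond,
        shapiro_pvalue=shapiro_p,
        _results=res,
    )


@dataclass
class CrossValidationResult:
    mae_mean: float
    mae_sd: float
    rmse_mean: float
    fold_errors: np.ndarray
    outliers: list[str]
    level: float


def crossvalidate_and_flag_outliers(
    records: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    level: float = 0.95,
    condition_col: str = "condition_id",
) -> tuple[ShapeResponseModel, CrossValidationResult]:
    """Tenfold CV error and 95%-prediction-interval outliers.

    Fold assignment is a seeded random partition; the CV error is the mean
    absolute held-out prediction error per fold, reported mean ± SD across
    folds (RMSE also kept).  Outliers are the conditions whose observed
    response lies outside the full fit's prediction interval at ``level``.
    """
    records = records.dropna(subset=PREDICTORS + [RESPONSE])
    if condition_col in records.columns:
        # canonical order makes fold assignment invariant to record order
        records = records.sort_values(condition_col, kind="stable")
    records = records.reset_index(drop=True)
    n = len(records)
    if folds > n:
        raise ValueError(f"{folds} folds but only {n} records")
    model = fit_shape_regression(records, condition_col=condition_col)

    X = sm.add_constant(records[PREDICTORS].to_numpy(dtype=float), has_constant="add")
    y = records[RESPONSE].to_numpy(dtype=float)
    maes, rmses = [], []
    for train, test in KFold(n_splits=folds, shuffle=True, random_state=seed).split(X):
        fit = sm.OLS(y[train], X[train]).fit()
        err = y[test] - fit.predict(X[test])
        maes.append(np.mean(np.abs(err)))
        rmses.append(np.sqrt(np.mean(err**2)))
    maes = np.array(maes)

    pred = model._results.get_prediction(X)
    lo, hi = pred.conf_int(obs=True, alpha=1 - level).T
    tol = 1e-8 * max(1.0, float(np.abs(y).max()))  # guard exact fits
    outside = (y < lo - tol) | (y > hi + tol)
    ids = np.array(model.condition_ids)
    cv = CrossValidationResult(
        mae_mean=float(maes.mean()),
        mae_sd=float(maes.std(ddof=1)),
        rmse_mean=float(np.mean(rmses)),
        fold_errors=maes,
        outliers=sorted(ids[outside].tolist()),
        level=level,
    )
    return model, cv
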