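"""Elastic-net regression of inter-pianist skill differences.

The cohort table has one row per pianist: 12 predictors (inter-strike mean
and SD of the six keystroke features) and two outcomes (fastest-tempo IOI,
loudness balance). All variables are z-scored, so coefficients are fully
standardized weights. For each outcome an elastic net

    min_b  1/(2n) ||y - Xb||^2 + alpha * (l1 * ||b||_1 + (1-l1)/2 * ||b||^2)

is fitted, with (alpha, l1_ratio) chosen by K-fold cross-validated MSE over
a grid; ties are broken toward larger alpha (the more parsimonious model).
The reported R-squared is in-sample (fitted vs observed outcomes); the
cross-validated R-squared is reported alongside under its own name.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .errors import (
    DegenerateColumnError,
    DegenerateInputError,
    FittingError,
    InsufficientDataError,
)
from .features import OUTCOME_COLUMNS, PREDICTOR_COLUMNS

DEFAULT_ALPHAS = tuple(np.logspace(-3, 0.5, 20))
DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class StandardizationParams:
    """Per-column mean/SD retained for inverse mapping back to raw units."""

    means: pd.Series
    sds: pd.Series

    def inverse(self, z: pd.DataFrame | pd.Series):
        return z * self.sds[getattr(z, "columns", getattr(z, "name", None))] \
            + self.means[getattr(z, "columns", getattr(z, "name", None))]


def standardize(table: pd.DataFrame, columns=None
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the given columns (default: all numeric) with the n-1 SD.

    Raises :class:`DegenerateColumnError` naming the first zero-variance
    column encountered.
    """
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    means = table[cols].mean()
    sds = table[cols].std(ddof=1)
    for c in cols:
        if not np.isfinite(sds[c]) or sds[c] == 0:
            raise DegenerateColumnError(f"column {c!r} has zero variance")
    out[cols] = (table[cols] - means) / sds
    return out, StandardizationParams(means=means, sds=sds)


@dataclass
class NetFit:
    """A fitted elastic net for one outcome."""

    outcome: str
    coef: pd.Series               # standardized weights, one per predictor
    intercept: float
    alpha: float
    l1_ratio: float
    r2: float                     # in-sample, fitted vs observed
    cv_r2: float                  # 1 - CV-MSE / Var(y), clearly not in-sample
    cv_scores: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.coef.index].to_numpy() @ self.coef.to_numpy() + self.intercept


def _cv_grid(X: np.ndarray, y: np.ndarray, alphas, l1_ratios, splits) -> pd.DataFrame:
    """Mean CV-MSE for every (alpha, l1_ratio); alphas descending per l1 so
    the first minimum encountered is the largest (tie-break toward shrinkage).
    Warm-starts along each alpha path for speed."""
    alphas = sorted(alphas, reverse=True)
    rows = [{"alpha": float(a), "l1_ratio": float(l1), "cv_mse": 0.0}
            for l1 in l1_ratios for a in alphas]
    k = len(splits)
    for f, (train, test) in enumerate(splits):
        i = 0
        for l1 in l1_ratios:
            model = ElasticNet(l1_ratio=l1, max_iter=50_000, tol=1e-6, warm_start=True)
            for a in alphas:
                model.set_params(alpha=a)
                model.fit(X[train], y[train])
                resid = y[test] - model.predict(X[test])
                rows[i]["cv_mse"] += float(np.mean(resid**2)) / k
                i += 1
    return pd.DataFrame(rows)


def fit_elastic_net(table: pd.DataFrame, outcome: str,
                    predictors=PREDICTOR_COLUMNS,
                    alphas=DEFAULT_ALPHAS, l1_ratios=DEFAULT_L1_RATIOS,
                    cv_folds: int = 5, seed: int = 0) -> NetFit:
    """Fit the penalized regression for one outcome on a standardized table.

    ``table`` must already be standardized (see :func:`standardize`); the
    hyperparameter pair is selected by ``cv_folds``-fold cross-validated MSE
    over ``alphas`` x ``l1_ratios``, ties broken toward larger alpha, then
    the model is refitted on all rows.
    """
    if len(alphas) == 0 or len(l1_ratios) == 0:
        raise FittingError("empty hyperparameter grid")
    X = table[list(predictors)].to_numpy()
    y = table[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise FittingError("non-finite values in the design after standardization")

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # edge grids (l1_ratio=0, alpha=0) are legitimate here; sklearn advises
        # Ridge/OLS instead but the coordinate-descent solution is what we compare
        warnings.filterwarnings("ignore", message=".*l1_ratio.*")
        warnings.filterwarnings("ignore", message="With alpha=0.*")
        scores = _cv_grid(X, y, alphas, l1_ratios, splits)
        if not np.any(np.isfinite(scores["cv_mse"])):
            raise FittingError("no hyperparameter pair produced a finite CV score")
        best = scores.loc[scores["cv_mse"].idxmin()]  # first minimum = largest alpha
        model = ElasticNet(alpha=best["alpha"], l1_ratio=best["l1_ratio"],
                           max_iter=200_000, tol=1e-8)
        model.fit(X, y)
    r2 = float(r2_score(y, model.predict(X)))
    var_y = float(np.var(y))
    return NetFit(
        outcome=outcome,
        coef=pd.Series(model.coef_, index=list(predictors)),
        intercept=float(model.intercept_),
        alpha=float(best["alpha"]),
        l1_ratio=float(best["l1_ratio"]),
        r2=r2,
        cv_r2=float(1.0 - best["cv_mse"] / var_y) if var_y > 0 else float("nan"),
        cv_scores=scores,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def outcome_correlation(y1, y2) -> CorrelationResult:
    """Pearson correlation between the two performance outcomes.

    Two-sided p-value from the t distribution with n-2 degrees of freedom.
    """
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    if a.size != b.size:
        raise ValueError("outcome vectors must have equal length")
    if a.size < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateInputError("zero-variance outcome: correlation undefined")
    res = stats.pearsonr(a, b)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(a.size))


def report(fits: list[NetFit]) -> pd.DataFrame:
    """Coefficient table: one row per outcome, columns = the 12 standardized
    weights plus intercept, alpha, L1 ratio, in-sample and CV R-squared."""
    rows = {}
    for fit in fits:
        row = {c: float(fit.coef[c]) for c in fit.coef.index}
        row.update(intercept=fit.intercept, alpha=fit.alpha,
                   l1_ratio=fit.l1_ratio, r2=fit.r2, cv_r2=fit.cv_r2)
        rows[fit.outcome] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "outcome"
    return df


def report_to_json(fits: list[NetFit], path=None) -> str:
    payload = report(fits).reset_index().to_dict(orient="records")
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def parse_report(text_or_path) -> list[NetFit]:
    """Inverse of :func:`report_to_json` (the CV trace is not serialized)."""
    try:
        payload = json.loads(text_or_path)
    except (json.JSONDecodeError, TypeError):
        with open(text_or_path) as fh:
            payload = json.load(fh)
    fits = []
    for row in payload:
        meta = {"outcome", "intercept", "alpha", "l1_ratio", "r2", "cv_r2"}
        coef = pd.Series({k: v for k, v in row.items() if k not in meta})
        fits.append(NetFit(outcome=row["outcome"], coef=coef,
                           intercept=row["intercept"], alpha=row["alpha"],
                           l1_ratio=row["l1_ratio"], r2=row["r2"],
                           cv_r2=row["cv_r2"]))
    return fits
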