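"""Six regression techniques behind a single fit/predict contract.

The techniques mirror the standard regression-family toolbox for
phenological onset modelling: ordinary least squares (``lm``), stepwise
AIC selection (``lmAIC``), the lasso (``lasso``), principal component
regression (``pcr``), least-squares gradient boosting (``gbm``) and
random forests (``rf``).  Tunable techniques use an inner k-fold CV over a
small hyperparameter grid.  Gradient-boosting fits expose Friedman's
relative influence: each feature's share of the ensemble's squared-error
reduction, scaled to sum to 100.

Missing predictor cells (post-cutoff censored months) are imputed with
training medians inside :func:`fit`; columns that are entirely missing or
constant in training are dropped internally but remain part of the
feature-name contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TECHNIQUES",
    "LearnerSpec",
    "FitResult",
    "fit",
    "predict",
    "relative_influence",
]

#: recognized techniques, ordered simplest-first (used for tie-breaking)
TECHNIQUES = ("lm", "lmAIC", "lasso", "pcr", "gbm", "rf")

MIN_TRAIN_ROWS = 20

DEFAULT_GRIDS: Mapping[str, Mapping[str, Sequence[Any]]] = {
    "gbm": {"n_estimators": [100, 300], "max_depth": [2, 3], "learning_rate": [0.1]},
    "rf": {"n_estimators": [300]},
    "pcr": {"n_components": [1, 2, 4, 6, 8, 12, 16, 20]},
}


@dataclass(frozen=True)
class LearnerSpec:
    """Choice of technique, hyperparameter grid and tuning protocol."""

    technique: str
    grid: Mapping[str, Sequence[Any]] | None = None
    inner_cv: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; pick from {TECHNIQUES}")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS.get(self.technique)
        if self.technique in DEFAULT_GRIDS and (not grid or any(len(v) == 0 for v in grid.values())):
            raise ValueError(f"empty hyperparameter grid for {self.technique}")

    def resolved_grid(self) -> Mapping[str, Sequence[Any]]:
        return dict(self.grid if self.grid is not None else DEFAULT_GRIDS.get(self.technique, {}))


@dataclass
class FitResult:
    """A fitted model plus everything needed to reproduce predictions."""

    technique: str
    model: Any
    feature_names: list[str]
    used_columns: list[str]
    medians: pd.Series
    hyperparams: dict[str, Any] = field(default_factory=dict)
    coefficients: pd.Series | None = None
    influence: pd.Series | None = None


def _impute(X: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    out = X.copy()
    out = out.fillna(medians)
    return out.fillna(0.0)  # columns that were all-NaN in training


def _drop_aliased(X: np.ndarray, names: list[str]) -> list[int]:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return []
    _, r, piv = qr(X - X.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size and diag.max() > 0 else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        warnings.warn(f"dropping aliased predictors: {dropped}", stacklevel=3)
    return keep


def _aic(rss: float, n: int, p: int) -> float:
    return n * np.log(max(rss / n, 1e-12)) + 2.0 * (p + 1)


def _ols_rss(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    design = np.column_stack([np.ones(len(y))] + [X[:, j] for j in cols])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


class _StepwiseOLS:
    """Forward-backward stepwise OLS minimizing AIC, from the empty model."""

    def __init__(self, max_steps: int = 60):
        self.max_steps = max_steps
        self.selected_: list[int] = []
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_StepwiseOLS":
        n, p = X.shape
        selected: list[int] = []
        current = _aic(_ols_rss(X, y, []), n, 0)
        for _ in range(self.max_steps):
            best: tuple[float, str, int] | None = None
            for j in range(p):
                if j in selected:
                    continue
                aic = _aic(_ols_rss(X, y, selected + [j]), n, len(selected) + 1)
                if best is None or aic < best[0]:
                    best = (aic, "add", j)
            for j in selected:
                cols = [c for c in selected if c != j]
                aic = _aic(_ols_rss(X, y, cols), n, len(cols))
                if best is None or aic < best[0]:
                    best = (aic, "drop", j)
            if best is None or best[0] >= current - 1e-10:
                break
            current = best[0]
            if best[1] == "add":
                selected.append(best[2])
            else:
                selected.remove(best[2])
        design = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.selected_ = selected
        self.intercept_ = float(coef[0])
        self.coef_full_ = np.zeros(p)
        for k, j in enumerate(selected):
            self.coef_full_[j] = coef[k + 1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept_ + X @ self.coef_full_


def fit(spec: LearnerSpec, X: pd.DataFrame, y: Sequence[float]) -> FitResult:
    """Fit one technique on a feature table.

    Imputation (training medians, 0 for fully censored columns) and
    zero-variance column handling happen here, so callers pass the raw
    42/69/115-column tables unchanged.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < MIN_TRAIN_ROWS:
        raise ValueError(f"need at least {MIN_TRAIN_ROWS} training rows, got {len(X)}")
    feature_names = list(X.columns)
    medians = X.median()
    Xi = _impute(X, medians)
    variances = Xi.var(axis=0, ddof=0)
    used = [c for c in feature_names if variances[c] > 0]
    Xm = Xi[used].to_numpy(dtype=float)

    tech = spec.technique
    grid = spec.resolved_grid()
    hyper: dict[str, Any] = {}
    coefficients: pd.Series | None = None
    influence: pd.Series | None = None

    if tech in ("lm", "lmAIC"):
        keep_idx = _drop_aliased(Xm, used)
        used = [used[i] for i in keep_idx]
        Xm = Xi[used].to_numpy(dtype=float)
        if tech == "lm":
            model = LinearRegression().fit(Xm, y)
            coefficients = pd.Series(model.coef_, index=used)
        else:
            model = _StepwiseOLS().fit(Xm, y)
            coefficients = pd.Series(model.coef_full_, index=used)
            hyper = {"selected": [used[j] for j in model.selected_]}
    elif tech == "lasso":
        lasso_kwargs = {}
        if "alphas" in grid:
            lasso_kwargs["alphas"] = list(grid["alphas"])
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lasso",
                    LassoCV(
                        cv=KFold(spec.inner_cv, shuffle=True, random_state=spec.seed),
                        random_state=spec.seed,
                        max_iter=10000,
                        **lasso_kwargs,
                    ),
                ),
            ]
        ).fit(Xm, y)
        lasso = model.named_steps["lasso"]
        hyper = {"alpha": float(lasso.alpha_)}
        coefficients = pd.Series(lasso.coef_, index=used)
    elif tech == "pcr":
        max_k = min(len(used), len(y) - 1)
        ks = sorted({int(k) for k in grid.get("n_components", [1]) if 1 <= k <= max_k}) or [1]
        pipe = Pipeline(
            [("scale", StandardScaler()), ("pca", PCA()), ("ols", LinearRegression())]
        )
        if len(ks) == 1:
            pipe.set_params(pca__n_components=ks[0])
            model = pipe.fit(Xm, y)
            hyper = {"n_components": ks[0]}
        else:
            search = GridSearchCV(
                pipe,
                {"pca__n_components": ks},
                cv=KFold(spec.inner_cv, shuffle=True, random_state=spec.seed),
                scoring="neg_mean_squared_error",
            ).fit(Xm, y)
            model = search.best_estimator_
            hyper = {"n_components": int(search.best_params_["pca__n_components"])}
    elif tech == "gbm":
        base = GradientBoostingRegressor(random_state=spec.seed)
        combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        if combos <= 1:
            params = {k: v[0] for k, v in grid.items()}
            model = GradientBoostingRegressor(random_state=spec.seed, **params).fit(Xm, y)
            hyper = dict(params)
        else:
            search = GridSearchCV(
                base,
                dict(grid),
                cv=KFold(spec.inner_cv, shuffle=True, random_state=spec.seed),
                scoring="neg_mean_squared_error",
            ).fit(Xm, y)
            model = search.best_estimator_
            hyper = dict(search.best_params_)
        influence = pd.Series(model.feature_importances_ * 100.0, index=used)
        influence = influence.reindex(feature_names, fill_value=0.0)
    elif tech == "rf":
        n_estimators = int(grid.get("n_estimators", [300])[0])
        model = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=spec.seed,
            n_jobs=1,
        ).fit(Xm, y)
        hyper = {"n_estimators": n_estimators}
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(tech)

    return FitResult(
        technique=tech,
        model=model,
        feature_names=feature_names,
        used_columns=used,
        medians=medians,
        hyperparams=hyper,
        coefficients=coefficients,
        influence=influence,
    )


def predict(fit_result: FitResult, X: pd.DataFrame) -> np.ndarray:
    """Predict onset DOYs; the columns must match training exactly."""
    missing = sorted(set(fit_result.feature_names) - set(X.columns))
    extra = sorted(set(X.columns) - set(fit_result.feature_names))
    if missing or extra:
        raise ValueError(f"feature mismatch: missing={missing}, extra={extra}")
    Xi = _impute(X[fit_result.feature_names], fit_result.medians)
    Xm = Xi[fit_result.used_columns].to_numpy(dtype=float)
    pred = np.asarray(fit_result.model.predict(Xm), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite predictions")
    return pred


def relative_influence(fit_result: FitResult) -> pd.Series:
    """Friedman's relative influence (percent, sums to 100) of a gbm fit."""
    if fit_result.technique != "gbm":
        raise ValueError("relative influence is defined for gbm fits only")
    inf = fit_result.influence.copy()
    total = inf.sum()
    if total > 0:
        inf = inf / total * 100.0
    return inf
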