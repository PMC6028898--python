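"""Leave-one-year-out evaluation of the phenophase model grid.

Cross-validation blocks by calendar year: each study year in turn is the
held-out test set while the remaining years train the model, so skill
estimates reflect genuine interannual transfer rather than within-year
autocorrelation.  Every training-fold artefact — the predictor cutoff, the
imputation medians, Boruta screening, hyperparameter tuning, location-
normalization history — is recomputed from the training years alone.

Performance is summarized as RMSE in days (averaged over folds) and R²,
the squared Pearson correlation between observed and predicted onsets
(computed on the pooled out-of-fold predictions).  Variable importance of
gradient-boosted fits is aggregated into meteorological / satellite /
spatial category shares scaled to 100%.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import FeatureBuilder, feature_categories
from .feature_screening import ScreeningResult, boruta_screen
from .meteo_features import CutoffRule, cutoff_for
from .model_suite import TECHNIQUES, FitResult, LearnerSpec, fit, predict, relative_influence

__all__ = [
    "PREDICTOR_GROUPS",
    "CVResult",
    "loyo_folds",
    "rmse",
    "r2",
    "build_predictor_group",
    "run_experiment_grid",
    "best_models",
    "category_importance",
    "fit_full_gbm",
    "climatology_cv_rmse",
    "results_frame",
]

logger = logging.getLogger(__name__)

PREDICTOR_GROUPS = ("meteo", "modis", "boruta", "all")

CATEGORY_LABELS = ("meteo", "modis", "spatial")


def loyo_folds(years: Sequence[int]) -> list[tuple[tuple[int, ...], int]]:
    """Leave-one-year-out folds: (train_years, test_year) per study year."""
    years = sorted(set(int(y) for y in years))
    if len(years) < 2:
        raise ValueError("need at least 2 years for leave-one-year-out CV")
    return [(tuple(y for y in years if y != test), test) for test in years]


def rmse(observed, predicted) -> float:
    """Root-mean-square error in days."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 1:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def r2(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values.

    By construction in [0, 1] and invariant to affine bias in the
    predictions.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need at least two paired values")
    if np.allclose(observed, observed[0]) or np.allclose(predicted, predicted[0]):
        raise ValueError("r2 undefined for a constant vector")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r**2)


def build_predictor_group(
    group: str,
    categories: Mapping[str, str] | None = None,
    screening: ScreeningResult | None = None,
) -> list[str]:
    """Column subset for one predictor group.

    meteo = meteorological + spatial predictors (46); modis = satellite
    predictors (69); all = every predictor (115); boruta = confirmed plus
    tentative features of a screening run.
    """
    categories = categories if categories is not None else feature_categories()
    names = list(categories)
    if group == "meteo":
        return [c for c in names if categories[c] in ("meteo", "spatial")]
    if group == "modis":
        return [c for c in names if categories[c] == "modis"]
    if group == "all":
        return names
    if group == "boruta":
        if screening is None:
            raise ValueError("boruta group requires a ScreeningResult")
        retained = set(screening.retained())
        return [c for c in names if c in retained]
    raise ValueError(f"unknown predictor group {group!r}; pick from {PREDICTOR_GROUPS}")


@dataclass
class CVResult:
    """Cross-validated performance of one (phenophase, technique, group)."""

    phenophase_id: str
    technique: str
    group: str
    predictions: pd.DataFrame  # columns: year, station_id, observed, predicted
    fold_rmse: dict[int, float]
    rmse_days: float
    r2: float
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def errors(self) -> np.ndarray:
        return (self.predictions["predicted"] - self.predictions["observed"]).to_numpy()


def _fold_seed(seed: int, *labels) -> int:
    tag = zlib.crc32("|".join(str(x) for x in labels).encode())
    return int(np.random.SeedSequence((int(seed), tag)).generate_state(1)[0] % 2**31)


def run_experiment_grid(
    builder: FeatureBuilder,
    phenology: pd.DataFrame,
    phenophases: Sequence[str] | None = None,
    techniques: Sequence[str] = TECHNIQUES,
    groups: Sequence[str] = PREDICTOR_GROUPS,
    seed: int = 0,
    grids: Mapping[str, Mapping] | None = None,
    inner_cv: int = 5,
    screening_kwargs: Mapping | None = None,
) -> list[CVResult]:
    """Run the phenophase x technique x predictor-group grid under LOYO CV.

    ``phenology`` should already be quality-controlled; rows whose
    ``qc_flag`` is not "ok" are excluded from fitting.  Failed fits are
    logged, recorded on the result and skipped.
    """
    grids = grids or {}
    screening_kwargs = dict(screening_kwargs or {})
    categories = feature_categories()
    usable = phenology[(phenology["qc_flag"] == "ok") & phenology["onset_doy"].notna()]
    if phenophases is None:
        phenophases = sorted(usable["phenophase_id"].unique())

    results: list[CVResult] = []
    for phen in phenophases:
        obs = usable[usable["phenophase_id"] == phen]
        if obs.empty:
            logger.warning("no usable observations for %s; skipped", phen)
            continue
        folds = loyo_folds(obs["year"].unique())
        collected: dict[tuple[str, str], list[pd.DataFrame]] = {
            (t, g): [] for t in techniques for g in groups
        }
        fold_scores: dict[tuple[str, str], dict[int, float]] = {
            (t, g): {} for t in techniques for g in groups
        }
        failures: dict[tuple[str, str], list[tuple[int, str]]] = {
            (t, g): [] for t in techniques for g in groups
        }
        for train_years, test_year in folds:
            t0 = time.perf_counter()
            train_obs = obs[obs["year"].isin(train_years)]
            test_obs = obs[obs["year"] == test_year]
            if train_obs.empty or test_obs.empty:
                continue
            rule = cutoff_for(phen, float(train_obs["onset_doy"].mean()))
            X_train = builder.feature_table(train_obs, rule, train_years)
            X_test = builder.feature_table(test_obs, rule, train_years)
            y_train = train_obs["onset_doy"].to_numpy(dtype=float)
            y_test = test_obs["onset_doy"].to_numpy(dtype=float)
            feature_cols = [c for c in X_train.columns if c not in ("station_id", "year")]

            screening = None
            if "boruta" in groups:
                screening = boruta_screen(
                    X_train[feature_cols],
                    y_train,
                    seed=_fold_seed(seed, phen, "boruta", test_year),
                    **screening_kwargs,
                )
            for technique in techniques:
                for group in groups:
                    cols = build_predictor_group(group, categories, screening)
                    spec = LearnerSpec(
                        technique,
                        grid=grids.get(technique),
                        inner_cv=inner_cv,
                        seed=_fold_seed(seed, phen, technique, group, test_year),
                    )
                    try:
                        fitres = fit(spec, X_train[cols], y_train)
                        pred = predict(fitres, X_test[cols])
                    except Exception as exc:
                        logger.warning(
                            "fit failed: %s/%s/%s fold %s: %s",
                            phen, technique, group, test_year, exc,
                        )
                        failures[(technique, group)].append((test_year, str(exc)))
                        continue
                    collected[(technique, group)].append(
                        pd.DataFrame(
                            {
                                "year": test_year,
                                "station_id": test_obs["station_id"].to_numpy(),
                                "observed": y_test,
                                "predicted": pred,
                            }
                        )
                    )
                    fold_scores[(technique, group)][test_year] = rmse(y_test, pred)
            logger.info(
                "%s fold %s done in %.1fs", phen, test_year, time.perf_counter() - t0
            )
        for technique in techniques:
            for group in groups:
                frames = collected[(technique, group)]
                if not frames:
                    continue
                preds = pd.concat(frames, ignore_index=True)
                scores = fold_scores[(technique, group)]
                try:
                    pooled_r2 = r2(preds["observed"], preds["predicted"])
                except ValueError:
                    pooled_r2 = float("nan")
                results.append(
                    CVResult(
                        phenophase_id=phen,
                        technique=technique,
                        group=group,
                        predictions=preds,
                        fold_rmse=scores,
                        rmse_days=float(np.mean(list(scores.values()))),
                        r2=pooled_r2,
                        failures=failures[(technique, group)],
                    )
                )
    return results


def results_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    """Long-format summary: one row per (phenophase, technique, group, fold)."""
    rows = []
    for res in results:
        for year, score in res.fold_rmse.items():
            rows.append(
                {
                    "phenophase_id": res.phenophase_id,
                    "technique": res.technique,
                    "group": res.group,
                    "fold_year": year,
                    "rmse": score,
                    "r2": res.r2,
                }
            )
    return pd.DataFrame(rows)


def best_models(results: Sequence[CVResult]) -> pd.DataFrame:
    """Per-phenophase best (technique, group) by mean RMSE.

    Ties break toward the simpler technique (lm < lmAIC < lasso < pcr <
    rf < gbm).
    """
    simplicity = {"lm": 0, "lmAIC": 1, "lasso": 2, "pcr": 3, "rf": 4, "gbm": 5}
    rows = []
    by_phen: dict[str, list[CVResult]] = {}
    for res in results:
        by_phen.setdefault(res.phenophase_id, []).append(res)
    for phen, group in sorted(by_phen.items()):
        best = min(group, key=lambda r: (r.rmse_days, simplicity.get(r.technique, 99)))
        rows.append(
            {
                "phenophase_id": phen,
                "technique": best.technique,
                "group": best.group,
                "rmse_days": best.rmse_days,
                "r2": best.r2,
            }
        )
    return pd.DataFrame(rows)


def category_importance(
    influence: pd.Series,
    categories: Mapping[str, str] | None = None,
    top_k: int = 10,
) -> dict[str, float]:
    """Category shares of gradient-boosting relative influence.

    The ``top_k`` features by relative influence are partitioned into
    meteorological, satellite (modis) and spatial categories; influence is
    averaged within each category (0 for an absent category) and the three
    means are scaled to sum to 100%.
    """
    categories = categories if categories is not None else feature_categories()
    top = influence.sort_values(ascending=False).head(min(top_k, len(influence)))
    means = {}
    for label in CATEGORY_LABELS:
        members = [f for f in top.index if categories.get(f) == label]
        means[label] = float(np.mean([top[f] for f in members])) if members else 0.0
    total = sum(means.values())
    if total <= 0:
        raise ValueError("no positive influence among the top features")
    return {label: 100.0 * val / total for label, val in means.items()}


def fit_full_gbm(
    builder: FeatureBuilder,
    phenology: pd.DataFrame,
    phenophase_id: str,
    seed: int = 0,
    grid: Mapping | None = None,
    inner_cv: int = 5,
) -> tuple[FitResult, pd.Series]:
    """Fit gbm on all study years and all predictors; return (fit, influence).

    This is the model used for variable-importance attribution: one fit
    per phenophase on the complete record, cutoff from the all-years mean
    onset.
    """
    obs = phenology[
        (phenology["phenophase_id"] == phenophase_id)
        & (phenology["qc_flag"] == "ok")
        & phenology["onset_doy"].notna()
    ]
    if obs.empty:
        raise ValueError(f"no usable observations for {phenophase_id}")
    years = tuple(sorted(obs["year"].unique()))
    rule = cutoff_for(phenophase_id, float(obs["onset_doy"].mean()))
    X = builder.feature_table(obs, rule, years)
    feature_cols = [c for c in X.columns if c not in ("station_id", "year")]
    spec = LearnerSpec("gbm", grid=grid, inner_cv=inner_cv, seed=_fold_seed(seed, phenophase_id, "full"))
    fitres = fit(spec, X[feature_cols], obs["onset_doy"].to_numpy(dtype=float))
    return fitres, relative_influence(fitres)


def climatology_cv_rmse(obs: pd.DataFrame) -> float:
    """LOYO RMSE of the climatological baseline (training-mean predictor)."""
    folds = loyo_folds(obs["year"].unique())
    scores = []
    for train_years, test_year in folds:
        train = obs[obs["year"].isin(train_years)]["onset_doy"]
        test = obs[obs["year"] == test_year]["onset_doy"]
        if train.empty or test.empty:
            continue
        scores.append(rmse(test, np.full(len(test), train.mean())))
    return float(np.mean(scores))
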