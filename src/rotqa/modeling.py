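"""Grouped splitting, attribution-based feature selection, SSIM prediction, statistics.

Feature selection is two-stage: each feature group (radiomics,
dosiomics) is ranked separately with a gradient-boosted regression model
and TreeSHAP-style per-sample attributions (mean |attribution| as the
importance score); the per-group top-k sets are merged, re-ranked with a
fresh model, and features whose importance share exceeds a configurable
floor are retained.  The retained set is concatenated with the rotation
angles for modeling.

Model search replaces genetic-programming AutoML with a fixed, seeded
candidate family (regularized linear, random forest, gradient-boosted
trees) selected by grouped 10-fold cross-validated R² on the training
plans — the same decision surface, but deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    median_absolute_error,
    r2_score,
)
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import MinMaxScaler

from .types import DegenerateInputError, ValidationError

__all__ = [
    "SplitPlan",
    "SelectionResult",
    "ModelReport",
    "CorrelationResult",
    "grouped_split",
    "min_max_scale",
    "rank_features",
    "tree_attributions",
    "TwoStageSelector",
    "two_stage_select",
    "CandidateSearchRegressor",
    "fit_evaluate",
    "scenario_compare",
    "pearson",
    "direction_analysis",
]

ANGLE_COLUMNS = ("pitch_deg", "roll_deg", "yaw_deg")


# ------------------------------------------------------------------ splitting


@dataclass(frozen=True)
class SplitPlan:
    """Plan-level train/test partition (no plan on both sides)."""

    train_plan_ids: frozenset
    test_plan_ids: frozenset
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.train_plan_ids & self.test_plan_ids:
            raise ValidationError("train and test plan sets overlap")

    def side(self, plan_ids: Sequence) -> np.ndarray:
        """Boolean mask: True for rows whose plan is in the training set."""
        return np.asarray([p in self.train_plan_ids for p in plan_ids])


def grouped_split(plan_ids: Sequence, fraction: float = 0.70, seed: int = 0) -> SplitPlan:
    """Randomly partition plans (not records) into train/test.

    Train count = round(fraction * n_plans); every record follows its
    plan, so record-level leakage is impossible by construction.
    """
    plans = sorted(set(plan_ids))
    if len(plans) < 2:
        raise ValidationError("need at least 2 plans to split")
    n_train = int(round(fraction * len(plans)))
    if n_train < 1 or n_train >= len(plans):
        raise ValidationError(f"fraction {fraction} leaves an empty side for {len(plans)} plans")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plans))
    train = frozenset(plans[i] for i in order[:n_train])
    test = frozenset(plans[i] for i in order[n_train:])
    return SplitPlan(train, test, fraction, seed)


def min_max_scale(table: pd.DataFrame, fit_on: Optional[np.ndarray] = None):
    """Min-max scale columns to [0, 1] using ranges fitted on ``fit_on`` rows.

    Test rows transformed with train ranges may exceed [0, 1]; constant
    columns map to 0.  Returns ``(scaled_table, fitted_scaler)``.
    """
    fit_rows = table if fit_on is None else table.loc[np.asarray(fit_on)]
    scaler = MinMaxScaler().fit(fit_rows.to_numpy(dtype=float))
    scaled = pd.DataFrame(
        scaler.transform(table.to_numpy(dtype=float)), index=table.index, columns=table.columns
    )
    return scaled, scaler


# ------------------------------------------------------------------ attribution ranking


def _xgb_regressor(seed: int) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        n_estimators=200,
        max_depth=4,
        learning_rate=0.1,
        subsample=1.0,
        colsample_bytree=1.0,
        n_jobs=1,
        random_state=int(seed),
        tree_method="hist",
    )


def tree_attributions(model: xgb.XGBRegressor, X: pd.DataFrame):
    """Per-sample additive feature attributions of a fitted boosted-tree model.

    Returns ``(contribs, base_value)`` with one column per feature;
    ``contribs.sum(axis=1) + base_value`` equals the model's margin
    prediction (TreeSHAP additivity).
    """
    booster = model.get_booster()
    dmat = xgb.DMatrix(X.to_numpy(dtype=float), feature_names=list(X.columns))
    raw = booster.predict(dmat, pred_contribs=True)
    return raw[:, :-1], float(raw[0, -1])


def rank_features(X: pd.DataFrame, y: np.ndarray, seed: int = 0) -> list[tuple[str, float]]:
    """Rank features by mean |attribution| of a boosted-tree fit on (X -> y)."""
    y = np.asarray(y, dtype=float)
    if len(X) < 20:
        raise ValidationError("need at least 20 rows to rank features")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant target")
    model = _xgb_regressor(seed).fit(X.to_numpy(dtype=float), y)
    contribs, _ = tree_attributions(model, X)
    importance = np.abs(contribs).mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    return [(X.columns[i], float(importance[i])) for i in order]


@dataclass
class SelectionResult:
    """Outcome of the two-stage attribution-based selection."""

    group_rankings: dict = field(default_factory=dict)  # group -> [(name, score)]
    group_retained: dict = field(default_factory=dict)  # group -> [names]
    merged_ranking: list = field(default_factory=list)
    retained: list = field(default_factory=list)


class TwoStageSelector(BaseEstimator):
    """Two-stage attribution-based feature selector (sklearn transformer).

    Stage 1 ranks each feature group independently (boosted trees +
    TreeSHAP attributions) and keeps the top ``k`` per group; stage 2
    re-ranks the merged set with a fresh model and retains features whose
    mean |attribution| is at least ``floor_frac`` of the total.
    Groups are recognized by column-name prefix.
    """

    def __init__(self, k: int = 17, floor_frac: float = 0.01, seed: int = 0,
                 group_prefixes: tuple[str, ...] = ("radiomics_", "dosiomics_")):
        self.k = k
        self.floor_frac = floor_frac
        self.seed = seed
        self.group_prefixes = group_prefixes

    def fit(self, X: pd.DataFrame, y) -> "TwoStageSelector":
        y = np.asarray(y, dtype=float)
        result = SelectionResult()
        merged_names: list[str] = []
        for g, prefix in enumerate(self.group_prefixes):
            cols = [c for c in X.columns if c.startswith(prefix)]
            if not cols:
                continue
            ranking = rank_features(X[cols], y, seed=self.seed + g)
            k_eff = min(self.k, len(cols))
            keep = [name for name, _ in ranking[:k_eff]]
            result.group_rankings[prefix] = ranking
            result.group_retained[prefix] = keep
            merged_names += keep
        if self.k == 0 or not merged_names:
            result.retained = []
            self.result_ = result
            self.retained_ = []
            return self
        merged_ranking = rank_features(X[merged_names], y, seed=self.seed + 1000)
        total = sum(score for _, score in merged_ranking)
        floor = self.floor_frac * total
        retained = [name for name, score in merged_ranking if score >= floor and score > 0]
        result.merged_ranking = merged_ranking
        result.retained = retained
        self.result_ = result
        self.retained_ = retained
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.retained_]

    def fit_transform(self, X: pd.DataFrame, y) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def two_stage_select(
    radiomics: pd.DataFrame,
    dosiomics: pd.DataFrame,
    target,
    k: int = 17,
    floor_frac: float = 0.01,
    seed: int = 0,
) -> SelectionResult:
    """Convenience wrapper over :class:`TwoStageSelector` for two tables."""
    if len(radiomics) != len(dosiomics):
        raise ValidationError("feature tables must be row-aligned")
    X = pd.concat(
        [radiomics.reset_index(drop=True), dosiomics.reset_index(drop=True)], axis=1
    )
    sel = TwoStageSelector(k=k, floor_frac=floor_frac, seed=seed).fit(X, target)
    return sel.result_


# ------------------------------------------------------------------ model search


@dataclass
class ModelReport:
    """Held-out performance of the selected model for one scenario."""

    scenario: str
    model_name: str
    r2: float
    mae: float
    rmse: float
    medae: float
    cv_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValidationError("R^2 cannot exceed 1")
        if self.mae < 0 or self.rmse < self.mae - 1e-12:
            raise ValidationError("need rmse >= mae >= 0")


def _candidates(seed: int) -> list[tuple[str, BaseEstimator]]:
    return [
        ("ridge_a1", Ridge(alpha=1.0)),
        ("ridge_a01", Ridge(alpha=0.1)),
        ("ridge_ols", Ridge(alpha=1e-8)),
        (
            "random_forest",
            RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1),
        ),
        ("xgb_d3", xgb.XGBRegressor(n_estimators=300, max_depth=3, learning_rate=0.05,
                                    n_jobs=1, random_state=seed, tree_method="hist")),
        ("xgb_d5", xgb.XGBRegressor(n_estimators=200, max_depth=5, learning_rate=0.1,
                                    n_jobs=1, random_state=seed, tree_method="hist")),
    ]


class CandidateSearchRegressor(BaseEstimator, RegressorMixin):
    """Pick the best of a fixed candidate family by grouped CV R² and refit.

    ``fit(X, y, groups=...)`` runs (up to) ``cv_folds``-fold grouped
    cross-validation per candidate, keeps the highest mean R², and refits
    that candidate on all rows.  Deterministic under a fixed seed.
    """

    def __init__(self, cv_folds: int = 10, seed: int = 0):
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.arange(len(y)) if groups is None else np.asarray(groups)
        n_groups = len(set(groups.tolist()))
        folds = min(self.cv_folds, n_groups)
        if folds < 2:
            raise ValidationError("need at least 2 groups for cross-validation")
        cv = GroupKFold(n_splits=folds)
        best = (-np.inf, None, None, ())
        for name, est in _candidates(self.seed):
            scores = []
            for tr, va in cv.split(X, y, groups):
                m = clone(est).fit(X[tr], y[tr])
                scores.append(r2_score(y[va], m.predict(X[va])))
            mean = float(np.mean(scores))
            if mean > best[0]:
                best = (mean, name, est, tuple(scores))
        self.cv_score_, self.best_name_, est, self.cv_scores_ = best
        self.best_estimator_ = clone(est).fit(X, y)
        return self

    def predict(self, X):
        return self.best_estimator_.predict(np.asarray(X, dtype=float))


def fit_evaluate(
    features: pd.DataFrame,
    target,
    plan_ids: Sequence,
    split: SplitPlan,
    scenario: str = "full",
    cv_folds: int = 10,
    seed: int = 0,
) -> ModelReport:
    """Model search on the training plans, report held-out test metrics.

    Features are min-max scaled with train-fitted ranges.  Reports R²,
    MAE, RMSE and MedAE on the records of the held-out test plans.
    """
    y = np.asarray(target, dtype=float)
    plan_ids = np.asarray(plan_ids)
    is_train = split.side(plan_ids)
    if is_train.all() or not is_train.any():
        raise DegenerateInputError("split leaves train or test empty for these records")
    scaled, _ = min_max_scale(features, fit_on=is_train)
    X = scaled.to_numpy(dtype=float)

    search = CandidateSearchRegressor(cv_folds=cv_folds, seed=seed)
    search.fit(X[is_train], y[is_train], groups=plan_ids[is_train])
    pred = search.predict(X[~is_train])
    y_te = y[~is_train]
    return ModelReport(
        scenario=scenario,
        model_name=search.best_name_,
        r2=float(r2_score(y_te, pred)),
        mae=float(mean_absolute_error(y_te, pred)),
        rmse=float(np.sqrt(mean_squared_error(y_te, pred))),
        medae=float(median_absolute_error(y_te, pred)),
        cv_scores=search.cv_scores_,
    )


def scenario_compare(
    table: pd.DataFrame,
    target_col: str = "ssim",
    plan_col: str = "plan_id",
    angle_cols: tuple[str, ...] = ANGLE_COLUMNS,
    k: int = 17,
    floor_frac: float = 0.01,
    fraction: float = 0.70,
    cv_folds: int = 10,
    seed: int = 0,
) -> dict[str, ModelReport]:
    """Compare the three modeling scenarios on one shared grouped split.

    ``full`` = selected radiomic/dosiomic features + rotation angles;
    ``rotation_only`` = the three angles; ``features_only`` = selected
    features without angles.  Selection is fitted on training rows only.
    """
    y = table[target_col].to_numpy(dtype=float)
    plans = table[plan_col].to_numpy()
    feat_cols = [
        c for c in table.columns if c.startswith("radiomics_") or c.startswith("dosiomics_")
    ]
    split = grouped_split(plans, fraction=fraction, seed=seed)
    is_train = split.side(plans)

    selector = TwoStageSelector(k=k, floor_frac=floor_frac, seed=seed)
    selector.fit(table.loc[is_train, feat_cols], y[is_train])
    selected = selector.retained_

    scenarios = {
        "full": selected + list(angle_cols),
        "rotation_only": list(angle_cols),
        "features_only": selected if selected else feat_cols[: max(1, k)],
    }
    reports = {}
    for name, cols in scenarios.items():
        reports[name] = fit_evaluate(
            table[cols], y, plans, split, scenario=name, cv_folds=cv_folds, seed=seed
        )
    reports["_selection"] = selector.result_  # type: ignore[assignment]
    reports["_split"] = split  # type: ignore[assignment]
    return reports


# ------------------------------------------------------------------ statistics


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12 or not 0 <= self.p <= 1:
            raise ValidationError("invalid correlation result")


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def direction_analysis(
    table: pd.DataFrame,
    metric_cols: Optional[Sequence[str]] = None,
    angle_col: str = "angle_total_deg",
    pass_col: Optional[str] = "gamma_rd_2%/2mm",
    pass_threshold: float = 95.0,
) -> pd.DataFrame:
    """Per-direction correlation table plus gamma pass proportions.

    Groups: each single direction present (UP/RO/CW) and ``multi`` for
    records with >= 2 directions; ``multi`` additionally regresses each
    metric on the direction count (rows with group ``multi_ndir``).
    Returns one row per (group, metric): Pearson r, p, n, and the group's
    proportion of records with the 2%/2 mm gamma pass rate above the
    clinical threshold.  Groups with fewer than 3 records are skipped.
    """
    if metric_cols is None:
        metric_cols = [
            c
            for c in table.columns
            if c == "ssim" or c.startswith("gamma_") or c.startswith("dd_")
        ]
    groups: dict[str, pd.DataFrame] = {}
    single = table[table["n_directions"] == 1]
    for label in ("UP", "RO", "CW"):
        groups[label] = single[single["direction_label"] == label]
    groups["multi"] = table[table["n_directions"] >= 2]

    rows = []
    for gname, g in groups.items():
        if len(g) < 3:
            continue
        if pass_col is not None and pass_col in g.columns:
            prop = 100.0 * float((g[pass_col] > pass_threshold).mean())
        else:
            prop = np.nan
        xs = {gname: g[angle_col].to_numpy(float)}
        if gname == "multi":
            xs["multi_ndir"] = g["n_directions"].to_numpy(float)
        for xname, x in xs.items():
            for metric in metric_cols:
                yv = g[metric].to_numpy(float)
                try:
                    c = pearson(x, yv)
                    r_, p_ = c.r, c.p
                except DegenerateInputError:
                    r_, p_ = np.nan, np.nan
                rows.append(
                    {
                        "group": xname,
                        "metric": metric,
                        "r": r_,
                        "p": p_,
                        "n": len(g),
                        "pass_proportion": prop,
                    }
                )
    return pd.DataFrame(rows)
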