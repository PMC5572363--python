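"""Predicting map inflation from the co-segregation proportion.

The sampled-proportion experiment yields, per rebuilt map, a proportion
level x (percent of co-segregating markers added) and an inflation factor
y = IF (percent). Seven regression learners are fitted to predict y from
x — linear regression (LR), a Gaussian identity-link GLM (numerically
equivalent to LR), quadratic and cubic polynomial regression (POLY2,
POLY3), k-nearest-neighbour regression (KNN), radial-basis support-vector
regression (SVM), a pruned regression tree (CART) and a random forest
(RF) — under two partition designs: a single 80/20 train/test split and
10-fold cross-validation with 5 replicates.

Goodness of fit is the root mean squared error (RMSE, in IF percentage
points) on held-out data; accuracy is the Pearson correlation between
predicted and observed held-out values. All learners share the same
seeded partitions so their scores are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

MODEL_NAMES = ("LR", "GLM", "POLY2", "POLY3", "KNN", "SVM", "CART", "RF")
PARTITION_DESIGNS = ("holdout_80_20", "cv10x5")

#: learner hyper-parameter defaults
DEFAULTS = {
    "knn_k_grid": (5, 9, 17, 33),
    "svr_C": 1.0,
    "svr_gamma": "scale",
    "svr_epsilon": 0.1,
    "rf_trees": 500,
    "cart_prune_folds": 5,
}


@dataclass
class PredictionResult:
    """Held-out score of one learner under one partition design."""

    model: str
    design: str
    rmse: float
    accuracy: float


class GaussianGLM(BaseEstimator, RegressorMixin):
    """Gaussian-family, identity-link GLM (iteratively reweighted LS).

    A distinct estimation route from ordinary least squares that must
    agree with it numerically on Gaussian data.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._res = sm.GLM(
            np.asarray(y, dtype=float),
            sm.add_constant(X, has_constant="add"),
            family=sm.families.Gaussian(),
        ).fit()
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self._res.predict(sm.add_constant(X, has_constant="add"))


class PrunedCART(BaseEstimator, RegressorMixin):
    """Regression tree with cost-complexity pruning chosen by internal CV.

    A full tree's pruning path supplies candidate alphas; the alpha with
    the lowest internal k-fold cross-validated squared error is kept.
    """

    def __init__(self, prune_folds: int = 5, random_state: int | None = None):
        self.prune_folds = prune_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        path = DecisionTreeRegressor(random_state=self.random_state).cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
        if len(alphas) > 25:  # subsample the path; scores vary smoothly in alpha
            alphas = alphas[np.linspace(0, len(alphas) - 1, 25).astype(int)]
        kf = KFold(n_splits=self.prune_folds, shuffle=True, random_state=self.random_state)
        errs = np.zeros(len(alphas))
        for tr, te in kf.split(X):
            for i, a in enumerate(alphas):
                t = DecisionTreeRegressor(ccp_alpha=a, random_state=self.random_state)
                t.fit(X[tr], y[tr])
                errs[i] += np.mean((t.predict(X[te]) - y[te]) ** 2)
        self.ccp_alpha_ = float(alphas[int(np.argmin(errs))])
        self.tree_ = DecisionTreeRegressor(
            ccp_alpha=self.ccp_alpha_, random_state=self.random_state
        ).fit(X, y)
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, dtype=float))


def _make_models(seed: int) -> dict[str, object]:
    """The seven learners (eight tags: GLM duplicates LR by construction)."""
    return {
        "LR": LinearRegression(),
        "GLM": GaussianGLM(),
        "POLY2": make_pipeline(PolynomialFeatures(2), LinearRegression()),
        "POLY3": make_pipeline(PolynomialFeatures(3), LinearRegression()),
        # neighbourhood size tuned by internal CV: the predictor is discrete
        # (a handful of proportion levels with many tied neighbours), so a
        # fixed small k would average an arbitrary subset of the ties
        "KNN": GridSearchCV(
            make_pipeline(StandardScaler(), KNeighborsRegressor()),
            {"kneighborsregressor__n_neighbors": list(DEFAULTS["knn_k_grid"])},
            cv=KFold(n_splits=5, shuffle=True, random_state=seed),
            scoring="neg_mean_squared_error",
            error_score=-np.inf,  # k larger than a small training fold just loses
        ),
        "SVM": TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(),
                SVR(
                    kernel="rbf",
                    C=DEFAULTS["svr_C"],
                    gamma=DEFAULTS["svr_gamma"],
                    epsilon=DEFAULTS["svr_epsilon"],
                ),
            ),
            transformer=StandardScaler(),
        ),
        "CART": PrunedCART(prune_folds=DEFAULTS["cart_prune_folds"], random_state=seed),
        "RF": RandomForestRegressor(
            n_estimators=DEFAULTS["rf_trees"], random_state=seed, n_jobs=1
        ),
    }


def make_dataset(records: pd.DataFrame) -> pd.DataFrame:
    """Feature/response table from experiment records.

    Keeps only sampled-proportion (phase II) maps; the predictor is the
    proportion level (percent, treated as continuous) and the response is
    the inflation factor (percent). One row per map; lg_id is carried for
    stratified reporting.
    """
    if records.empty:
        raise ValueError("no records supplied")
    mask = records["mode"] == "phaseII_sampled"
    excluded = int((~mask).sum())
    if excluded:
        logger.info("excluded %d non-sampled (sequential) records", excluded)
    df = records.loc[mask, ["lg_id", "proportion_pct", "IF"]].rename(
        columns={"proportion_pct": "x", "IF": "y"}
    )
    if df.empty:
        raise ValueError("no sampled-proportion records to learn from")
    return df.reset_index(drop=True)


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        logger.warning("degenerate variance in held-out data; accuracy undefined")
        return rmse, float("nan")
    return rmse, float(pearsonr(y_pred, y_true).statistic)


def fit_models(
    table: pd.DataFrame,
    design: str = "holdout_80_20",
    seed: int = 0,
    models: tuple[str, ...] = MODEL_NAMES,
) -> pd.DataFrame:
    """Fit the learners under one partition design and score held-out data.

    ``holdout_80_20`` fits on a seeded 80% split and scores the remaining
    20%. ``cv10x5`` runs 10-fold cross-validation with 5 replicates and
    reports the mean RMSE / Pearson accuracy over the 50 fold evaluations.
    All learners see the same partitions.
    """
    if design not in PARTITION_DESIGNS:
        raise ValueError(f"unknown partition design {design!r}")
    if len(table) < 50:
        raise ValueError("need at least 50 maps to fit prediction models")
    X = table[["x"]].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    registry = _make_models(seed)
    results: list[PredictionResult] = []
    if design == "holdout_80_20":
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.2, random_state=seed)
        for name in models:
            est = clone(registry[name])
            est.fit(X_tr, y_tr)
            rmse, acc = _score(y_te, np.asarray(est.predict(X_te), dtype=float))
            results.append(PredictionResult(name, design, rmse, acc))
    else:
        rkf = RepeatedKFold(n_splits=10, n_repeats=5, random_state=seed)
        folds = list(rkf.split(X))
        for name in models:
            rmses, accs = [], []
            for tr, te in folds:
                est = clone(registry[name])
                est.fit(X[tr], y[tr])
                rmse, acc = _score(y[te], np.asarray(est.predict(X[te]), dtype=float))
                rmses.append(rmse)
                accs.append(acc)
            results.append(
                PredictionResult(name, design, float(np.mean(rmses)), float(np.nanmean(accs)))
            )
    return pd.DataFrame([r.__dict__ for r in results])
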