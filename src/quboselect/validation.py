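"""Baseline ranking and cumulative top-k validation harness.

Two pieces mirror how annealing-based selection is benchmarked in
practice:

* a multivariable linear regression (MLR) baseline that ranks features by
  the magnitude of their standardized OLS coefficients, and
* a gradient-boosted-tree evaluation of cumulative top-k feature sets
  (top 10, 20, 30, 40, 50 by default) under both a classification task
  (the continuous score median-split into binary classes; balanced
  accuracy) and a regression task (negative mean absolute error), with
  repeated k-fold cross-validation and Welch two-sample t-tests between
  methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import balanced_accuracy_score, mean_absolute_error, mean_squared_error
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

from .ranking import FeatureRanking
from .synthetic import SurveyTable

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "mlr_ranking",
    "random_ranking",
    "evaluate_feature_sets",
    "compare_methods",
    "welch_t",
]

TASKS = ("classification", "regression")


@dataclass(frozen=True)
class EvaluationConfig:
    """Settings of the cumulative top-k evaluation.

    ``conditions`` are the cumulative set sizes; any exceeding the number
    of available features is an error.  ``regression_metric`` is ``"mae"``
    (negative mean absolute error) by default, with ``"mse"`` available.
    ``model`` selects the learner: ``"xgboost"`` (default) or ``"dummy"``
    (median/prior constant predictors, the chance-level reference).
    """

    conditions: tuple[int, ...] = (10, 20, 30, 40, 50)
    n_repeats: int = 30
    n_folds: int = 10
    classification_split: str = "median"
    regression_metric: str = "mae"
    model: str = "xgboost"
    xgb_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.conditions) != sorted(self.conditions):
            raise ValueError("conditions must be sorted ascending")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.classification_split != "median":
            raise ValueError(f"unknown classification split {self.classification_split!r}")
        if self.regression_metric not in ("mae", "mse"):
            raise ValueError(f"unknown regression metric {self.regression_metric!r}")
        if self.model not in ("xgboost", "dummy"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class EvaluationReport:
    """Metric distributions per (task, condition) for one selection method.

    ``metrics[(task, c)]`` is the vector of ``n_repeats`` per-repeat values
    (each a mean over CV folds): balanced accuracy in [0, 1] for
    classification, negative error (<= 0) for regression.
    """

    method: str
    conditions: tuple[int, ...]
    n_repeats: int
    metrics: dict[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        for (task, c), v in self.metrics.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_repeats,):
                raise ValueError(f"metric vector for ({task}, {c}) has wrong length")
            if task == "classification" and (v.min() < 0 or v.max() > 1):
                raise ValueError("balanced accuracy out of [0, 1]")
            if task == "regression" and v.max() > 1e-12:
                raise ValueError("negative error metric must be <= 0")
            self.metrics[(task, c)] = v

    def mean(self, task: str, condition: int) -> float:
        return float(self.metrics[(task, condition)].mean())

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"method": self.method, "task": task, "condition": c, "repeat": r, "value": val}
            for (task, c), v in self.metrics.items()
            for r, val in enumerate(v)
        ]
        return pd.DataFrame(rows)


def mlr_ranking(table: SurveyTable, name: str = "mlr") -> FeatureRanking:
    """Rank features by |standardized OLS coefficient| of y on all features.

    Features are standardized to zero mean, unit variance before the joint
    fit; constant columns are dropped (with a warning) and ranked last.
    When n <= p the ordinary fit is replaced by a lightly regularized ridge
    fit (also logged via warning) so the ranking stays defined.
    """
    X = table.X.astype(float)
    y = table.y
    n, p = X.shape
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"mlr_ranking: dropping {int((~keep).sum())} constant feature column(s)",
            UserWarning,
            stacklevel=2,
        )
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if n > keep.sum():
        model = LinearRegression()
    else:
        warnings.warn("mlr_ranking: n <= p, falling back to ridge", UserWarning, stacklevel=2)
        model = Ridge(alpha=1.0)
    model.fit(Xs, y)
    scores = np.zeros(p)
    scores[keep] = np.abs(model.coef_)
    # |coefficient| descending, feature index ascending on ties
    order = np.lexsort((np.arange(p), -scores))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return FeatureRanking(
        feature_names=table.feature_names,
        ranks=ranks,
        scores=scores,
        metadata={"method": name, "estimator": type(model).__name__},
    )


def random_ranking(table: SurveyTable, seed: int, name: str = "random") -> FeatureRanking:
    """Uniformly random feature ranking — the null reference for comparisons."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(table.p)
    ranks = np.empty(table.p, dtype=int)
    ranks[order] = np.arange(1, table.p + 1)
    return FeatureRanking(
        feature_names=table.feature_names, ranks=ranks, metadata={"method": name, "seed": seed}
    )


def binarize_target(y: np.ndarray, split: str = "median") -> np.ndarray:
    """Median split of the continuous score into balanced binary classes."""
    if split != "median":
        raise ValueError(f"unknown split rule {split!r}")
    return (y > np.median(y)).astype(int)


def _make_models(config: EvaluationConfig, rs: int):
    if config.model == "dummy":
        return DummyClassifier(strategy="prior"), DummyRegressor(strategy="median")
    params = dict(n_jobs=1, tree_method="hist", random_state=rs, verbosity=0)
    params.update(config.xgb_params)
    return XGBClassifier(**params), XGBRegressor(**params)


def evaluate_feature_sets(
    table: SurveyTable,
    ranking: FeatureRanking,
    config: EvaluationConfig | None = None,
    method: str | None = None,
) -> EvaluationReport:
    """Cumulative top-k evaluation of one ranking with boosted trees.

    For each condition c the model sees only the top-c ranked features.
    Classification uses the median-split binary target, stratified k-fold
    CV and balanced accuracy; regression uses plain k-fold CV and the
    negated error.  Each repeat reshuffles the folds with a seed derived
    from ``(config.seed, repeat)``.
    """
    config = config or EvaluationConfig()
    if any(c > table.p for c in config.conditions):
        raise ValueError(f"condition exceeds feature count p={table.p}")
    method = method or ranking.metadata.get("method", "ranking")
    X_all = table.X.astype(float)
    y = table.y
    y_bin = binarize_target(y, config.classification_split)
    err = mean_absolute_error if config.regression_metric == "mae" else mean_squared_error

    name_to_idx = {nm: i for i, nm in enumerate(table.feature_names)}
    metrics: dict[tuple[str, int], np.ndarray] = {}
    for c in config.conditions:
        cols = [name_to_idx[nm] for nm in ranking.top(c)]
        Xc = X_all[:, cols]
        clf_vals = np.empty(config.n_repeats)
        reg_vals = np.empty(config.n_repeats)
        for r in range(config.n_repeats):
            rs = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31))
            clf, reg = _make_models(config, rs)
            skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rs)
            accs = []
            for tr, te in skf.split(Xc, y_bin):
                clf.fit(Xc[tr], y_bin[tr])
                accs.append(balanced_accuracy_score(y_bin[te], clf.predict(Xc[te])))
            clf_vals[r] = np.mean(accs)
            kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=rs)
            errs = []
            for tr, te in kf.split(Xc):
                reg.fit(Xc[tr], y[tr])
                errs.append(-err(y[te], reg.predict(Xc[te])))
            reg_vals[r] = np.mean(errs)
        metrics[("classification", c)] = clf_vals
        metrics[("regression", c)] = reg_vals
    return EvaluationReport(
        method=method,
        conditions=tuple(config.conditions),
        n_repeats=config.n_repeats,
        metrics=metrics,
    )


def welch_t(a, b) -> tuple[float, float, bool]:
    """Welch two-sample t-test; returns (t, two-sided p, degenerate flag).

    When both samples have zero variance the test statistic is undefined;
    p is reported as 1.0 (t = 0) with the degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 0.0, 1.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def compare_methods(report_a: EvaluationReport, report_b: EvaluationReport) -> pd.DataFrame:
    """Per-(task, condition) Welch t-test table between two methods."""
    if report_a.n_repeats != report_b.n_repeats:
        raise ValueError("reports have different n_repeats")
    if report_a.conditions != report_b.conditions:
        raise ValueError("reports have different conditions")
    rows = []
    for task in TASKS:
        for c in report_a.conditions:
            key = (task, c)
            if key not in report_a.metrics or key not in report_b.metrics:
                continue
            t, p, degenerate = welch_t(report_a.metrics[key], report_b.metrics[key])
            rows.append(
                {
                    "task": task,
                    "condition": c,
                    "mean_a": float(report_a.metrics[key].mean()),
                    "mean_b": float(report_b.metrics[key].mean()),
                    "t": t,
                    "p_value": p,
                    "significant": bool(p < 0.05),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
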