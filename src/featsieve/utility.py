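"""Utility filter: per-feature predictive-value screening.

Each candidate feature is scored three ways against the binary target:

* ``pval`` — two-sided p-value of a univariate association test (Welch
  t-test for continuous features; chi-square, or Fisher exact on sparse
  2x2 tables, for discrete ones),
* ``mi`` — plug-in mutual information (nats) on a quantile-binned joint
  distribution,
* ``fimp`` — global model-based importance: the mean absolute per-sample
  attribution of a cross-validated gradient-boosted tree classifier.

A feature passes the filter if it meets the configured criteria (any/all).
Thresholds default to the deliberately lenient screening values
(p < 0.2, MI >= 1e-3, FImp >= 1e-4): the stage is meant to discard only
clearly uninformative features.
"""

from __future__ import annotations

import warnings

import lightgbm as lgb
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold

from ._common import derive_seed, logger

#: features with at most this many distinct values use the contingency test
DISCRETE_MAX_LEVELS = 5


class UtilityConfig(BaseModel):
    theta_p: float = Field(default=0.2, gt=0.0)
    theta_mi: float = Field(default=1e-3, gt=0.0)
    theta_fimp: float = Field(default=1e-4, gt=0.0)
    mode: str = Field(default="any", pattern="^(any|all)$")
    n_bins: int = Field(default=10, ge=2)
    seed: int = 0


def univariate_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value of association between a feature and binary target.

    Continuous features: Welch two-sample test of location between classes.
    Discrete features (<= DISCRETE_MAX_LEVELS distinct values): chi-square
    test of independence, replaced by Fisher's exact test when the table is
    2x2 with any expected cell below 5.  Constant features carry no
    information and return p = 1.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(np.unique(x)) <= 1:
        logger.warning("constant feature in univariate test; p=1.0")
        return 1.0
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need >=2 observations per class")
    levels = np.unique(x)
    if len(levels) <= DISCRETE_MAX_LEVELS:
        table = pd.crosstab(x, y).to_numpy()
        if table.shape == (2, 2):
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                return float(stats.fisher_exact(table)[1])
        return float(stats.chi2_contingency(table)[1])
    a, b = x[y == 1], x[y == 0]
    return float(stats.ttest_ind(a, b, equal_var=False)[1])


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) between binned ``x`` and binary ``y``.

    Continuous features are discretized into at most ``n_bins`` quantile
    bins; discrete features are used as-is.  Degenerate binning (a single
    bin) yields 0.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) > n_bins:
        binned = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    else:
        binned = pd.factorize(x)[0]
    if len(np.unique(binned)) <= 1:
        return 0.0
    return float(mutual_info_score(binned, np.asarray(y)))


def model_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_splits: int = 5,
    n_estimators: int = 100,
) -> pd.Series:
    """Global attribution-based importance from a cross-validated booster.

    A LightGBM classifier is trained on each training fold; per-sample
    feature attributions (TreeSHAP contributions to the log-odds margin)
    are computed on the held-out fold.  The importance of a feature is the
    mean absolute attribution over all held-out samples.  Deterministic
    under ``seed`` (single-threaded, row-wise histogram construction).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("model_importance requires both classes present")
    if len(y) < 50:
        raise ValueError("model_importance requires >= 50 rows")
    if int(y.sum()) < 10:
        raise ValueError("model_importance requires >= 10 positives")
    values = X.to_numpy(dtype=float)
    abs_contrib = np.zeros(X.shape[1])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train, test in skf.split(values, y):
        fold_train = pd.DataFrame(values[train], columns=range(X.shape[1]))
        fold_test = pd.DataFrame(values[test], columns=range(X.shape[1]))
        model = lgb.LGBMClassifier(
            n_estimators=n_estimators,
            num_leaves=31,
            learning_rate=0.1,
            min_child_samples=20,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            random_state=seed,
            verbose=-1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(fold_train, y[train])
        contrib = model.predict(fold_test, pred_contrib=True)
        abs_contrib += np.abs(contrib[:, :-1]).sum(axis=0)  # last col = base value
    return pd.Series(abs_contrib / len(y), index=X.columns, name="fimp")


def shap_attributions(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_estimators: int = 100
) -> tuple[np.ndarray, np.ndarray, "lgb.LGBMClassifier"]:
    """Fit one booster on the full data; return (contributions, margins, model).

    Contributions include the base-value column last; their row sums equal
    the raw log-odds margin (additivity of TreeSHAP).  Used for additivity
    checks and the importance-baseline comparison.
    """
    model = lgb.LGBMClassifier(
        n_estimators=n_estimators,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        random_state=seed,
        verbose=-1,
    )
    Xv = pd.DataFrame(X.to_numpy(dtype=float), columns=range(X.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xv, y)
    contrib = model.predict(Xv, pred_contrib=True)
    margin = model.predict(Xv, raw_score=True)
    return contrib, margin, model


def compute_utility_scores(
    X: pd.DataFrame, y: np.ndarray, config: UtilityConfig | None = None
) -> pd.DataFrame:
    """Score every feature; returns a frame with pval/mi/fimp columns."""
    config = config or UtilityConfig()
    pvals = {c: univariate_pvalue(X[c].to_numpy(), y) for c in X.columns}
    mis = {c: mutual_information(X[c].to_numpy(), y, config.n_bins) for c in X.columns}
    fimp = model_importance(X, y, seed=derive_seed(config.seed, "fimp"))
    scores = pd.DataFrame(
        {"pval": pd.Series(pvals), "mi": pd.Series(mis), "fimp": fimp}
    )
    scores.index.name = "feature"
    return apply_utility_filter(scores, config)


def apply_utility_filter(scores: pd.DataFrame, config: UtilityConfig) -> pd.DataFrame:
    """Attach pass flags.  p is compared strictly <, MI and FImp with >=."""
    out = scores.copy()
    out["pass_pval"] = out["pval"] < config.theta_p
    out["pass_mi"] = out["mi"] >= config.theta_mi
    out["pass_fimp"] = out["fimp"] >= config.theta_fimp
    flags = out[["pass_pval", "pass_mi", "pass_fimp"]]
    out["pass_utility"] = flags.any(axis=1) if config.mode == "any" else flags.all(axis=1)
    return out
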