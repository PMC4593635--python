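"""Statistical stages: regression tree on FI and the path-length model.

The regression tree predicts web-level mean flow indirectness from the
topological metric suite.  Splitting follows the classic cost-complexity
rule: a split is made only when it increases R-squared by at least
``min_gain`` (0.01 by default, i.e. rpart's cp), which maps exactly onto
scikit-learn's ``min_impurity_decrease = min_gain * Var(y)``.  The grown
tree is then pruned by 10-fold cross-validation over its cost-complexity
path.

The connectance -> path-length relationship is modeled as a through-origin
quadratic, PathLen = b1*C + b2*C**2 (no other intercept is possible: a web
with no links has no paths), compared against the through-origin linear
model by AIC under a Gaussian likelihood with the variance profiled out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "CartResult",
    "QuadraticFit",
    "fit_cart",
    "predict_fi",
    "fit_pathlen_quadratic",
    "tree_to_dict",
]


@dataclass
class CartResult:
    """Fitted regression tree: structure, selected variables, fit quality."""

    tree: dict  # nested node dicts: {var, threshold, left, right} or {value}
    feature_names: list[str]
    selected_variables: list[str]
    r_squared: float  # in-sample fraction of variance explained
    n_leaves: int
    n_samples: int
    ccp_alpha: float  # pruning strength chosen by cross-validation


@dataclass
class QuadraticFit:
    """Through-origin quadratic fit of path length on connectance."""

    b1: float
    b2: float
    r_squared: float  # uncentered: 1 - SSR/sum(y^2), the no-intercept convention
    r_squared_centered: float  # 1 - SSR/SST, for reference
    aic_quadratic: float
    aic_linear: float
    n: int

    @property
    def delta_aic(self) -> float:
        return self.aic_quadratic - self.aic_linear


def _sklearn_to_dict(t, feature_names: list[str], node: int = 0) -> dict:
    """Extract a fitted sklearn tree into plain nested dicts."""
    if t.children_left[node] == -1:
        return {"value": float(t.value[node].ravel()[0]),
                "n": int(t.n_node_samples[node])}
    return {
        "var": feature_names[t.feature[node]],
        "threshold": float(t.threshold[node]),
        "n": int(t.n_node_samples[node]),
        # left branch is taken when the condition (var < threshold) is met
        "left": _sklearn_to_dict(t, feature_names, t.children_left[node]),
        "right": _sklearn_to_dict(t, feature_names, t.children_right[node]),
    }


def tree_to_dict(estimator: DecisionTreeRegressor, feature_names: list[str]) -> dict:
    return _sklearn_to_dict(estimator.tree_, feature_names)


def _collect_vars(node: dict, out: set) -> set:
    if "var" in node:
        out.add(node["var"])
        _collect_vars(node["left"], out)
        _collect_vars(node["right"], out)
    return out


def _count_leaves(node: dict) -> int:
    if "var" not in node:
        return 1
    return _count_leaves(node["left"]) + _count_leaves(node["right"])


def fit_cart(
    records: pd.DataFrame,
    predictors: list[str],
    response: str = "mean_FI",
    min_gain: float = 0.01,
    cv_folds: int = 10,
    seed: int = 0,
) -> CartResult:
    """Regression tree on mean FI with min-R²-gain splits and CV pruning.

    Rows flagged invalid (if a ``valid`` column is present) or with missing
    values are dropped before fitting.
    """
    data = records
    if "valid" in data.columns:
        data = data[data["valid"].astype(bool)]
    data = data.dropna(subset=[*predictors, response])
    if len(data) < 2:
        raise ValueError("need at least 2 valid records to fit a tree")
    X = data[predictors].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    var_y = float(y.var())

    def grow(**kw) -> DecisionTreeRegressor:
        est = DecisionTreeRegressor(
            min_impurity_decrease=min_gain * var_y, random_state=seed, **kw
        )
        est.fit(X, y)
        return est

    full = grow()
    ccp_alpha = 0.0
    if var_y > 0 and full.get_n_leaves() > 1 and len(data) >= cv_folds:
        # candidate pruning strengths from the cost-complexity path
        path = full.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) > 1:
            cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            cv_mse = []
            for alpha in alphas:
                errs = []
                for tr, te in cv.split(X):
                    est = DecisionTreeRegressor(
                        min_impurity_decrease=min_gain * float(y[tr].var()),
                        ccp_alpha=float(alpha), random_state=seed,
                    )
                    est.fit(X[tr], y[tr])
                    errs.append(float(np.mean((est.predict(X[te]) - y[te]) ** 2)))
                cv_mse.append(np.mean(errs))
            ccp_alpha = float(alphas[int(np.argmin(cv_mse))])
            if ccp_alpha > 0:
                full = grow(ccp_alpha=ccp_alpha)

    pred = full.predict(X)
    # in-sample tree R^2 is >= 0 by construction (leaf means minimize SSE);
    # a response constant to float precision gets R^2 = 0 by convention
    sse = float(np.sum((y - pred) ** 2))
    sst = var_y * len(y)
    scale = max(1.0, float(np.abs(y).max()) ** 2) * len(y)
    r2 = max(0.0, 1.0 - sse / sst) if sst > 1e-24 * scale else 0.0
    tree = tree_to_dict(full, predictors)
    return CartResult(
        tree=tree,
        feature_names=list(predictors),
        selected_variables=sorted(_collect_vars(tree, set())),
        r_squared=r2,
        n_leaves=_count_leaves(tree),
        n_samples=len(data),
        ccp_alpha=ccp_alpha,
    )


def predict_fi(tree: dict | CartResult, metrics: dict) -> float:
    """Route a metric vector down the tree; left branch when var < threshold."""
    node = tree.tree if isinstance(tree, CartResult) else tree
    while "var" in node:
        var = node["var"]
        if var not in metrics or metrics[var] is None or not np.isfinite(metrics[var]):
            raise KeyError(f"metric {var!r} required by the tree is missing")
        node = node["left"] if metrics[var] < node["threshold"] else node["right"]
    return float(node["value"])


def _profiled_gaussian_aic(resid: np.ndarray, k_params: int) -> float:
    """AIC with sigma^2 profiled out: n*log(SSR/n) + 2*(k_params + 1)."""
    n = resid.size
    ssr = float(resid @ resid)
    return n * np.log(ssr / n) + 2.0 * (k_params + 1)


def fit_pathlen_quadratic(records: pd.DataFrame,
                          connectance: str = "nominal_C",
                          pathlen: str = "PathLen") -> QuadraticFit:
    """Least-squares PathLen = b1*C + b2*C^2 with no intercept, vs linear."""
    data = records.dropna(subset=[connectance, pathlen])
    C = data[connectance].to_numpy(dtype=float)
    y = data[pathlen].to_numpy(dtype=float)
    if len(np.unique(C)) < 3:
        raise ValueError("need at least 3 distinct connectance values")
    Xq = np.column_stack([C, C**2])
    fit_q = sm.OLS(y, Xq).fit()
    fit_l = sm.OLS(y, C[:, None]).fit()
    resid_q = y - fit_q.fittedvalues
    resid_l = y - fit_l.fittedvalues
    sst = float(np.sum((y - y.mean()) ** 2))
    return QuadraticFit(
        b1=float(fit_q.params[0]),
        b2=float(fit_q.params[1]),
        r_squared=float(fit_q.rsquared),  # statsmodels reports uncentered R2 when no const
        r_squared_centered=1.0 - float(resid_q @ resid_q) / sst,
        aic_quadratic=_profiled_gaussian_aic(resid_q, 2),
        aic_linear=_profiled_gaussian_aic(resid_l, 1),
        n=len(y),
    )
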