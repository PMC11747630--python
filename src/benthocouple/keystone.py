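"""Keystone ASV detection via PLS regression and VIP scores.

A partial least squares (PLS1) regression relates CLR ASV profiles to
a carbon response (particulate organic carbon flux for the water
column, sediment organic-carbon content for the seafloor). Each ASV's
variable importance in projection (VIP) summarises its contribution to
the explained response variance; keystones are ranked by combining VIP
with network degree centrality through a rank product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneOut

__all__ = [
    "PlsModel",
    "fit_pls",
    "vip_scores",
    "choose_n_components",
    "keystone_ranking",
]


@dataclass
class PlsModel:
    """Fitted PLS1 model (NIPALS extraction, via scikit-learn).

    Stores per-component X-weights, X-loadings, X-scores and y-loadings
    together with the fraction of centred y-variance explained by each
    component. Score vectors are mutually orthogonal and weight vectors
    unit-norm.
    """

    n_components: int
    x_weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    x_scores: np.ndarray  # (n, a)
    y_loadings: np.ndarray  # (a,)
    y_variance_explained: np.ndarray  # (a,)
    predictor_ids: list[str]
    fitted_values: np.ndarray
    _sk: PLSRegression | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
        return self._sk.predict(x).ravel()


def fit_pls(X: pd.DataFrame, y, n_components: int = 2, scale: bool = False) -> PlsModel:
    """Fit a PLS1 regression of the response on CLR ASV profiles.

    ``X`` and ``y`` are centred internally (optionally standardized with
    ``scale=True``); components are extracted sequentially so the fit
    is deterministic.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    x = X.to_numpy(dtype=float)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("response length does not match sample count")
    a_max = min(n - 1, p)
    if n_components > a_max:
        raise ValueError(f"n_components must be <= min(n-1, p) = {a_max}")
    sk = PLSRegression(n_components=n_components, scale=scale)
    sk.fit(x, y)
    scores = sk.x_scores_
    q = sk.y_loadings_.ravel()
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    # y-variance explained by each component: ||t_a||^2 q_a^2 / ||y_c||^2
    ss = (scores**2).sum(axis=0) * q**2 / ss_y
    return PlsModel(
        n_components=n_components,
        x_weights=sk.x_weights_,
        x_loadings=sk.x_loadings_,
        x_scores=scores,
        y_loadings=q,
        y_variance_explained=ss,
        predictor_ids=list(X.columns) if isinstance(X, pd.DataFrame) else [str(i) for i in range(p)],
        fitted_values=sk.predict(x).ravel(),
        _sk=sk,
    )


def vip_scores(model: PlsModel) -> pd.Series:
    """Variable importance in projection for every predictor.

    ``VIP_j = sqrt(p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a)``
    where ``SS_a`` is the y-variance explained by component ``a``. The
    mean of the squared VIPs is exactly 1.
    """
    w = model.x_weights
    p = w.shape[0]
    wnorm2 = (w**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    ss = model.y_variance_explained
    total = ss.sum()
    if total <= 0:
        return pd.Series(np.ones(p), index=model.predictor_ids, name="vip")
    vip = np.sqrt(p * ((w**2 / wnorm2) @ ss) / total)
    return pd.Series(vip, index=model.predictor_ids, name="vip")


def choose_n_components(
    X: pd.DataFrame, y, max_components: int = 10, scale: bool = False
) -> int:
    """Pick the component count by leave-one-out CV with a 1-SE rule.

    The smallest component count whose mean squared prediction error is
    within one standard error of the minimum is returned; capped at
    ``max_components``.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = X.to_numpy(dtype=float)
    n, p = x.shape
    a_max = min(max_components, n - 2, p)
    if a_max < 1:
        return 1
    errors = np.zeros((a_max, n))
    for train, test in LeaveOneOut().split(x):
        for a in range(1, a_max + 1):
            sk = PLSRegression(n_components=a, scale=scale)
            sk.fit(x[train], y[train])
            pred = sk.predict(x[test]).ravel()
            errors[a - 1, test] = (pred - y[test]) ** 2
    mse = errors.mean(axis=1)
    se = errors.std(axis=1, ddof=1) / np.sqrt(n)
    best = int(np.argmin(mse))
    threshold = mse[best] + se[best]
    for a in range(a_max):
        if mse[a] <= threshold:
            return a + 1
    return best + 1


def keystone_ranking(
    centrality: pd.DataFrame,
    vip: pd.Series,
    module_labels: pd.Series | None = None,
    module_filter=None,
) -> pd.DataFrame:
    """Rank ASVs by the product of rank-normalised centrality and VIP.

    Both degree centrality and VIP are converted to ranks scaled to
    (0, 1] (largest value -> 1); the keystone score is their product.
    Ties are broken by ASV id. ``module_filter`` optionally restricts
    the ranking to ASVs of the listed modules.
    """
    shared = centrality.index.intersection(vip.index)
    if module_labels is not None and module_filter is not None:
        allowed = module_labels.index[module_labels.isin(list(module_filter))]
        shared = shared.intersection(allowed)
    if len(shared) == 0:
        raise ValueError("no ASVs shared between centrality and VIP tables")
    shared = sorted(shared)
    deg = centrality.loc[shared, "degree_centrality"].astype(float)
    v = vip.loc[shared].astype(float)
    n = len(shared)
    deg_rank = deg.rank(method="average") / n
    vip_rank = v.rank(method="average") / n
    score = deg_rank * vip_rank
    out = pd.DataFrame(
        {
            "degree_centrality": deg,
            "vip": v,
            "keystone_score": score,
        }
    )
    if module_labels is not None:
        out["module"] = module_labels.reindex(out.index)
    out = out.iloc[np.lexsort((out.index, -out["keystone_score"].to_numpy()))]
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
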