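"""ARIMA member on the seasonally adjusted series with exogenous regressors.

The predictor subset and the (p, d, q) orders are chosen jointly by a grid
search minimizing in-sample BIC, over all covariate subsets up to a size cap
(capped so the parameter count cannot balloon into overfitting).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.statespace.sarimax import SARIMAX

from ..fortnights import FortnightSeries
from ..preprocess import LaggedPredictorSet
from .base import MemberFit

DEFAULT_ORDER_GRID = tuple(
    (p, d, q) for p in range(3) for d in range(2) for q in range(3)
)


@dataclass
class ArimaFit(MemberFit):
    results: object = None  # SARIMAX results
    selected: tuple[str, ...] = ()

    def simulate_paths(self, horizon, n_paths, rng, future_X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = np.random.RandomState(int(rng.integers(2**31)))
            sims = self.results.simulate(
                nsimulations=horizon,
                repetitions=n_paths,
                anchor="end",
                exog=future_X,
                random_state=state,
            )
        return np.asarray(sims).reshape(horizon, n_paths).T


def _fit_one(y: np.ndarray, exog: np.ndarray | None, order) -> object | None:
    trend = "c" if order[1] == 0 else "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SARIMAX(y, exog=exog, order=order, trend=trend)
            res = model.fit(disp=False, maxiter=200)
        if not np.isfinite(res.bic):
            return None
        return res
    except Exception:
        return None


def fit_arima_seasadj(
    target: FortnightSeries,
    candidates: LaggedPredictorSet | None,
    max_predictors: int = 5,
    order_grid=DEFAULT_ORDER_GRID,
    train_end: int | None = None,
) -> ArimaFit:
    """Grid search over covariate subsets and ARIMA orders, minimizing BIC.

    ``candidates`` may be None (plain ARIMA).  Gaussian innovations.
    """
    train_end = (candidates.train_end if candidates is not None else len(target)) \
        if train_end is None else train_end
    y = np.asarray(target.values[:train_end], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    names = candidates.names if candidates is not None else []
    X = candidates.frame.iloc[:train_end].to_numpy() if names else None
    if X is not None and not np.all(np.isfinite(X)):
        raise ValueError("predictors contain non-finite values")

    best = None
    for size in range(0, min(max_predictors, len(names)) + 1):
        for subset in itertools.combinations(range(len(names)), size):
            exog = X[:, list(subset)] if subset else None
            for order in order_grid:
                res = _fit_one(y, exog, order)
                if res is None:
                    continue
                if best is None or res.bic < best[0]:
                    best = (res.bic, subset, order, res)
    if best is None:
        raise RuntimeError("no ARIMA candidate converged")

    bic, subset, order, res = best
    selected = tuple(names[i] for i in subset)
    predictors = None
    if candidates is not None and selected:
        predictors = LaggedPredictorSet(
            candidates.frame[list(selected)], candidates.meta.loc[list(selected)],
            candidates.train_end,
        )
    return ArimaFit(
        member_name="arima_seasadj",
        target_scale="seasonally_adjusted",
        origin=train_end - 1,
        params={name: float(val) for name, val in res.params.items()}
        if hasattr(res.params, "items")
        else {f"p{i}": float(v) for i, v in enumerate(res.params)},
        fit_metadata={"bic": float(bic), "order": order, "selected": selected,
                      "bse": np.asarray(res.bse, dtype=float).tolist()},
        residual_sd=float(np.std(res.resid[max(order[1], 1):], ddof=1)),
        predictors=predictors,
        results=res,
        selected=selected,
    )
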