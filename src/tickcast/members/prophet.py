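"""Prophet-style decomposable trend regression on log(x+1) admissions.

The model is linear in its parameters: a piecewise-linear trend whose slope
changes at a grid of candidate changepoints (sparse Laplace prior on the
slope changes, scale 0.50 by default to allow a flexible nonlinear trend),
Fourier-basis yearly seasonality (period 24 fortnights) and additive linear
regressor terms, with Gaussian observation error.  The regressors entering
the model are the few candidates that individually minimize model deviance.

Estimation is MAP (the Laplace prior makes this a lasso-type convex problem,
solved with a smoothed absolute value); forecast uncertainty combines the
Gaussian-approximate posterior of the non-sparse coefficients, observation
noise and simulated future changepoints whose magnitude matches the fitted
historical slope-change scale — mirroring how the original Prophet model
propagates trend uncertainty.  Forecast paths are back-transformed with
exp(x) - 1 and floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..fortnights import FORTNIGHTS_PER_YEAR, FortnightSeries
from ..preprocess import LaggedPredictorSet
from .base import MemberFit


def _fourier(positions: np.ndarray, order: int, start_fortnight: int = 1) -> np.ndarray:
    phase = (start_fortnight - 1 + positions) / FORTNIGHTS_PER_YEAR
    cols = []
    for i in range(1, order + 1):
        cols.append(np.sin(2 * np.pi * i * phase))
        cols.append(np.cos(2 * np.pi * i * phase))
    return np.column_stack(cols)


def _hinges(t: np.ndarray, changepoints: np.ndarray) -> np.ndarray:
    return np.clip(t[:, None] - changepoints[None, :], 0.0, None)


@dataclass
class ProphetFit(MemberFit):
    beta: np.ndarray = None  # [k, m, deltas..., seasonal..., regressors...]
    cov_dense: np.ndarray = None  # Gaussian posterior cov of non-delta coefs
    dense_idx: np.ndarray = None
    changepoints: np.ndarray = None  # on the normalized time scale
    t_scale: float = 1.0
    sigma: float = float("nan")
    fourier_order: int = 10
    start_fortnight: int = 1
    delta_scale: float = 0.0  # fitted historical slope-change magnitude

    def _design(self, positions: np.ndarray, future_X: np.ndarray | None) -> np.ndarray:
        t = positions / self.t_scale
        blocks = [np.ones((len(t), 1)), t[:, None], _hinges(t, self.changepoints),
                  _fourier(positions, self.fourier_order, self.start_fortnight)]
        if future_X is not None and future_X.size:
            blocks.append(future_X)
        return np.hstack(blocks)

    def simulate_paths(self, horizon, n_paths, rng, future_X):
        positions = self.origin + 1 + np.arange(horizon)
        Xf = self._design(positions, future_X)
        betas = np.tile(self.beta, (n_paths, 1))
        if len(self.dense_idx):
            L = np.linalg.cholesky(self.cov_dense + 1e-12 * np.eye(len(self.dense_idx)))
            betas[:, self.dense_idx] += rng.standard_normal(
                (n_paths, len(self.dense_idx))) @ L.T
        yhat = betas @ Xf.T

        # future changepoints: potential slope changes past the training window,
        # Laplace-distributed with the fitted historical magnitude
        t_future = positions / self.t_scale
        t_origin = self.origin / self.t_scale
        cp_rate = len(self.changepoints) / max(t_origin, 1e-9)
        if self.delta_scale > 0 and cp_rate > 0:
            mask = rng.random((n_paths, horizon)) < cp_rate * np.diff(
                np.concatenate([[t_origin], t_future]))
            deltas = rng.laplace(0.0, self.delta_scale, size=(n_paths, horizon)) * mask
            # hinge effect of a slope change at step h on every later step k
            M = np.clip(t_future[None, :] - t_future[:, None], 0.0, None)
            yhat = yhat + deltas @ M
        yhat = yhat + rng.normal(0.0, self.sigma, size=yhat.shape)
        return yhat


def _map_fit(X, y, laplace_idx, laplace_scale, gauss_prior_sd, sigma, smooth_eps=1e-8):
    k = X.shape[1]
    prior_sd = np.asarray(gauss_prior_sd, dtype=float)

    def objective(beta):
        resid = y - X @ beta
        nll = 0.5 * np.sum(resid**2) / sigma**2
        pen_l = np.sum(np.sqrt(beta[laplace_idx] ** 2 + smooth_eps)) / laplace_scale
        gauss = np.ones(k, dtype=bool)
        gauss[laplace_idx] = False
        pen_g = 0.5 * np.sum((beta[gauss] / prior_sd[gauss]) ** 2)
        return nll + pen_l + pen_g

    def grad(beta):
        resid = y - X @ beta
        g = -(X.T @ resid) / sigma**2
        gl = np.zeros(k)
        gl[laplace_idx] = beta[laplace_idx] / np.sqrt(
            beta[laplace_idx] ** 2 + smooth_eps) / laplace_scale
        gauss = np.ones(k, dtype=bool)
        gauss[laplace_idx] = False
        gg = np.zeros(k)
        gg[gauss] = beta[gauss] / prior_sd[gauss] ** 2
        return g + gl + gg

    res = optimize.minimize(objective, np.zeros(k), jac=grad, method="L-BFGS-B",
                            options={"maxiter": 2000})
    return res.x


def rank_predictors_by_deviance(
    y_log1p: np.ndarray,
    candidates: LaggedPredictorSet,
    positions: np.ndarray,
    start_fortnight: int = 1,
    fourier_order: int = 10,
) -> list[tuple[str, float]]:
    """Gaussian deviance of a trend+seasonality model with each single regressor."""
    t = positions / max(positions[-1], 1.0)
    base = np.column_stack([np.ones_like(t), t,
                            _fourier(positions, fourier_order, start_fortnight)])
    out = []
    for name in candidates.names:
        x = candidates.frame[name].to_numpy()[positions]
        X = np.column_stack([base, x])
        beta, *_ = np.linalg.lstsq(X, y_log1p, rcond=None)
        rss = float(np.sum((y_log1p - X @ beta) ** 2))
        out.append((name, len(y_log1p) * np.log(rss / len(y_log1p))))
    return sorted(out, key=lambda kv: kv[1])


def fit_prophet_raw(
    counts: FortnightSeries,
    predictors: LaggedPredictorSet | None,
    n_predictors: int = 3,
    changepoint_scale: float = 0.50,
    n_changepoints: int = 25,
    fourier_order: int = 10,
    train_end: int | None = None,
) -> ProphetFit:
    """Fit the decomposable trend regression to log(counts + 1)."""
    if np.any(counts.values < 0):
        raise ValueError("counts must be nonnegative")
    train_end = (predictors.train_end if predictors is not None else len(counts)) \
        if train_end is None else train_end
    y = np.log1p(np.asarray(counts.values[:train_end], dtype=float))
    n = len(y)
    positions = np.arange(n)

    selected: list[str] = []
    if predictors is not None and predictors.names:
        ranking = rank_predictors_by_deviance(
            y, predictors, positions, counts.start_fortnight, fourier_order)
        if len(ranking) < n_predictors:
            warnings.warn("fewer candidate predictors than requested; using all")
        selected = [name for name, _ in ranking[:n_predictors]]

    sub = None
    if selected:
        sub = LaggedPredictorSet(
            predictors.frame[selected], predictors.meta.loc[selected], predictors.train_end
        )

    t_scale = float(max(n - 1, 1))
    changepoints = np.linspace(0.0, 0.8, n_changepoints + 2)[1:-1]
    X_reg = sub.frame.iloc[:train_end].to_numpy() if sub is not None else None

    fit = ProphetFit(
        member_name="prophet_raw", target_scale="log1p_count", origin=train_end - 1,
        changepoints=changepoints, t_scale=t_scale, fourier_order=fourier_order,
        start_fortnight=counts.start_fortnight, predictors=sub,
    )
    X = fit._design(positions, X_reg)
    k = X.shape[1]
    n_cp = len(changepoints)
    laplace_idx = np.arange(2, 2 + n_cp)
    prior_sd = np.full(k, 10.0)
    prior_sd[:2] = 5.0

    sigma = max(np.std(y, ddof=1), 1e-3)
    beta = None
    for _ in range(3):  # alternate MAP fit and noise-scale update
        beta = _map_fit(X, y, laplace_idx, changepoint_scale, prior_sd, sigma)
        resid = y - X @ beta
        sigma = max(float(np.std(resid, ddof=1)), 1e-6)

    dense = np.ones(k, dtype=bool)
    dense[laplace_idx] = False
    dense_idx = np.flatnonzero(dense)
    Xd = X[:, dense_idx]
    H = Xd.T @ Xd / sigma**2 + np.diag(1.0 / prior_sd[dense_idx] ** 2)
    cov_dense = np.linalg.inv(H)

    deltas = beta[laplace_idx]
    fit.beta = beta
    fit.cov_dense = cov_dense
    fit.dense_idx = dense_idx
    fit.sigma = sigma
    fit.delta_scale = float(np.mean(np.abs(deltas)))
    fit.residual_sd = sigma
    fit.params = {"k": float(beta[0]), "m": float(beta[1]), "sigma": sigma,
                  "regressors": {nm: float(b) for nm, b in
                                 zip(selected, beta[k - len(selected):])} if selected else {}}
    fit.fit_metadata = {"selected": selected, "n_changepoints": n_cp,
                        "max_abs_delta": float(np.max(np.abs(deltas))) if n_cp else 0.0}
    return fit
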