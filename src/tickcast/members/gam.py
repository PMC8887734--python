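"""Negative-binomial generalized additive member on raw admission counts.

log mu_t is an additive combination of an unpenalized cubic-spline trend in
(continuous) year, a cyclic cubic seasonal smooth of fortnight-of-year
(period 24, endpoints matched) and one shrinkage smooth per environmental
predictor.  Predictor smooths carry a ridge ("shrinkage") penalty that can
drive a term's effective degrees of freedom to ~0 when the data give it no
support — automatic variable selection.  Smoothing strengths are chosen by
generalized cross-validation; the overdispersion phi (variance mu + mu^2/phi,
NB success probability phi/(phi+mu)) is profiled by maximum likelihood.

Estimation is penalized iteratively reweighted least squares (Fisher scoring
for the log link), written directly on the design/penalty matrices.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special

from ..fortnights import FORTNIGHTS_PER_YEAR, FortnightSeries
from ..preprocess import LaggedPredictorSet
from .base import MemberFit


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.clip(mu, 1e-10, None)
    return float(
        np.sum(
            special.gammaln(y + phi) - special.gammaln(phi) - special.gammaln(y + 1)
            + phi * np.log(phi / (phi + mu)) + y * np.log(mu / (phi + mu))
        )
    )


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.clip(mu, 1e-10, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + phi) * np.log((y + phi) / (mu + phi))))


def _second_diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


def _pirls(X, y, S, phi, max_iter=50, tol=1e-8):
    mu = y + 0.5
    eta = np.log(mu)
    beta = None
    for _ in range(max_iter):
        w = mu * phi / (phi + mu)  # Fisher weights for log link, NB variance
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A, b = XtW @ X + S, XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        eta_new = np.clip(X @ beta_new, -30.0, 30.0)
        if beta is not None and np.max(np.abs(eta_new - eta)) < tol:
            beta, eta = beta_new, eta_new
            break
        beta, eta = beta_new, eta_new
        mu = np.exp(eta)
    mu = np.exp(eta)
    w = mu * phi / (phi + mu)
    XtWX = (X.T * w) @ X
    H_inv = np.linalg.inv(XtWX + S)
    edf_per_coef = np.diag(H_inv @ XtWX)
    return beta, mu, H_inv, edf_per_coef


@dataclass
class GamFit(MemberFit):
    design_info: object = None
    beta: np.ndarray = None
    cov: np.ndarray = None
    phi: float = float("nan")
    term_slices: dict = field(default_factory=dict)
    edf: dict = field(default_factory=dict)
    start_fortnight: int = 1

    def _future_frame(self, horizon: int, future_X: np.ndarray | None) -> pd.DataFrame:
        pos = self.origin + 1 + np.arange(horizon)
        data = {
            "t_year": pos / FORTNIGHTS_PER_YEAR,
            "fn": (self.start_fortnight - 1 + pos) % FORTNIGHTS_PER_YEAR + 1.0,
        }
        names = self.predictors.names if self.predictors is not None else []
        for j, name in enumerate(names):
            data[name] = future_X[:, j]
        return pd.DataFrame(data)

    def predict_mu(self, horizon: int, future_X: np.ndarray | None,
                   beta: np.ndarray | None = None) -> np.ndarray:
        new = self._future_frame(horizon, future_X)
        (Xf,) = patsy.build_design_matrices([self.design_info], new)
        b = self.beta if beta is None else beta
        return np.exp(np.clip(np.asarray(Xf) @ b, -30, 30))

    def simulate_paths(self, horizon, n_paths, rng, future_X):
        new = self._future_frame(horizon, future_X)
        (Xf,) = patsy.build_design_matrices([self.design_info], new)
        Xf = np.asarray(Xf)
        C = 0.5 * (self.cov + self.cov.T)
        evals, evecs = np.linalg.eigh(C)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
        betas = self.beta + rng.standard_normal((n_paths, len(self.beta))) @ L.T
        mu = np.exp(np.clip(betas @ Xf.T, -30, 30))
        return rng.negative_binomial(self.phi, self.phi / (self.phi + mu)).astype(float)


def _profile_phi(y, mu):
    res = optimize.minimize_scalar(
        lambda lp: -_nb_loglik(y, mu, np.exp(lp)), bounds=(-4.0, 12.0), method="bounded"
    )
    return float(np.exp(res.x))


def fit_gam_raw(
    counts: FortnightSeries,
    predictors: LaggedPredictorSet | None,
    df_trend: int = 6,
    df_season: int = 8,
    df_predictor: int = 5,
    lambda_grid: np.ndarray | None = None,
    gcv_gamma: float = 1.4,
    train_end: int | None = None,
) -> GamFit:
    """Fit the NB GAM by penalized IRLS with GCV-selected smoothing.

    GCV criterion: n * deviance / (n - gamma * edf)^2, minimized by coordinate
    descent over a log-spaced grid for the seasonal wiggliness penalty and
    each predictor's shrinkage ridge; the edf-inflation factor gamma (default
    1.4, the usual guard against GCV undersmoothing) makes weakly supported
    predictor smooths collapse toward zero effective degrees of freedom.
    phi is profiled by maximum likelihood.
    """
    train_end = (predictors.train_end if predictors is not None else len(counts)) \
        if train_end is None else train_end
    y = np.asarray(counts.values[:train_end], dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero counts: nothing to fit")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    n = len(y)
    names = predictors.names if predictors is not None else []

    data = {
        "t_year": np.arange(n) / FORTNIGHTS_PER_YEAR,
        "fn": counts.fortnights[:train_end].astype(float),
    }
    for name in names:
        data[name] = predictors.frame[name].to_numpy()[:train_end]
    # cyclic bounds [1, 25): fortnight 25 is identified with fortnight 1
    formula = (
        f"cr(t_year, df={df_trend})"
        f" + cc(fn, df={df_season}, lower_bound=1, upper_bound={FORTNIGHTS_PER_YEAR + 1})"
    )
    formula += "".join(f" + cr({name}, df={df_predictor})" for name in names)
    design = patsy.dmatrix(formula, data, return_type="matrix")
    X = np.asarray(design)
    design_info = design.design_info

    slices = dict(design_info.term_name_slices)
    k = X.shape[1]

    # penalty per penalized block: wiggliness for the season, ridge for
    # predictors; each penalty is rescaled to the magnitude of its design
    # block so the lambda grid is comparable across terms and the penalized
    # system stays well conditioned
    pen_blocks: dict[str, np.ndarray] = {}
    for term, sl in slices.items():
        width = sl.stop - sl.start
        block_scale = float(np.mean(np.sum(X[:, sl] ** 2, axis=0)))
        if term.startswith("cc("):
            P = np.zeros((k, k))
            raw = _second_diff_penalty(width)
            P[sl, sl] = raw * (block_scale / max(np.abs(raw).max(), 1e-12))
            pen_blocks[term] = P
        elif term.startswith("cr(") and "t_year" not in term:
            P = np.zeros((k, k))
            P[sl, sl] = np.eye(width) * block_scale
            pen_blocks[term] = P

    if lambda_grid is None:
        lambda_grid = 10.0 ** np.arange(-3.0, 6.5, 1.0)
    lambdas = {term: 1.0 for term in pen_blocks}

    def assemble_S():
        S = 1e-8 * np.eye(k)
        for term, P in pen_blocks.items():
            S = S + lambdas[term] * P
        return S

    phi = _profile_phi(y, np.full(n, max(y.mean(), 0.1)))

    def gcv(S):
        beta, mu, _, edf_pc = _pirls(X, y, S, phi)
        edf = edf_pc.sum()
        return n * _nb_deviance(y, mu, phi) / max(n - gcv_gamma * edf, 1.0) ** 2

    for _outer in range(2):
        for _pass in range(2):
            for term in pen_blocks:
                best_lam, best_score = lambdas[term], np.inf
                for lam in lambda_grid:
                    lambdas[term] = lam
                    score = gcv(assemble_S())
                    if score < best_score:
                        best_score, best_lam = score, lam
                lambdas[term] = best_lam
        S = assemble_S()
        beta, mu, H_inv, edf_pc = _pirls(X, y, S, phi)
        phi = _profile_phi(y, mu)

    S = assemble_S()
    beta, mu, H_inv, edf_pc = _pirls(X, y, S, phi)
    edf = {term: float(edf_pc[sl].sum()) for term, sl in slices.items()}

    return GamFit(
        member_name="gam_raw",
        target_scale="raw_count",
        origin=train_end - 1,
        params={"phi": phi, "lambdas": dict(lambdas)},
        fit_metadata={"edf": edf, "deviance": _nb_deviance(y, mu, phi),
                      "loglik": _nb_loglik(y, mu, phi)},
        residual_sd=float(np.std(y - mu, ddof=1)),
        predictors=predictors if names else None,
        design_info=design_info,
        beta=beta,
        cov=H_inv,
        phi=phi,
        term_slices={t: (s.start, s.stop) for t, s in slices.items()},
        edf=edf,
        start_fortnight=counts.start_fortnight,
    )
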