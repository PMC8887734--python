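"""Interval scoring and convex ensemble weighting.

The ensemble combines member forecasts by weighted quantile averaging; the
weights minimize the mean interval score of the combined 95% interval over a
validation window.  The interval score of an interval [L, U] at observation Y
is (U - L) + c (L - Y) 1[Y < L] + c (Y - U) 1[Y > U].  The standard
(Gneiting-Raftery) penalty uses c = 2/alpha; a variant with c = 2*alpha is
selectable (``penalty_convention``) because both readings appear in applied
work.  No scaling denominator is applied by default; optional scaling by the
in-sample seasonal-naive absolute error turns the mean score into a scaled
(MASE-like) score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .members.base import ForecastDistribution


@dataclass
class PredictionInterval:
    lower: float | np.ndarray
    upper: float | np.ndarray
    level: float = 0.95

    def __post_init__(self):
        if np.any(np.asarray(self.lower) > np.asarray(self.upper)):
            raise ValueError("interval lower bound exceeds upper bound")


@dataclass
class ScoreConfig:
    alpha: float = 0.05
    penalty_convention: str = "two_over_alpha"  # or "two_times_alpha"
    scale_denominator: float | None = None  # e.g. seasonal-naive MAE; off by default

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.penalty_convention not in ("two_over_alpha", "two_times_alpha"):
            raise ValueError(f"unknown penalty convention {self.penalty_convention!r}")

    @property
    def penalty(self) -> float:
        return 2.0 / self.alpha if self.penalty_convention == "two_over_alpha" else 2.0 * self.alpha


def interval_score(interval: PredictionInterval, y, cfg: ScoreConfig | None = None):
    """Penalized interval width; lower is better.  Vectorizes over horizons."""
    cfg = cfg or ScoreConfig()
    L = np.asarray(interval.lower, dtype=float)
    U = np.asarray(interval.upper, dtype=float)
    y = np.asarray(y, dtype=float)
    c = cfg.penalty
    score = (U - L) + c * (L - y) * (y < L) + c * (y - U) * (y > U)
    if cfg.scale_denominator:
        score = score / cfg.scale_denominator
    return score if score.ndim else float(score)


@dataclass
class EnsembleWeights:
    names: tuple[str, ...]
    weights: np.ndarray
    validation_score: float = float("nan")

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.names):
            raise ValueError("one weight per member required")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        self.weights = np.clip(self.weights, 0.0, None)
        self.weights = self.weights / self.weights.sum()

    def as_dict(self) -> dict[str, float]:
        return {n: float(w) for n, w in zip(self.names, self.weights)}


def weighted_interval(
    member_intervals: Sequence[PredictionInterval], weights: EnsembleWeights | np.ndarray
) -> PredictionInterval:
    """Quantile averaging: L = sum w_i L_i, U = sum w_i U_i."""
    w = weights.weights if isinstance(weights, EnsembleWeights) else np.asarray(weights, float)
    if len(member_intervals) != len(w):
        raise ValueError("weight / member count mismatch")
    levels = {iv.level for iv in member_intervals}
    if len(levels) != 1:
        raise ValueError("member intervals must share the nominal level")
    L = sum(wi * np.asarray(iv.lower, float) for wi, iv in zip(w, member_intervals))
    U = sum(wi * np.asarray(iv.upper, float) for wi, iv in zip(w, member_intervals))
    return PredictionInterval(L, U, level=levels.pop())


def _stack_validation(member_forecasts, observations, level):
    """Align member intervals with observations into (M, K) arrays over all
    validation (origin, horizon) pairs."""
    names = tuple(member_forecasts)
    Ls, Us = [], []
    for name in names:
        fcs = member_forecasts[name]
        fcs = fcs if isinstance(fcs, (list, tuple)) else [fcs]
        l_parts, u_parts = [], []
        for fc in fcs:
            lo, up = fc.interval(level)
            l_parts.append(lo)
            u_parts.append(up)
        Ls.append(np.concatenate(l_parts))
        Us.append(np.concatenate(u_parts))
    L = np.vstack(Ls)
    U = np.vstack(Us)
    y = np.asarray(observations, dtype=float).ravel()
    if L.shape[1] != len(y):
        raise ValueError("observations do not match the validation forecast pairs")
    return names, L, U, y


def mean_weighted_score(w: np.ndarray, L: np.ndarray, U: np.ndarray, y: np.ndarray,
                        cfg: ScoreConfig) -> float:
    Lw = w @ L
    Uw = w @ U
    c = cfg.penalty
    s = (Uw - Lw) + c * (Lw - y) * (y < Lw) + c * (y - Uw) * (y > Uw)
    if cfg.scale_denominator:
        s = s / cfg.scale_denominator
    return float(s.mean())


def optimize_weights(
    member_forecasts: dict[str, ForecastDistribution | list],
    observations,
    cfg: ScoreConfig | None = None,
    n_restarts: int = 25,
    seed: int = 0,
    level: float = 0.95,
) -> EnsembleWeights:
    """Minimize the mean interval score of the weighted 95% interval over the
    validation window, subject to the simplex constraint.

    The simplex is handled by an unconstrained softmax reparameterization with
    multi-start gradient optimization; every simplex corner (single-member
    ensemble) is also evaluated so the result can never lose to the best
    single member by more than optimizer tolerance.
    """
    cfg = cfg or ScoreConfig()
    names, L, U, y = _stack_validation(member_forecasts, observations, level)
    m = len(names)
    if m < 2:
        raise ValueError("need at least two members")
    if L.shape[1] == 0:
        raise ValueError("validation window is empty")

    def softmax(z):
        e = np.exp(z - z.max())
        return e / e.sum()

    def objective(z):
        return mean_weighted_score(softmax(z), L, U, y, cfg)

    rng = np.random.default_rng(seed)
    best_w, best_s = None, np.inf
    # corners first: single-member candidates are always feasible
    for i in range(m):
        w = np.eye(m)[i]
        s = mean_weighted_score(w, L, U, y, cfg)
        if s < best_s:
            best_w, best_s = w, s
    starts = [np.zeros(m)] + [rng.normal(0.0, 2.0, size=m) for _ in range(n_restarts - 1)]
    n_converged = 0
    for z0 in starts:
        res = optimize.minimize(objective, z0, method="Nelder-Mead",
                                options={"maxiter": 3000, "xatol": 1e-10, "fatol": 1e-12})
        if np.isfinite(res.fun):
            n_converged += 1
            if res.fun < best_s:
                best_w, best_s = softmax(res.x), float(res.fun)
    if n_converged == 0:
        raise RuntimeError("weight optimization failed to converge from any start")
    # snap numerically-zero weights
    w = np.where(best_w < 1e-6, 0.0, best_w)
    w = w / w.sum()
    s = mean_weighted_score(w, L, U, y, cfg)
    if s <= best_s + 1e-12:
        best_w, best_s = w, s
    return EnsembleWeights(names, best_w, validation_score=best_s)


def grid_search_weights(
    member_forecasts: dict, observations, cfg: ScoreConfig | None = None,
    step: float = 0.01, level: float = 0.95,
) -> EnsembleWeights:
    """Exhaustive simplex grid search (oracle; feasible for <= 3 members)."""
    cfg = cfg or ScoreConfig()
    names, L, U, y = _stack_validation(member_forecasts, observations, level)
    m = len(names)
    if m > 3:
        raise ValueError("grid search oracle supports at most 3 members")
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    best_w, best_s = None, np.inf
    for w1 in ticks:
        if m == 2:
            w = np.array([w1, 1.0 - w1])
            s = mean_weighted_score(w, L, U, y, cfg)
            if s < best_s:
                best_w, best_s = w, s
            continue
        for w2 in ticks[ticks <= 1.0 - w1 + 1e-12]:
            w = np.array([w1, w2, 1.0 - w1 - w2])
            s = mean_weighted_score(w, L, U, y, cfg)
            if s < best_s:
                best_w, best_s = w, s
    return EnsembleWeights(names, best_w, validation_score=best_s)


def combine(
    member_forecasts: dict[str, ForecastDistribution], weights: EnsembleWeights,
    truncate_at_zero: bool = True,
) -> "CombinedForecast":
    """Weighted quantile averaging of member forecasts at all reported levels."""
    fcs = [member_forecasts[name] for name in weights.names]
    horizons = {fc.horizon for fc in fcs}
    origins = {fc.origin for fc in fcs}
    if len(horizons) != 1 or len(origins) != 1:
        raise ValueError("member forecasts must share origin and horizons")
    w = weights.weights
    floor = (lambda a: np.clip(a, 0.0, None)) if truncate_at_zero else (lambda a: a)

    def avg(q):
        return floor(sum(wi * fc.quantile(q) for wi, fc in zip(w, fcs)))

    return CombinedForecast(
        origin=origins.pop(),
        median=avg(0.5),
        lower_80=avg(0.10), upper_80=avg(0.90),
        lower_95=avg(0.025), upper_95=avg(0.975),
    )


@dataclass
class CombinedForecast:
    """Quantile summaries of the weighted ensemble at each horizon."""

    origin: int
    median: np.ndarray
    lower_80: np.ndarray
    upper_80: np.ndarray
    lower_95: np.ndarray
    upper_95: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.median)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        if abs(level - 0.95) < 1e-9:
            return self.lower_95, self.upper_95
        if abs(level - 0.80) < 1e-9:
            return self.lower_80, self.upper_80
        raise ValueError("combined forecasts carry 80% and 95% intervals only")

    def quantile(self, q: float) -> np.ndarray:
        table = {0.5: self.median, 0.10: self.lower_80, 0.90: self.upper_80,
                 0.025: self.lower_95, 0.975: self.upper_95}
        for key, val in table.items():
            if abs(q - key) < 1e-9:
                return val
        raise ValueError("combined forecasts carry fixed quantiles only")
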