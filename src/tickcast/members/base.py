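"""Shared forecast representation for all ensemble members.

Every member — likelihood-based or Bayesian — emits its forecast as a set of
sample trajectories, so the ensemble combiner and the particle filter operate
on one common type regardless of how a member was estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class ForecastDistribution:
    """Per-horizon sample paths from a fitted model.

    ``paths`` has shape (S, H): S sample trajectories over horizons 1..H
    fortnights beyond ``origin`` (the 0-based position of the last training
    observation on the fortnight grid).  Summaries (median, 80% and 95%
    central intervals) are derived from path quantiles.
    """

    origin: int
    paths: np.ndarray

    def __post_init__(self):
        self.paths = np.atleast_2d(np.asarray(self.paths, dtype=float))
        if self.paths.shape[0] < 1:
            raise ValueError("need at least one sample path")

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    @property
    def horizon(self) -> int:
        return self.paths.shape[1]

    @property
    def horizons(self) -> np.ndarray:
        return np.arange(1, self.horizon + 1)

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.paths, q, axis=0)

    @property
    def median(self) -> np.ndarray:
        return self.quantile(0.5)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Central interval endpoints (L, U) per horizon."""
        alpha = 1.0 - level
        return self.quantile(alpha / 2.0), self.quantile(1.0 - alpha / 2.0)

    def truncated(self, lower: float = 0.0) -> "ForecastDistribution":
        """Pathwise floor (counts cannot be negative)."""
        return ForecastDistribution(self.origin, np.clip(self.paths, lower, None))

    def head(self, horizon: int) -> "ForecastDistribution":
        if not 1 <= horizon <= self.horizon:
            raise ValueError("horizon out of range")
        return ForecastDistribution(self.origin, self.paths[:, :horizon])

    def summary(self):
        import pandas as pd

        l95, u95 = self.interval(0.95)
        l80, u80 = self.interval(0.80)
        return pd.DataFrame(
            {
                "horizon": self.horizons,
                "median": self.median,
                "lower_80": l80,
                "upper_80": u80,
                "lower_95": l95,
                "upper_95": u95,
            }
        )


@dataclass
class MemberFit:
    """A fitted ensemble member with everything needed to simulate forecasts.

    ``target_scale`` records the space the member models (Fig.-2-style
    mapping): the seasonally adjusted series for the ARIMA/GARCH members, raw
    counts for the GAM, log1p counts for the Prophet-style member and the ETS
    benchmark, or the raw STL seasonal component for the seasonal ETS.
    """

    member_name: str
    target_scale: str  # seasonally_adjusted | raw_count | log1p_count | seasonal_component
    origin: int  # position of the last training observation
    params: dict = field(default_factory=dict)
    fit_metadata: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    predictors: Any = None  # LaggedPredictorSet or None

    def simulate_paths(self, horizon: int, n_paths: int, rng: np.random.Generator,
                       future_X: np.ndarray | None) -> np.ndarray:
        raise NotImplementedError


def forecast(
    fit: MemberFit,
    horizon_fortnights: int,
    n_paths: int = 1000,
    seed: int | None = None,
    persistence: bool = True,
) -> ForecastDistribution:
    """Simulate ``n_paths`` trajectories over 1..H fortnights past the origin.

    Members with regressors need covariate values at forecast time; those are
    available from observed data for steps within each predictor's lag, and
    carried forward (or refused, with ``persistence=False``) beyond that.
    Output stays on the member's own target scale; use
    :func:`to_outcome_scale` / :func:`back_transform_counts` to reach counts.
    """
    if horizon_fortnights < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    future_X = None
    if fit.predictors is not None and len(fit.predictors.names) > 0:
        future_X = fit.predictors.future_rows(fit.origin, horizon_fortnights, persistence)
    paths = fit.simulate_paths(horizon_fortnights, n_paths, rng, future_X)
    return ForecastDistribution(fit.origin, paths)


def to_outcome_scale(
    seasadj_forecast: ForecastDistribution, seasonal_forecast: ForecastDistribution
) -> ForecastDistribution:
    """Restore seasonality: pathwise sum of a seasonally adjusted member's
    paths and the seasonal ETS forecast's paths, floored at zero counts.

    Paths are paired by index (independent uncertainty sources); the seasonal
    forecast's paths are recycled if counts differ.
    """
    if seasadj_forecast.origin != seasonal_forecast.origin:
        raise ValueError("forecasts must share the same origin")
    if seasadj_forecast.horizon != seasonal_forecast.horizon:
        raise ValueError("forecast horizons do not match")
    s = seasonal_forecast.paths
    if s.shape[0] != seasadj_forecast.n_paths:
        idx = np.arange(seasadj_forecast.n_paths) % s.shape[0]
        s = s[idx]
    return ForecastDistribution(seasadj_forecast.origin, seasadj_forecast.paths + s).truncated()


def back_transform_counts(forecast_log1p: ForecastDistribution) -> ForecastDistribution:
    """Map log(x+1)-scale paths back to the count scale, floored at zero."""
    return ForecastDistribution(forecast_log1p.origin, np.expm1(forecast_log1p.paths)).truncated()
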