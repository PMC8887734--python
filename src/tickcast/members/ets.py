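"""Exponential smoothing (ETS) state-space models.

Two roles: (i) the benchmark forecaster, trained on log(x+1) admission counts
and back-transformed to the count scale; (ii) the seasonal-component
forecaster whose forecasts restore seasonality to the seasonally adjusted
members.  Error/trend/seasonal components are chosen automatically by
information criterion among additive candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.exponential_smoothing.ets import ETSModel

from ..fortnights import FORTNIGHTS_PER_YEAR, FortnightSeries
from .base import MemberFit

TARGET_SCALES = ("log1p_count", "seasonal_component", "seasonally_adjusted", "raw")


@dataclass
class EtsFit(MemberFit):
    results: object = None

    def simulate_paths(self, horizon, n_paths, rng, future_X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = np.random.RandomState(int(rng.integers(2**31)))
            sims = self.results.simulate(
                nsimulations=horizon, repetitions=n_paths, anchor="end", random_state=state
            )
        return np.asarray(sims).reshape(horizon, n_paths).T


def fit_ets(
    series: FortnightSeries,
    target_scale: str = "log1p_count",
    seasonal_periods: int = FORTNIGHTS_PER_YEAR,
    train_end: int | None = None,
) -> EtsFit:
    """Automatic-component additive ETS fit, selected by AICc.

    ``target_scale='log1p_count'`` applies the log(x+1) transform to the input
    (benchmark use); other scales are modelled as given.
    """
    if target_scale not in TARGET_SCALES:
        raise ValueError(f"unknown target_scale {target_scale!r}")
    train_end = len(series) if train_end is None else train_end
    y = np.asarray(series.values[:train_end], dtype=float)
    if len(y) < 3 * seasonal_periods:
        raise ValueError("ETS needs at least three full seasonal cycles")
    if target_scale == "log1p_count":
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        y = np.log1p(y)

    candidates = []
    for trend in (None, "add"):
        for damped in ((False,) if trend is None else (False, True)):
            for seasonal in (None, "add"):
                candidates.append((trend, damped, seasonal))

    best = None
    for trend, damped, seasonal in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ETSModel(
                    y, error="add", trend=trend, damped_trend=damped,
                    seasonal=seasonal,
                    seasonal_periods=seasonal_periods if seasonal else None,
                )
                res = model.fit(disp=False)
            aicc = res.aicc
            if np.isfinite(aicc) and (best is None or aicc < best[0]):
                best = (aicc, (trend, damped, seasonal), res)
        except Exception:
            continue
    if best is None:
        raise RuntimeError("no ETS candidate converged")
    aicc, spec, res = best
    name = "ets_seasonal" if target_scale == "seasonal_component" else "ets_benchmark"
    return EtsFit(
        member_name=name,
        target_scale=target_scale,
        origin=train_end - 1,
        params={k: float(v) for k, v in res.params.items()}
        if hasattr(res.params, "items") else {},
        fit_metadata={"aicc": float(aicc), "trend": spec[0], "damped": spec[1],
                      "seasonal": spec[2]},
        residual_sd=float(np.std(res.resid, ddof=1)),
        results=res,
    )
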