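"""Rolling-origin evaluation of benchmark, re-trained ensemble and
particle-filtered ensemble forecasts.

At every origin the models see only data up to that origin: the STL
decomposition, anomaly climatology, collinearity pruning, lag selection and
predictor scaling are all recomputed on the training window, so no
information can leak backward from the evaluation period.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fortnights import FORTNIGHTS_PER_YEAR, FortnightSeries
from . import members as mb
from . import preprocess as pp
from .ensemble import (
    CombinedForecast,
    EnsembleWeights,
    PredictionInterval,
    ScoreConfig,
    combine,
    interval_score,
    optimize_weights,
)
from .particle_filter import FilterConfig, init_particles, pf_forecast, run_filter


def train_test_split(series: FortnightSeries, train_fraction: float = 0.85):
    """Split into training / weight-optimization validation / test windows.

    Training size is ceil(train_fraction * T).  The held-out remainder is
    split so the final full season (up to 24 fortnights) forms the test
    window and the earlier held-out fortnights form the validation window
    used to optimize ensemble weights.
    """
    T = len(series)
    if T < 2 * FORTNIGHTS_PER_YEAR:
        raise ValueError("series must span at least two seasonal cycles")
    n_train = math.ceil(train_fraction * T)
    holdout = T - n_train
    if holdout < 2:
        raise ValueError("train_fraction leaves no held-out data")
    if holdout > FORTNIGHTS_PER_YEAR:
        n_val = holdout - FORTNIGHTS_PER_YEAR
    else:
        n_val = math.ceil(holdout / 2)
    train = series.slice(0, n_train)
    validation = series.slice(n_train, n_train + n_val)
    test = series.slice(n_train + n_val, T)
    return train, validation, test


def point_errors(forecast, observed: np.ndarray) -> dict:
    """Absolute error of the forecast median per horizon, with median/IQR summary."""
    observed = np.asarray(observed, dtype=float)
    median = np.asarray(forecast.median, dtype=float)
    k = min(len(median), len(observed))
    if k == 0:
        raise ValueError("no overlap between forecast horizons and observations")
    err = np.abs(median[:k] - observed[:k])
    q25, q50, q75 = np.percentile(err, [25, 50, 75])
    return {"errors": err, "median": float(q50), "iqr": (float(q25), float(q75))}


@dataclass
class EvaluationWindowPlan:
    """Rolling origins (training sizes) and the two horizon bands.

    Horizon bands share the boundary fortnight (2-12 and 12-24 weeks both
    include week 12): near term is horizons 1-6, medium term 6-12, and
    fortnight 6 is counted in both, as printed.
    """

    origins: list[int]  # training sizes, advancing one fortnight at a time
    near_term: tuple[int, int] = (1, 6)
    medium_term: tuple[int, int] = (6, 12)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.origins, self.origins[1:])):
            raise ValueError("origins must be strictly increasing")

    @property
    def max_horizon(self) -> int:
        return self.medium_term[1]


@dataclass
class MemberSettings:
    """Fitting cost knobs shared by every stage that trains members."""

    members: tuple[str, ...] = ("arima_seasadj", "garch_seasadj", "gam_raw", "prophet_raw")
    max_predictors: int = 2
    order_grid: tuple = ((0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1), (0, 1, 2))
    garch_steps: int = 1200
    garch_burn: int = 400
    n_paths: int = 1000
    seed: int = 0


@dataclass
class PreparedOrigin:
    """Everything the members need, derived strictly from data up to an origin."""

    train_end: int
    counts: FortnightSeries
    seasadj: FortnightSeries
    seasonal: FortnightSeries
    predictors: pp.LaggedPredictorSet
    decomposition: pp.STLDecomposition


def prepare_origin(counts: FortnightSeries, covariates: pd.DataFrame, train_end: int,
                   max_lag: int = 6, lead: int = FORTNIGHTS_PER_YEAR,
                   verbatim_moisture: bool = True) -> PreparedOrigin:
    """Training-window-only preprocessing at one origin."""
    train_counts = counts.slice(0, train_end)
    decomp = pp.stl_decompose(train_counts)
    seasadj = pp.seasonally_adjust(decomp)
    clim_mask = np.zeros(len(covariates), dtype=bool)
    clim_mask[: lead + train_end] = True
    cand = pp.engineer_predictors(covariates, climatology_mask=clim_mask,
                                  verbatim_moisture=verbatim_moisture)
    retained = pp.prune_collinear(cand.iloc[: lead + train_end])
    # lags chosen against the seasonally adjusted series on the training window
    lagged_adj = pp.select_lags(cand[retained], seasadj, train_end=train_end,
                                max_lag=max_lag, lead=lead)
    # realign the chosen lags over the full span so future rows exist for forecasting
    frame = {}
    for name in retained:
        k = int(lagged_adj.meta.loc[name, "lag"])
        x = cand[name].to_numpy()
        laggedx = x[lead - k : lead - k + len(counts)]
        mean = laggedx[:train_end].mean()
        sd = laggedx[:train_end].std(ddof=1)
        frame[name] = (laggedx - mean) / sd
    predictors = pp.LaggedPredictorSet(pd.DataFrame(frame), lagged_adj.meta, train_end)
    return PreparedOrigin(train_end, counts, seasadj, decomp.seasonal, predictors, decomp)


def fit_members(prep: PreparedOrigin, settings: MemberSettings) -> dict[str, mb.MemberFit]:
    """Fit the requested members plus the seasonal ETS and the benchmark."""
    fits: dict[str, mb.MemberFit] = {}
    if "arima_seasadj" in settings.members:
        fits["arima_seasadj"] = mb.fit_arima_seasadj(
            prep.seasadj, prep.predictors, max_predictors=settings.max_predictors,
            order_grid=settings.order_grid, train_end=prep.train_end)
    if "garch_seasadj" in settings.members:
        fits["garch_seasadj"] = mb.fit_garch_seasadj(
            prep.seasadj, prep.predictors, n_steps=settings.garch_steps,
            n_burn=settings.garch_burn, seed=settings.seed, train_end=prep.train_end)
    if "gam_raw" in settings.members:
        fits["gam_raw"] = mb.fit_gam_raw(prep.counts, prep.predictors,
                                         train_end=prep.train_end)
    if "prophet_raw" in settings.members:
        fits["prophet_raw"] = mb.fit_prophet_raw(prep.counts, prep.predictors,
                                                 train_end=prep.train_end)
    fits["ets_seasonal"] = mb.fit_ets(prep.seasonal, "seasonal_component")
    fits["ets_benchmark"] = mb.fit_ets(prep.counts, "log1p_count", train_end=prep.train_end)
    return fits


def member_count_forecasts(fits: dict, horizon: int, n_paths: int = 1000,
                           seed: int = 0) -> dict[str, mb.ForecastDistribution]:
    """Forecast every member and bring all of them to the outcome (count) scale."""
    seasonal_fc = mb.forecast(fits["ets_seasonal"], horizon, n_paths, seed=seed + 11)
    out = {}
    for i, (name, fit) in enumerate(fits.items()):
        if name in ("ets_seasonal",):
            continue
        fc = mb.forecast(fit, horizon, n_paths, seed=seed + i)
        if fit.target_scale == "seasonally_adjusted":
            fc = mb.to_outcome_scale(fc, seasonal_fc)
        elif fit.target_scale == "log1p_count":
            fc = mb.back_transform_counts(fc)
        else:
            fc = fc.truncated()
        out[name] = fc
    out["_seasonal"] = seasonal_fc
    return out


def validation_forecasts(counts: FortnightSeries, covariates: pd.DataFrame,
                         val_start: int, val_end: int, settings: MemberSettings,
                         horizon: int | None = None):
    """One-shot forecasts over the validation window for weight optimization."""
    horizon = horizon or (val_end - val_start)
    prep = prepare_origin(counts, covariates, val_start)
    fits = fit_members(prep, settings)
    fcs = member_count_forecasts(fits, horizon, settings.n_paths, settings.seed)
    member_fcs = {k: v for k, v in fcs.items()
                  if k not in ("_seasonal", "ets_benchmark")}
    observations = counts.values[val_start : val_start + horizon]
    return member_fcs, observations, fits, prep


@dataclass
class EvaluationReport:
    """Per (model, origin, horizon) point and interval errors."""

    rows: pd.DataFrame  # model, origin, horizon, observed, median, lower, upper,
    #                     point_error, interval_score
    skipped: list = field(default_factory=list)

    def summaries(self) -> pd.DataFrame:
        out = []
        for model, grp in self.rows.groupby("model"):
            q25, q50, q75 = np.percentile(grp["point_error"], [25, 50, 75])
            out.append({"model": model, "median_point_error": q50,
                        "iqr_low": q25, "iqr_high": q75,
                        "mean_interval_score": grp["interval_score"].mean()})
        return pd.DataFrame(out)

    def band_scores(self, plan: EvaluationWindowPlan) -> pd.DataFrame:
        bands = {"near": plan.near_term, "medium": plan.medium_term}
        out = []
        for model, grp in self.rows.groupby("model"):
            for band, (lo, hi) in bands.items():
                sel = grp[(grp["horizon"] >= lo) & (grp["horizon"] <= hi)]
                out.append({"model": model, "band": band,
                            "mean_interval_score": sel["interval_score"].mean(),
                            "mean_point_error": sel["point_error"].mean()})
        return pd.DataFrame(out)


def rolling_evaluate(
    counts: FortnightSeries,
    covariates: pd.DataFrame,
    plan: EvaluationWindowPlan,
    weights: EnsembleWeights,
    settings: MemberSettings | None = None,
    mode: str = "retrained",
    cfg: ScoreConfig | None = None,
    pf_particles: int = 2000,
) -> EvaluationReport:
    """Advance the training cut-point fortnight by fortnight and score forecasts.

    ``mode='retrained'``: every member refits on all data up to the origin.
    ``mode='pf'``: the seasonally adjusted members are fitted once at the
    first origin and thereafter assimilate incoming seasonally adjusted
    observations by particle filtering; the GAM and Prophet-style members are
    refit as usual.  The benchmark refits at every origin in both modes.
    """
    settings = settings or MemberSettings()
    cfg = cfg or ScoreConfig()
    if mode not in ("retrained", "pf"):
        raise ValueError("mode must be 'retrained' or 'pf'")
    rows, skipped = [], []
    pf_state = None  # lazy-initialized at the first origin in pf mode

    for origin in plan.origins:
        H = min(plan.max_horizon, len(counts) - origin)
        if H < 1:
            break
        observed = counts.values[origin : origin + H]
        try:
            prep = prepare_origin(counts, covariates, origin)
            if mode == "retrained" or pf_state is None:
                fits = fit_members(prep, settings)
                fcs = member_count_forecasts(fits, H, settings.n_paths, settings.seed)
                if mode == "pf":
                    pf_state = _init_pf_state(fits, prep, pf_particles, settings.seed)
            else:
                fits, fcs = _pf_origin(pf_state, prep, counts, origin, H, settings)
        except Exception as exc:  # noqa: BLE001 - a failed origin is reported, not fatal
            skipped.append((origin, repr(exc)))
            continue

        ens_members = {name: fcs[name] for name in weights.names}
        ens = combine(ens_members, weights)
        bench = fcs["ets_benchmark"]
        for model_name, fc in (("ensemble", ens), ("benchmark", bench)):
            lo, up = fc.interval(0.95)
            med = fc.median
            for h in range(1, H + 1):
                y = observed[h - 1]
                rows.append({
                    "model": model_name, "origin": origin, "horizon": h,
                    "observed": y, "median": med[h - 1],
                    "lower": lo[h - 1], "upper": up[h - 1],
                    "point_error": abs(med[h - 1] - y),
                    "interval_score": interval_score(
                        PredictionInterval(lo[h - 1], up[h - 1]), y, cfg),
                })
    return EvaluationReport(pd.DataFrame(rows), skipped)


def _init_pf_state(fits, prep, n_particles, seed):
    state = {"fits": fits, "last_end": prep.train_end, "filters": {}}
    for name in ("arima_seasadj", "garch_seasadj"):
        if name in fits:
            fit = fits[name]
            exog_seq = None
            if fit.predictors is not None:
                exog_seq = fit.predictors.future_rows(fit.origin, 48, persistence=True)
            fcfg = FilterConfig(obs_noise_sd=max(fit.residual_sd, 1e-3), rng_seed=seed)
            state["filters"][name] = init_particles(fit, n_particles, fcfg, exog_seq=exog_seq)
    return state


def _pf_origin(pf_state, prep, counts, origin, H, settings):
    """Assimilate new observations since the last origin; refit the raw-count members."""
    fits = dict(pf_state["fits"])
    fits["gam_raw"] = mb.fit_gam_raw(prep.counts, prep.predictors, train_end=origin) \
        if "gam_raw" in fits else fits.get("gam_raw")
    if "prophet_raw" in fits:
        fits["prophet_raw"] = mb.fit_prophet_raw(prep.counts, prep.predictors,
                                                 train_end=origin)
    fits = {k: v for k, v in fits.items() if v is not None}
    fits["ets_benchmark"] = mb.fit_ets(prep.counts, "log1p_count", train_end=origin)
    fits["ets_seasonal"] = mb.fit_ets(prep.seasonal, "seasonal_component")

    # convert the new counts to the seasonally adjusted scale using the
    # training-window STL seasonal extended by the seasonal ETS forecast
    base_end = pf_state["last_end"]
    seasonal_fc = mb.forecast(fits["ets_seasonal"], origin - base_end + H,
                              settings.n_paths, seed=settings.seed + 11)
    new_obs = counts.values[base_end:origin]
    seas_med = seasonal_fc.median[: len(new_obs)]
    adj_obs = new_obs - seas_med
    for name, ps in pf_state["filters"].items():
        ps, _ = run_filter(ps, adj_obs)
        pf_state["filters"][name] = ps
    pf_state["last_end"] = origin

    fcs = member_count_forecasts(
        {k: v for k, v in fits.items() if k not in ("arima_seasadj", "garch_seasadj")},
        H, settings.n_paths, settings.seed)
    seasonal_now = fcs["_seasonal"]
    for name, ps in pf_state["filters"].items():
        fcs[name] = pf_forecast(ps, H, seasonal_now, n_paths=settings.n_paths)
    return fits, fcs


def compare_report(report: EvaluationReport) -> pd.DataFrame:
    """Per-model medians [IQR], mean interval scores and per-origin win fractions."""
    if report.rows.empty:
        raise ValueError("report is empty")
    summary = report.summaries().set_index("model")
    pivot = report.rows.pivot_table(index=["origin", "horizon"], columns="model",
                                    values="interval_score")
    if {"ensemble", "benchmark"} <= set(pivot.columns):
        per_origin = pivot.groupby("origin").mean()
        wins_e = (per_origin["ensemble"] < per_origin["benchmark"]).mean()
        wins_b = (per_origin["benchmark"] < per_origin["ensemble"]).mean()
        summary["win_fraction"] = [
            {"ensemble": wins_e, "benchmark": wins_b}.get(m, np.nan)
            for m in summary.index
        ]
    return summary.reset_index()


def smooth_score_trend(origins: np.ndarray, scores: np.ndarray, df: int = 4,
                       level: float = 0.99):
    """Cubic-regression-spline trend of score vs. origin with a wide confidence
    band (reporting/plotting aid; evaluation metrics stay unsmoothed)."""
    import patsy
    import statsmodels.api as sm

    design = patsy.dmatrix(f"cr(x, df={df})", {"x": origins}, return_type="dataframe")
    fit = sm.OLS(scores, design).fit()
    pred = fit.get_prediction(design).summary_frame(alpha=1 - level)
    return pred["mean"].to_numpy(), pred["mean_ci_lower"].to_numpy(), pred["mean_ci_upper"].to_numpy()
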