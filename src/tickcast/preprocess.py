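"""From raw records and covariates to modelling inputs.

Stages: duplicate removal in the case line list, fortnight binning,
seasonal-trend decomposition by Loess (STL), seasonal adjustment,
stationarity testing, engineered moisture/anomaly predictors, collinearity
pruning and cross-correlation lag selection with unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.stattools import adfuller

from .fortnights import (
    FORTNIGHTS_PER_YEAR,
    FortnightSeries,
    fortnight_grid,
    fortnight_of_date,
    quarter_of_fortnight,
)


def dedupe_cases(records: pd.DataFrame, window_days: int = 14) -> pd.DataFrame:
    """Drop re-recordings within ``window_days`` of a retained record.

    Records are grouped into (clinic, species) streams; within each stream a
    record falling within the window after the most recently *retained* record
    is treated as a duplicate admission of the same animal.  Improbable
    records are retained (the abstraction procedure is assumed ~95% specific
    and all retrieved records are kept).  Idempotent.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    records = records.sort_values("admission_date", kind="stable")
    keep = np.ones(len(records), dtype=bool)
    window = pd.Timedelta(days=window_days)
    dates = pd.to_datetime(records["admission_date"])
    for _, idx in records.groupby(["clinic_id", "species"]).indices.items():
        last_kept = None
        for i in np.sort(idx):
            d = dates.iloc[i]
            if last_kept is not None and (d - last_kept) <= window:
                keep[i] = False
            else:
                last_kept = d
    return records.loc[keep].reset_index(drop=True)


def bin_fortnights(records: pd.DataFrame, start_year: int, end_year: int) -> FortnightSeries:
    """Bin dated records into half-month counts over complete calendar years.

    Days 1-15 go to the first half of a month, day 16 onward to the second.
    Empty bins are zero-filled; the total count is conserved.
    """
    n = (end_year - start_year + 1) * FORTNIGHTS_PER_YEAR
    counts = np.zeros(n)
    dates = pd.to_datetime(records["admission_date"]) if len(records) else pd.Series(dtype="datetime64[ns]")
    for d in dates:
        year, f = fortnight_of_date(d.date())
        if not start_year <= year <= end_year:
            raise ValueError(f"record date {d.date()} outside [{start_year}, {end_year}]")
        counts[(year - start_year) * FORTNIGHTS_PER_YEAR + f - 1] += 1
    return FortnightSeries(counts, start_year)


@dataclass
class STLDecomposition:
    """Additive seasonal / trend / remainder split of a fortnight series."""

    seasonal: FortnightSeries
    trend: FortnightSeries
    remainder: FortnightSeries

    def reconstruct(self) -> np.ndarray:
        return self.seasonal.values + self.trend.values + self.remainder.values


def stl_decompose(
    series: FortnightSeries,
    periodicity: int = FORTNIGHTS_PER_YEAR,
    seasonal_window: int = 99,
    robust: bool = False,
) -> STLDecomposition:
    """Seasonal-trend decomposition based on Loess smoothing.

    The seasonal component is the Loess smooth of each seasonal sub-series
    (the 24 fortnights across years); a large odd ``seasonal_window`` gives a
    near-periodic seasonal pattern.  The trend is the Loess smooth of the
    deseasonalized series; the remainder is the residual, so the three
    components sum exactly to the input.
    """
    if len(series) < 2 * periodicity:
        raise ValueError("series must span at least two seasonal cycles")
    res = STL(series.values, period=periodicity, seasonal=seasonal_window, robust=robust).fit()
    mk = lambda v: series.with_values(v)
    return STLDecomposition(mk(res.seasonal), mk(res.trend), mk(res.resid))


def seasonally_adjust(decomp: STLDecomposition) -> FortnightSeries:
    """The seasonally adjusted series: trend + remainder."""
    return decomp.trend.with_values(decomp.trend.values + decomp.remainder.values)


def adf_test(series: FortnightSeries | np.ndarray) -> tuple[float, float]:
    """Augmented Dickey-Fuller unit-root test (constant term, AIC lag order).

    Returns (statistic, p-value); p < 0.05 rejects the unit root, supporting
    stationarity of the seasonally adjusted series.
    """
    values = series.values if isinstance(series, FortnightSeries) else np.asarray(series, float)
    if len(values) < 20:
        raise ValueError("series too short for a Dickey-Fuller test")
    if np.ptp(values) == 0:
        raise ValueError("constant series: degenerate Dickey-Fuller regression")
    stat, pvalue, *_ = adfuller(values, regression="c", autolag="AIC")
    return float(stat), float(pvalue)


def moist_vegetation(
    rainfall,
    evapotranspiration,
    shrub_cover,
    forest_cover,
    intended_form: bool = False,
) -> np.ndarray:
    """Moist-vegetation index.

    Default is the published arithmetic, verbatim:
    ``rainfall * (-1 * evapotranspiration) * (shrub_cover + forest_cover)``.
    With ``intended_form=True`` the plausibly intended positive-moisture
    variant ``rainfall / (1 + evapotranspiration) * (shrub + forest)`` is
    returned instead (more rainfall and less evapotranspiration -> wetter).
    """
    arrays = [np.asarray(a, dtype=float) for a in
              (rainfall, evapotranspiration, shrub_cover, forest_cover)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("input series must be aligned (equal lengths)")
    rain, et, shrub, forest = arrays
    if intended_form:
        return rain / (1.0 + et) * (shrub + forest)
    return rain * (-1.0 * et) * (shrub + forest)


def quarterly_anomaly(
    values: np.ndarray,
    fortnights: np.ndarray,
    years: np.ndarray,
    climatology_mask: np.ndarray | None = None,
) -> np.ndarray:
    """How each calendar quarter compared to the long-term average for that
    same quarter-of-year.

    Every fortnight in a given (year, quarter) receives that quarter's mean
    value minus the climatological mean of the quarter-of-year (Jan-Mar,
    Apr-Jun, Jul-Sep, Oct-Dec).  The climatology is computed over
    ``climatology_mask`` only (default: all rows), so a training-only
    climatology never leaks validation information.  Linear in the input for
    a shared climatology; a series that repeats identically every year has
    anomaly zero everywhere.
    """
    values = np.asarray(values, dtype=float)
    fortnights = np.asarray(fortnights)
    years = np.asarray(years)
    if not values.shape == fortnights.shape == years.shape:
        raise ValueError("values, fortnights and years must be aligned")
    if climatology_mask is None:
        climatology_mask = np.ones(len(values), dtype=bool)
    climatology_mask = np.asarray(climatology_mask, dtype=bool)
    if climatology_mask.sum() < 2 * FORTNIGHTS_PER_YEAR:
        raise ValueError("climatology window must span at least two full years")
    quarters = np.array([quarter_of_fortnight(int(f)) for f in fortnights])
    clim = np.empty(4)
    for q in range(4):
        base = values[(quarters == q) & climatology_mask]
        if len(base) == 0:
            raise ValueError(f"no climatology data for quarter {q}")
        clim[q] = base.mean()
    anom = np.empty_like(values)
    for key in np.unique(years * 4 + quarters):
        in_yq = years * 4 + quarters == key
        anom[in_yq] = values[in_yq].mean() - clim[key % 4]
    return anom


# priority used in the source study region: anomalies beat raw NDVI, maximum
# temperature beats minimum temperature; earlier names win ties.
DEFAULT_PRIORITY = (
    "moist_vegetation",
    "moist_vegetation_anomaly",
    "max_temperature",
    "max_temperature_anomaly",
    "ndvi_anomaly",
    "soi",
    "min_temperature",
    "ndvi",
)


def prune_collinear(
    covariates: pd.DataFrame,
    threshold: float = 0.70,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> list[str]:
    """Greedy removal of collinear predictors.

    While any retained pair has |Pearson r| > ``threshold``, drop the
    lower-priority member of the worst-offending pair.  Names absent from the
    priority list rank below all listed names, in column order.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates")

    def rank(name: str) -> int:
        return priority.index(name) if name in priority else len(priority) + list(covariates).index(name)

    retained = list(covariates.columns)
    while True:
        corr = covariates[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        if not corr[i, j] > threshold:
            return retained
        a, b = retained[i], retained[j]
        retained.remove(b if rank(a) <= rank(b) else a)
        if len(retained) == 1:
            return retained


@dataclass
class LaggedPredictorSet:
    """Lag-selected, unit-variance-scaled predictors aligned to the target grid.

    Row t of ``frame`` holds the covariate value observed at t - lag, scaled by
    the training-window mean/sd.  ``meta`` records per predictor the chosen
    lag, its cross-correlation with the target, the scaling constants and a
    weak-signal flag.
    """

    frame: pd.DataFrame  # indexed by absolute position on the target grid
    meta: pd.DataFrame  # index: name; columns: lag, correlation, mean, sd, weak
    train_end: int  # exclusive end of the training window (positions)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def min_lag(self) -> int:
        return int(self.meta["lag"].min())

    def training_matrix(self, start: int = 0) -> np.ndarray:
        return self.frame.iloc[start : self.train_end].to_numpy()

    def future_rows(self, origin: int, horizon: int, persistence: bool = True) -> np.ndarray:
        """Predictor rows for forecast steps origin+1 .. origin+horizon.

        A row at step h only uses covariates observed at or before ``origin``
        when h <= lag; later steps would need unobserved covariates and are
        filled by last-value-carried-forward when ``persistence`` is on,
        otherwise an error lists the missing inputs.
        """
        rows = np.full((horizon, len(self.names)), np.nan)
        missing = []
        for j, name in enumerate(self.names):
            lag = int(self.meta.loc[name, "lag"])
            col = self.frame[name].to_numpy()
            for h in range(1, horizon + 1):
                t = origin + h
                if h <= lag and t < len(col):
                    rows[h - 1, j] = col[t]
                elif persistence:
                    t_last = min(origin + lag, len(col) - 1)
                    rows[h - 1, j] = col[t_last]
                else:
                    missing.append((name, h))
        if missing:
            raise ValueError(f"unobserved lagged covariates required: {missing}")
        return rows


def select_lags(
    covariates: pd.DataFrame,
    target: FortnightSeries,
    train_end: int | None = None,
    max_lag: int = 6,
    weak_threshold: float = 0.10,
    lead: int | None = None,
) -> LaggedPredictorSet:
    """Choose, per covariate, the lag in 1..max_lag with the strongest
    cross-correlation against the (seasonally adjusted) target.

    ``covariates`` rows must extend at least ``max_lag`` fortnights before the
    target start (``lead`` rows of lead-in; default max_lag).  Ties break
    toward the smaller lag.  Outputs are scaled to unit variance on the
    training window (positions [0, train_end) of the target grid).
    """
    lead = max_lag if lead is None else lead
    if lead < max_lag:
        raise ValueError("covariates must extend >= max_lag before the target start")
    y = target.values
    n = len(y)
    train_end = n if train_end is None else train_end
    if len(covariates) < lead + n:
        raise ValueError("covariate table too short for the target span")

    cols, meta_rows = {}, []
    y_train = y[:train_end]
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        if np.std(x[: lead + train_end]) == 0:
            raise ValueError(f"zero-variance covariate {name!r}")
        best_lag, best_r = None, 0.0
        for k in range(1, max_lag + 1):
            lagged_train = x[lead - k : lead - k + train_end]
            r = np.corrcoef(lagged_train, y_train)[0, 1]
            if best_lag is None or abs(r) > abs(best_r) + 1e-12:
                best_lag, best_r = k, r
        lagged = x[lead - best_lag : lead - best_lag + n]
        mean = lagged[:train_end].mean()
        sd = lagged[:train_end].std(ddof=1)
        cols[name] = (lagged - mean) / sd
        meta_rows.append((name, best_lag, best_r, mean, sd, abs(best_r) < weak_threshold))

    frame = pd.DataFrame(cols)
    meta = pd.DataFrame(
        meta_rows, columns=["name", "lag", "correlation", "mean", "sd", "weak"]
    ).set_index("name")
    return LaggedPredictorSet(frame, meta, train_end)


def engineer_predictors(
    covariates: pd.DataFrame,
    climatology_mask: np.ndarray | None = None,
    verbatim_moisture: bool = True,
) -> pd.DataFrame:
    """Build the candidate predictor table from a raw covariate table.

    Produces moist vegetation (published formula by default), quarterly
    anomalies of moist vegetation / max and min temperature / NDVI, raw
    temperatures, NDVI and SOI, mirroring the study's candidate set.
    """
    fns = covariates["fortnight"].to_numpy()
    yrs = covariates["year"].to_numpy()
    moist = moist_vegetation(
        covariates["rainfall"], covariates["evapotranspiration"],
        covariates["shrub_cover"], covariates["forest_cover"],
        intended_form=not verbatim_moisture,
    )
    out = pd.DataFrame(
        {
            "moist_vegetation": moist,
            "max_temperature": covariates["max_temperature"].to_numpy(),
            "min_temperature": covariates["min_temperature"].to_numpy(),
            "ndvi": covariates["ndvi"].to_numpy(),
            "soi": covariates["soi"].to_numpy(),
        }
    )
    for name in ("moist_vegetation", "max_temperature", "min_temperature", "ndvi"):
        out[f"{name}_anomaly"] = quarterly_anomaly(out[name].to_numpy(), fns, yrs,
                                                   climatology_mask)
    return out
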