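"""Synthetic case line lists and environmental covariate tables.

Emulates an 11-year fortnightly admission series from a cluster of veterinary
clinics in a subtropical tick-paralysis hotspot: a strong September-November
seasonal peak, a nonlinear long-term trend with a mid-series trough,
negative-binomial overdispersion, lagged environmental effects on the
log-mean, a small fraction of misclassified ("improbable") records and
occasional duplicate admissions of the same animal within a fortnight.

Ground truth (per-fortnight means and counts) is returned in a separate table
so that pipeline code can never consume it by accident.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fortnights import (
    FORTNIGHTS_PER_YEAR,
    fortnight_bounds,
    fortnight_grid,
    quarter_of_fortnight,
)

CLIMATE_VARIABLES = ("max_temperature", "min_temperature", "rainfall", "evapotranspiration", "ndvi")
COVARIATE_COLUMNS = CLIMATE_VARIABLES + ("soi", "shrub_cover", "forest_cover")

# Fortnightly seasonal means for a warm, wet subtropical coastal climate
# (summer-peaking temperature/rain; NDVI nearly aseasonal so its quarterly
# anomaly is strongly collinear with the raw index, as observed in the region).
_SEASONAL_MEANS = {
    "max_temperature": (25.0, 4.0),  # (annual mean, seasonal amplitude), peak mid-January
    "min_temperature": (15.0, 6.0),
    "rainfall": (65.0, 40.0),  # mm per fortnight
    "evapotranspiration": (55.0, 20.0),  # mm per fortnight
    "ndvi": (0.62, 0.01),
}
_NOISE_SD = {
    "max_temperature": 1.0,
    "min_temperature": 1.0,
    "rainfall": 25.0,
    "evapotranspiration": 6.0,
    "ndvi": 0.02,
}

# Relative monthly admission rates: minimal Feb-Jul, strong Sep-Nov peak.
_MONTHLY_RELATIVE = np.array([0.6, 0.3, 0.3, 0.3, 0.3, 0.3, 0.4, 1.2, 2.6, 3.2, 2.4, 1.3])


def default_seasonal_amplitudes() -> np.ndarray:
    """Per-fortnight multiplicative seasonal factors, normalized to mean 1."""
    amps = np.repeat(_MONTHLY_RELATIVE, 2)
    return amps / amps.mean()


def default_trend_knots(n_years: int = 11) -> list[tuple[float, float]]:
    """Piecewise-linear log-mean trend: decline into a mid-series trough, recovery after."""
    t_end = n_years * FORTNIGHTS_PER_YEAR - 1
    return [(0.0, 0.30), (0.40 * t_end, -0.50), (0.65 * t_end, -0.30), (float(t_end), 0.45)]


@dataclass
class SimulationConfig:
    """Ground-truth generating process for the synthetic study system."""

    n_years: int = 11
    start_year: int = 2007
    baseline: float = 2.0  # mean admissions per fortnight at seasonal factor 1, trend 0
    seasonal_amplitudes: np.ndarray = field(default_factory=default_seasonal_amplitudes)
    trend_knots: list[tuple[float, float]] | None = None
    covariate_effects: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "max_temperature_anomaly": (2, -0.25),
            "soi": (2, 0.15),
            "moist_vegetation": (6, 0.10),
        }
    )
    phi: float = 5.0  # negative-binomial overdispersion (variance = mu + mu^2/phi)
    false_positive_rate: float = 0.05
    duplicate_rate: float = 0.5  # ~766 retrieved vs 520 retained admissions
    duplicate_window_days: int = 14
    covariate_ar: float = 0.7  # AR(1) coefficient of climate noise
    soi_ar: float = 0.9
    covariate_noise_scale: float = 1.0
    n_clinics: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        self.seasonal_amplitudes = np.asarray(self.seasonal_amplitudes, dtype=float)
        if self.seasonal_amplitudes.shape != (FORTNIGHTS_PER_YEAR,):
            raise ValueError("seasonal_amplitudes must have exactly 24 entries")
        if np.any(self.seasonal_amplitudes <= 0):
            raise ValueError("seasonal_amplitudes must all be > 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        for name, rate in (("false_positive_rate", self.false_positive_rate),
                           ("duplicate_rate", self.duplicate_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trend_knots is None:
            self.trend_knots = default_trend_knots(self.n_years)

    @property
    def n_fortnights(self) -> int:
        return self.n_years * FORTNIGHTS_PER_YEAR

    @property
    def max_lag(self) -> int:
        lags = [lag for lag, _ in self.covariate_effects.values()]
        return max(lags, default=0)


@dataclass
class SimulationResult:
    """Case line list plus the separate ground-truth table."""

    records: pd.DataFrame  # admission_date, clinic_id, species, record_class
    truth: pd.DataFrame  # year, fortnight, mu, count
    n_duplicates: int
    n_false_positives: int

    @property
    def counts(self) -> np.ndarray:
        return self.truth["count"].to_numpy()


def _seasonal_cycle(mean: float, amplitude: float, peak_fortnight: float = 1.5) -> np.ndarray:
    f = np.arange(1, FORTNIGHTS_PER_YEAR + 1)
    return mean + amplitude * np.cos(2 * np.pi * (f - peak_fortnight) / FORTNIGHTS_PER_YEAR)


def _ar1(n: int, rho: float, innov_sd: float, rng: np.random.Generator) -> np.ndarray:
    if innov_sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    stat_sd = innov_sd / np.sqrt(max(1.0 - rho**2, 1e-12)) if abs(rho) < 1 else innov_sd
    x[0] = rng.normal(0.0, stat_sd)
    e = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t - 1]
    return x


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the fortnight-aligned covariate table.

    Each climate series is its seasonal mean plus AR(1) noise; SOI is a
    zero-mean AR(1); land-cover proportions change only between years.  One
    lead-in year is prepended so that lagged predictors exist from the first
    simulated case fortnight.  Deterministic for a given ``rng_seed``.
    """
    if config.n_years < 2:
        raise ValueError("n_years must be >= 2 (lag selection needs history)")
    rng = np.random.default_rng(config.rng_seed)
    n = (config.n_years + 1) * FORTNIGHTS_PER_YEAR  # lead-in year included
    index = fortnight_grid(config.start_year - 1, n)
    fns = np.asarray(index.get_level_values("fortnight"))
    years = np.asarray(index.get_level_values("year"))

    out = {}
    for name in CLIMATE_VARIABLES:
        mean, amp = _SEASONAL_MEANS[name]
        seasonal = _seasonal_cycle(mean, amp)[fns - 1]
        # NDVI is a monthly-resolution vegetation index: its departures from
        # climatology persist for months, unlike fortnight-scale weather noise
        rho = max(config.covariate_ar, 0.9) if name == "ndvi" else config.covariate_ar
        noise = _ar1(n, rho, _NOISE_SD[name] * config.covariate_noise_scale, rng)
        series = seasonal + noise
        if name == "rainfall":
            series = np.clip(series, 0.0, None)
        elif name == "ndvi":
            series = np.clip(series, 0.0, 1.0)
        out[name] = series

    out["soi"] = _ar1(n, config.soi_ar, 3.0 * config.covariate_noise_scale, rng)

    # land cover: small yearly random-walk steps, constant within a year
    n_years_total = config.n_years + 1
    for name, start in (("shrub_cover", 0.18), ("forest_cover", 0.35)):
        steps = rng.normal(0.0, 0.005 * config.covariate_noise_scale, size=n_years_total - 1)
        yearly = np.clip(start + np.concatenate([[0.0], np.cumsum(steps)]), 0.0, 1.0)
        out[name] = yearly[years - (config.start_year - 1)]

    table = pd.DataFrame(out, index=index).reset_index()
    return table[["year", "fortnight", *COVARIATE_COLUMNS]]


def _predictor_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    """Derived predictors the generating process may act through.

    ``moist_vegetation`` here is the positive-moisture form rain/(1+ET) x cover
    (the generator needs a monotone 'wetter and shrubbier means more ticks'
    driver); the preprocessing module exposes the published index separately.
    """
    frame = covariates.set_index(["year", "fortnight"]).copy()
    frame["moist_vegetation"] = (
        frame["rainfall"] / (1.0 + frame["evapotranspiration"])
        * (frame["shrub_cover"] + frame["forest_cover"])
    )
    quarters = np.array([quarter_of_fortnight(f) for f in frame.index.get_level_values("fortnight")])
    years = np.asarray(frame.index.get_level_values("year"))
    for name in ("max_temperature", "min_temperature", "ndvi", "moist_vegetation"):
        vals = frame[name].to_numpy()
        clim = np.array([vals[quarters == q].mean() for q in range(4)])
        anom = np.empty_like(vals)
        for key in np.unique(years * 4 + quarters):
            in_yq = years * 4 + quarters == key
            anom[in_yq] = vals[in_yq].mean() - clim[key % 4]
        frame[f"{name}_anomaly"] = anom
    return frame


def simulate_cases(config: SimulationConfig, covariates: pd.DataFrame) -> SimulationResult:
    """Draw fortnight counts and expand them into a dated case line list.

    log mean = log(baseline) + log(seasonal factor) + trend(t)
               + sum of effects on lagged, unit-scaled predictors;
    counts are negative binomial with overdispersion ``phi`` (success
    probability phi / (phi + mu)).  Duplicate re-admissions and improbable
    (false-positive) records are injected at the configured rates.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    n = config.n_fortnights
    grid = fortnight_grid(config.start_year, n)

    predictors = _predictor_frame(covariates)
    for name in config.covariate_effects:
        if name not in predictors.columns:
            raise KeyError(f"covariate effect references unknown predictor {name!r}")

    start_pos = predictors.index.get_loc((config.start_year, 1))
    if start_pos < config.max_lag:
        raise ValueError("covariates must cover all simulated fortnights plus the maximum lag")
    if len(predictors) < start_pos + n:
        raise ValueError("covariate table too short for the simulated span")

    t = np.arange(n, dtype=float)
    knots = np.asarray(config.trend_knots, dtype=float)
    trend = np.interp(t, knots[:, 0], knots[:, 1])
    fns = np.asarray(grid.get_level_values("fortnight"))
    log_mu = np.log(config.baseline) + np.log(config.seasonal_amplitudes[fns - 1]) + trend

    for name, (lag, coef) in config.covariate_effects.items():
        vals = predictors[name].to_numpy()
        scaled = (vals - vals.mean()) / vals.std(ddof=1)
        log_mu += coef * scaled[start_pos - lag : start_pos - lag + n]

    mu = np.exp(log_mu)
    counts = rng.negative_binomial(config.phi, config.phi / (config.phi + mu))

    clinic_weights = rng.dirichlet(np.full(config.n_clinics, 8.0))
    clinic_ids = [f"clinic_{i + 1}" for i in range(config.n_clinics)]
    rows: list[tuple[dt.date, str, str, str]] = []
    for (year, fn), count in zip(grid, counts):
        if count == 0:
            continue
        first, last = fortnight_bounds(year, fn)
        days = rng.integers(0, (last - first).days + 1, size=count)
        clinics = rng.choice(config.n_clinics, size=count, p=clinic_weights)
        for d, c in zip(days, clinics):
            species = "dog" if rng.random() < 0.77 else "cat"
            record_class = "confirmed" if rng.random() < 0.8 / 0.95 else "probable"
            rows.append((first + dt.timedelta(days=int(d)), clinic_ids[c], species, record_class))

    last_day = fortnight_bounds(config.start_year + config.n_years - 1, FORTNIGHTS_PER_YEAR)[1]
    first_day = dt.date(config.start_year, 1, 1)

    # duplicate re-recordings of the same admission within the dedup window
    duplicates = []
    for row in rows:
        if rng.random() < config.duplicate_rate:
            offset = int(rng.integers(1, config.duplicate_window_days))
            date = min(row[0] + dt.timedelta(days=offset), last_day)
            duplicates.append((date, row[1], row[2], row[3]))

    # improbable records: uniform over the study span, diluting seasonality
    n_base = len(rows) + len(duplicates)
    fp_rate = config.false_positive_rate
    n_fp = rng.poisson(n_base * fp_rate / (1.0 - fp_rate)) if fp_rate > 0 else 0
    span_days = (last_day - first_day).days
    false_positives = []
    for _ in range(n_fp):
        date = first_day + dt.timedelta(days=int(rng.integers(0, span_days + 1)))
        clinic = clinic_ids[rng.choice(config.n_clinics, p=clinic_weights)]
        species = "dog" if rng.random() < 0.77 else "cat"
        false_positives.append((date, clinic, species, "improbable"))

    records = pd.DataFrame(
        rows + duplicates + false_positives,
        columns=["admission_date", "clinic_id", "species", "record_class"],
    ).sort_values("admission_date", kind="stable").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "year": grid.get_level_values("year"),
            "fortnight": grid.get_level_values("fortnight"),
            "mu": mu,
            "count": counts,
        }
    )
    return SimulationResult(records, truth, len(duplicates), n_fp)


def write_simulation(result: SimulationResult, covariates: pd.DataFrame, out_dir) -> None:
    """Write case line list, covariate table and ground truth as CSV (ISO dates)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = result.records.copy()
    records["admission_date"] = records["admission_date"].astype(str)
    records.to_csv(out / "cases.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    result.truth.to_csv(out / "ground_truth.csv", index=False)
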