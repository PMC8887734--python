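"""Sequential Monte Carlo assimilation of incoming observations.

The two members fitted to the seasonally adjusted series (ARIMA and the
Bayesian GARCH-type model) are adapted to new observations without refitting:
a cloud of particles — each one a possible forecast trajectory propagated by
the fitted model equations — is reweighted by the Gaussian log-likelihood of
each incoming seasonally adjusted observation given the particle's one-step
proposal.  Log-likelihoods accumulate ("condensation", performed in log space
to avoid underflow).  When the effective sample size 1/sum(w^2) drops below a
threshold (default N/2) the particles are resampled with replacement in
proportion to their weights, mutated by small Gaussian random-walk jitter to
restore diversity, and the weights reset to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .members.base import ForecastDistribution, to_outcome_scale
from .members.arima import ArimaFit
from .members.garch import GarchFit


@dataclass
class FilterConfig:
    obs_noise_sd: float  # observation likelihood scale (from the member's residual sd)
    mutation_sd: float | None = None  # default: 10% of obs_noise_sd
    ess_threshold_fraction: float = 0.5
    resampling: str = "multinomial"  # or "systematic"
    rng_seed: int = 0

    def __post_init__(self):
        if self.obs_noise_sd <= 0:
            raise ValueError("obs_noise_sd must be > 0")
        if self.mutation_sd is None:
            self.mutation_sd = 0.1 * self.obs_noise_sd
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        if not 0.0 < self.ess_threshold_fraction <= 1.0:
            raise ValueError("ess_threshold_fraction must be in (0, 1]")
        if self.resampling not in ("multinomial", "systematic"):
            raise ValueError(f"unknown resampling scheme {self.resampling!r}")


class ParticleModel:
    """One-step state transition of a fitted model's trajectory.

    ``states`` is an (N, k) float array; ``propagate`` advances every particle
    one fortnight and returns its proposal for the next observation.
    ``mutation_mask`` marks state columns that random-walk jitter may touch
    (trajectory states yes, fixed parameter draws no).
    """

    mutation_mask: np.ndarray

    def initial_states(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def propagate(self, states: np.ndarray, step: int, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class AR1Model(ParticleModel):
    """Linear-Gaussian AR(1) state space (exact Kalman answer exists)."""

    def __init__(self, phi: float, innovation_sd: float,
                 init_mean: float = 0.0, init_sd: float = 1.0):
        self.phi = phi
        self.innovation_sd = innovation_sd
        self.init_mean = init_mean
        self.init_sd = init_sd
        self.mutation_mask = np.array([True])

    def initial_states(self, n, rng):
        return rng.normal(self.init_mean, self.init_sd, size=(n, 1))

    def propagate(self, states, step, rng):
        x = self.phi * states[:, 0] + rng.normal(0.0, self.innovation_sd, size=len(states))
        return x[:, None], x


class ArimaParticleModel(ParticleModel):
    """Trajectory propagation by the fitted ARIMA's own recursion.

    The regression part (exogenous predictors, constant) is removed, the
    ARMA(p, q) recursion runs on the d-times differenced residual series, and
    levels are re-integrated.  State per particle: p lagged (differenced)
    values, q lagged innovations, d lagged levels.  All particles start at the
    training-terminal state; diversity comes from simulated innovations.
    """

    def __init__(self, fit: ArimaFit, exog_seq: np.ndarray | None):
        res = fit.results
        p, d, q = fit.fit_metadata["order"]
        if d > 1:
            raise ValueError("particle propagation supports d <= 1")
        self.p, self.d, self.q = p, d, q
        self.ar = np.asarray(res.arparams, dtype=float)
        self.ma = np.asarray(res.maparams, dtype=float)
        names = list(res.param_names)
        params = np.asarray(res.params, dtype=float)
        self.const = float(params[names.index("intercept")]) if "intercept" in names else 0.0
        k_exog = len(fit.predictors.names) if fit.predictors is not None else 0
        self.beta = params[[names.index(f"x{i + 1}") for i in range(k_exog)]] if k_exog else np.zeros(0)
        self.sigma = float(np.sqrt(params[names.index("sigma2")]))
        self.exog_seq = exog_seq  # (H, k_exog) future predictor rows

        # regression-adjusted training series and its terminal state
        y = np.asarray(res.model.endog, dtype=float).ravel()
        X = res.model.exog
        r = y - (X @ self.beta if X is not None and k_exog else 0.0) - (
            self.const if d == 0 else 0.0)
        w = np.diff(r, n=d) if d else r
        resid = np.asarray(res.resid, dtype=float)
        self._w_tail = w[len(w) - p:][::-1].copy() if p else np.zeros(0)
        self._e_tail = resid[len(resid) - q:][::-1].copy() if q else np.zeros(0)
        self._r_last = np.array([r[-1]]) if d else np.zeros(0)
        k = p + q + d
        self.mutation_mask = np.ones(max(k, 1), dtype=bool)

    def initial_states(self, n, rng):
        base = np.concatenate([self._w_tail, self._e_tail, self._r_last])
        if base.size == 0:
            base = np.zeros(1)
        return np.tile(base, (n, 1))

    def _exog_term(self, step: int) -> float | np.ndarray:
        if self.beta.size == 0:
            return 0.0
        if self.exog_seq is None or step >= len(self.exog_seq):
            row = self.exog_seq[-1] if self.exog_seq is not None else np.zeros(len(self.beta))
        else:
            row = self.exog_seq[step]
        return float(row @ self.beta)

    def propagate(self, states, step, rng):
        n = len(states)
        p, d, q = self.p, self.d, self.q
        w_lags = states[:, :p]
        e_lags = states[:, p : p + q]
        e = rng.normal(0.0, self.sigma, size=n)
        w = e.copy()  # the constant is handled on the observation side
        if p:
            w += w_lags @ self.ar
        if q:
            w += e_lags @ self.ma
        r = states[:, p + q] + w if d else w
        cols = []
        if p:
            cols.append(np.column_stack([w, w_lags[:, : p - 1]]) if p > 1 else w[:, None])
        if q:
            cols.append(np.column_stack([e, e_lags[:, : q - 1]]) if q > 1 else e[:, None])
        if d:
            cols.append(r[:, None])
        new = np.hstack(cols) if cols else np.zeros((n, 1))
        proposal = r + self._exog_term(step) + (self.const if d == 0 else 0.0)
        return new, proposal


class GarchParticleModel(ParticleModel):
    """Trajectory propagation for the Bayesian MA(2)/ARCH(2) member.

    Each particle carries one posterior parameter draw plus its two lagged
    innovations; resampling duplicates well-supported parameter draws, so the
    filter also sharpens the parameter distribution over time.
    """

    def __init__(self, fit: GarchFit, exog_seq: np.ndarray | None):
        self.fit = fit
        self.exog_seq = exog_seq
        self.p = fit.n_predictors
        ndim = fit.draws.shape[1]
        self.mutation_mask = np.zeros(ndim + 2, dtype=bool)
        self.mutation_mask[-2:] = True  # jitter innovation states only

    def initial_states(self, n, rng):
        idx = rng.integers(0, len(self.fit.draws), size=n)
        draws = self.fit.draws[idx]
        e1 = np.full(n, self.fit.last_eps[0])
        e2 = np.full(n, self.fit.last_eps[1])
        return np.column_stack([draws, e1, e2])

    def propagate(self, states, step, rng):
        p = self.p
        draws = states[:, :-2]
        e1, e2 = states[:, -2], states[:, -1]
        c = draws[:, 0]
        beta = draws[:, 1 : 1 + p]
        th1, th2 = draws[:, 1 + p], draws[:, 2 + p]
        omega = np.exp(draws[:, 3 + p])
        a1, a2 = np.clip(draws[:, 4 + p], 0, None), np.clip(draws[:, 5 + p], 0, None)
        sig2 = omega + a1 * e1**2 + a2 * e2**2
        e = rng.normal(0.0, np.sqrt(sig2))
        xrow = 0.0
        if p and self.exog_seq is not None:
            row = self.exog_seq[min(step, len(self.exog_seq) - 1)]
            xrow = beta @ row
        proposal = c + xrow + th1 * e1 + th2 * e2 + e
        new = np.column_stack([draws, e, e1])
        return new, proposal


@dataclass
class ParticleSet:
    """N weighted forecast trajectories with their model state."""

    model: ParticleModel
    states: np.ndarray
    log_weights: np.ndarray
    cfg: FilterConfig
    t: int = 0  # assimilation steps performed
    rng: np.random.Generator = None
    n_resamples: int = 0

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def weights(self) -> np.ndarray:
        lw = self.log_weights - self.log_weights.max()
        w = np.exp(lw)
        return w / w.sum()


def init_particles(fit, n: int = 5000, cfg: FilterConfig | None = None,
                   exog_seq: np.ndarray | None = None) -> ParticleSet:
    """Spawn N uniform-weight particles from a fitted seasonally adjusted member."""
    if isinstance(fit, ArimaFit):
        model = ArimaParticleModel(fit, exog_seq)
    elif isinstance(fit, GarchFit):
        model = GarchParticleModel(fit, exog_seq)
    elif isinstance(fit, ParticleModel):
        model = fit
    else:
        raise TypeError(
            "particle filtering supports the seasonally adjusted members "
            "(ARIMA, GARCH) or a ParticleModel"
        )
    cfg = cfg or FilterConfig(obs_noise_sd=getattr(fit, "residual_sd", 1.0))
    rng = np.random.default_rng(cfg.rng_seed)
    states = model.initial_states(n, rng)
    return ParticleSet(model=model, states=states,
                       log_weights=np.zeros(n), cfg=cfg, rng=rng)


def assimilate(particles: ParticleSet, observation: float,
               cfg: FilterConfig | None = None) -> ParticleSet:
    """Advance one step and condition on the incoming observation.

    Each particle's accumulated log-weight gains the Gaussian log-likelihood
    of the observation given its one-step proposal (log-space condensation).
    """
    if not np.isfinite(observation):
        raise ValueError("observation must be finite")
    cfg = cfg or particles.cfg
    states, proposals = particles.model.propagate(particles.states, particles.t, particles.rng)
    loglik = stats.norm.logpdf(observation, loc=proposals, scale=cfg.obs_noise_sd)
    return replace(particles, states=states,
                   log_weights=particles.log_weights + loglik, t=particles.t + 1)


def effective_sample_size(particles: ParticleSet | np.ndarray) -> float:
    """ESS = 1 / sum(normalized weights squared); in [1, N]."""
    w = particles.weights if isinstance(particles, ParticleSet) else np.asarray(particles, float)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("weights must be positive and finite")
    w = w / total
    return float(1.0 / np.sum(w**2))


def _resample_indices(w: np.ndarray, n: int, scheme: str, rng) -> np.ndarray:
    if scheme == "multinomial":
        return rng.choice(n, size=n, p=w)
    positions = (rng.random() + np.arange(n)) / n  # systematic
    return np.searchsorted(np.cumsum(w), positions)


def maybe_resample(particles: ParticleSet, cfg: FilterConfig | None = None) -> ParticleSet:
    """Resample-with-replacement + mutate when ESS drops below the threshold.

    After resampling, trajectory states receive Gaussian random-walk jitter of
    scale ``mutation_sd`` and all weights are reset to uniform.
    """
    cfg = cfg or particles.cfg
    if effective_sample_size(particles) >= cfg.ess_threshold_fraction * particles.n:
        return particles
    idx = _resample_indices(particles.weights, particles.n, cfg.resampling, particles.rng)
    states = particles.states[idx].copy()
    if cfg.mutation_sd > 0:
        mask = particles.model.mutation_mask
        jitter = particles.rng.normal(0.0, cfg.mutation_sd, size=(particles.n, int(mask.sum())))
        states[:, mask] += jitter
    return replace(particles, states=states, log_weights=np.zeros(particles.n),
                   n_resamples=particles.n_resamples + 1)


def run_filter(particles: ParticleSet, observations, cfg: FilterConfig | None = None
               ) -> tuple[ParticleSet, dict]:
    """Assimilate a sequence of observations with automatic resampling."""
    cfg = cfg or particles.cfg
    ess_trace = []
    for y in np.asarray(observations, dtype=float):
        particles = assimilate(particles, y, cfg)
        ess_trace.append(effective_sample_size(particles))
        particles = maybe_resample(particles, cfg)
    return particles, {"ess": np.array(ess_trace), "n_resamples": particles.n_resamples}


def weighted_quantiles(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Quantiles of a weighted sample (interpolated inverse CDF)."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    cdf = np.cumsum(w) - 0.5 * w
    return np.interp(np.asarray(qs, float), cdf, v)


def pf_forecast(particles: ParticleSet, horizon: int,
                ets_seasonal_forecast: ForecastDistribution | None = None,
                n_paths: int = 1000) -> ForecastDistribution:
    """Weighted particle forecast over 1..horizon fortnights.

    Particles are propagated forward (without reweighting); ``n_paths``
    trajectories are drawn in proportion to the particle weights, and the
    seasonal ETS forecast is added pathwise to return to the count scale.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    states = particles.states.copy()
    paths = np.empty((particles.n, horizon))
    for h in range(horizon):
        states, proposals = particles.model.propagate(states, particles.t + h, particles.rng)
        paths[:, h] = proposals
    idx = particles.rng.choice(particles.n, size=n_paths, p=particles.weights)
    fc = ForecastDistribution(origin=particles.t, paths=paths[idx])
    if ets_seasonal_forecast is not None:
        fc = ForecastDistribution(ets_seasonal_forecast.origin, fc.paths)
        fc = to_outcome_scale(fc, ets_seasonal_forecast)
    return fc


def adapt_to_subseries(
    ensemble_fits: dict[str, ArimaFit | GarchFit],
    clinic_series: dict[str, "FortnightSeries"],
    n_particles: int = 5000,
    seed: int = 0,
    exog_seq: np.ndarray | None = None,
) -> dict[str, dict]:
    """Clinic-level particle filters seeded from the aggregate fits.

    All aggregate parameter distributions are retained; only the Gaussian
    observation-error scale is re-initialized per clinic, from the residual sd
    of an ARIMA(1,0,1) fitted to that clinic's seasonally adjusted series.
    Each filter then assimilates the clinic's full seasonally adjusted series.
    """
    import warnings

    from statsmodels.tsa.statespace.sarimax import SARIMAX

    from .fortnights import FORTNIGHTS_PER_YEAR
    from .preprocess import seasonally_adjust, stl_decompose

    out: dict[str, dict] = {}
    for i_clinic, (clinic, series) in enumerate(clinic_series.items()):
        if len(series) < 2 * FORTNIGHTS_PER_YEAR:
            raise ValueError(f"clinic series {clinic!r} shorter than two seasonal cycles")
        decomp = stl_decompose(series)
        adj = seasonally_adjust(decomp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res101 = SARIMAX(adj.values, order=(1, 0, 1), trend="c").fit(disp=False)
        obs_sd = float(np.std(res101.resid[1:], ddof=1))
        entry = {"obs_noise_sd": obs_sd, "seasonally_adjusted": adj,
                 "seasonal": decomp.seasonal, "filters": {}}
        for name, fit in ensemble_fits.items():
            cfg = FilterConfig(obs_noise_sd=obs_sd, rng_seed=seed + 1000 * i_clinic)
            ps = init_particles(fit, n_particles, cfg, exog_seq=exog_seq)
            ps, diag = run_filter(ps, adj.values, cfg)
            entry["filters"][name] = ps
        out[clinic] = entry
    return out
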