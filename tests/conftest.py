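import numpy as np
import pytest

from tickcast import preprocess as pp
from tickcast.simulate import SimulationConfig, simulate_cases, simulate_covariates

# small order grid keeps ARIMA grid searches affordable in the test suite
FAST_ORDERS = ((0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1))


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at default (study-condition) settings,
    preprocessed end to end; shared read-only across tests."""
    cfg = SimulationConfig(rng_seed=11)
    covariates = simulate_covariates(cfg)
    result = simulate_cases(cfg, covariates)
    deduped = pp.dedupe_cases(result.records, cfg.duplicate_window_days)
    counts = pp.bin_fortnights(deduped, cfg.start_year,
                               cfg.start_year + cfg.n_years - 1)
    decomp = pp.stl_decompose(counts)
    seasadj = pp.seasonally_adjust(decomp)
    candidates = pp.engineer_predictors(covariates)
    retained = pp.prune_collinear(candidates)
    lagged = pp.select_lags(candidates[retained], seasadj, train_end=225)
    return {
        "config": cfg,
        "covariates": covariates,
        "result": result,
        "counts": counts,
        "decomp": decomp,
        "seasadj": seasadj,
        "candidates": candidates,
        "retained": retained,
        "lagged": lagged,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
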