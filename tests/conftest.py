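import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hapticmem as hm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    return hm.REFERENCE_MODEL_PARAMS


@pytest.fixture(scope="session")
def exp2_conds():
    return hm.exp2_conditions()


@pytest.fixture(scope="session")
def exp2_trials():
    """One simulated Exp-2 dataset shared across tests (4 participants)."""
    cfg = hm.ExperimentConfig.exp2(n_participants=4, seed=11)
    return hm.simulate_experiment(cfg, hm.ObserverParams())


@pytest.fixture(scope="session")
def exp2_jnd_table(exp2_trials):
    table = hm.build_jnd_table(exp2_trials)
    return hm.exclude_outliers(table)


def simulate_condition_trials(
    cond,
    observer,
    repetitions,
    seed,
    standards=None,
):
    """Trials for a single condition with responses drawn at the observer's
    true probability -- a lightweight generation oracle for recovery tests."""
    if standards is None:
        standards = hm.default_standards()
    sigma_d, _ = hm.predict_jnd(
        observer.model, cond, comparison_noise_mode=observer.comparison_noise_mode
    )
    rng = np.random.default_rng(seed)
    rows = []
    for series in standards:
        bias = observer.pse_bias(cond, series.standard_period)
        for comp in series.comparison_periods:
            p = hm.response_probability(
                comp, series.standard_period, sigma_d, pse_bias=bias, lapse=observer.lapse
            )
            k = rng.binomial(repetitions, p)
            for i in range(repetitions):
                rows.append(
                    {
                        "participant": 1,
                        "condition": cond.describe(),
                        "n1": cond.n1,
                        "masked": cond.masked,
                        "standard_period_mm": series.standard_period,
                        "comparison_period_mm": float(comp),
                        "response": 1 if i < k else 0,
                    }
                )
    return pd.DataFrame(rows)
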