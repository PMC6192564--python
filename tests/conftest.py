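import logging

import numpy as np
import pandas as pd
import pytest

from ppickd.simulate import SimulationConfig, simulate_cohort

logging.disable(logging.WARNING)


RECOVERY_LOG_HR = {"ppi": float(np.log(1.5)), "age70": float(np.log(2.39)),
                   "female": 0.04, "hypertension": 0.16, "diabetes": 0.36}


def make_cohort(seed, n, **overrides):
    cfg = SimulationConfig(seed=seed, n_participants=n, **overrides)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small cohort shared by read-only tests."""
    return make_cohort(seed=42, n=400)


def random_counting_table(rng, n_subjects=20, t_max=100.0):
    """Random valid start-stop table (contiguous intervals per subject)."""
    rows = []
    for pid in range(n_subjects):
        entry = rng.uniform(0, 0.5 * t_max)
        end = rng.uniform(entry + 1.0, t_max)
        cuts = np.unique(np.concatenate(
            [[entry, end], rng.uniform(entry, end, rng.integers(0, 4))]))
        status = int(rng.random() < 0.6)
        for i, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
            rows.append({"participant_id": pid, "start": lo, "stop": hi,
                         "status": status if i == len(cuts) - 2 else 0,
                         "x": float(rng.random() < 0.5)})
    return pd.DataFrame(rows)
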