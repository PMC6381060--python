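import numpy as np
import pytest

from skewadapt import DirectionGrid, run_experiment, summarize_trials, variant_params
from skewadapt import protocols

SEED = 11


@pytest.fixture(scope="session")
def grid():
    return DirectionGrid.default()


@pytest.fixture(scope="session")
def half_grid():
    return DirectionGrid.half_circle()


@pytest.fixture(scope="session")
def session_cache(grid):
    """Lazily computed, cached simulated sessions shared across tests.

    Keys: (variant, experiment, mode) with mode in {"std", "null", "mirror"}.
    Values: dict with "trials" and "summary".
    """
    cache = {}

    def get(variant: int, experiment: int, mode: str = "std"):
        key = (variant, experiment, mode)
        if key not in cache:
            params = variant_params(variant)
            sched = protocols.build_schedule(experiment, SEED)
            if mode == "null":
                sched = protocols.null_schedule(experiment, SEED)
            elif mode == "mirror":
                sched = protocols.mirrored_schedule(sched)
            trials = run_experiment(params, sched, grid=grid)
            res = summarize_trials(trials)
            cache[key] = {"trials": trials, "summary": res["summary"], "fits": res["fits"]}
        return cache[key]

    return get
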