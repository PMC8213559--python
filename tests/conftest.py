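import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import magest

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lum():
    return magest.luminance_stimulus_table()


@pytest.fixture(scope="session")
def red():
    return magest.red_stimulus_table()


def make_dataset(
    stimulus_set,
    method="standard",
    mean_a=0.45,
    sd_a=0.15,
    noise_sd=0.04,
    n_participants=8,
    n_reps=5,
    seed=0,
    **kwargs,
):
    pop = magest.PopulationSpec(
        mean_a=mean_a,
        sd_a=sd_a,
        noise_sd=noise_sd,
        n_participants=n_participants,
        n_reps=n_reps,
        seed=seed,
        **kwargs,
    )
    participants = magest.draw_participants(pop)
    return magest.simulate_ratings(participants, stimulus_set, method, pop), pop, participants


@pytest.fixture(scope="session")
def power_fit_small(lum):
    """One reduced-draw power-law fit on a small power-generated dataset,
    shared by model, comparison and PPC tests."""
    ds, pop, participants = make_dataset(lum, n_participants=8, seed=21)
    clean, _ = magest.preprocess(ds)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = magest.fit(
            magest.PowerModelSpec(), clean, chains=4, warmup=800, total_draws=3000, seed=22
        )
    return {"dataset": clean, "pop": pop, "participants": participants, "samples": samples}


def anova_frame(rows):
    """Build a RatingDataset-compatible trial frame from (pid, method, sid,
    intensity, response, direction) tuples."""
    recs = [
        (pid, method, sid, inten, resp, direction, t)
        for t, (pid, method, sid, inten, resp, direction) in enumerate(rows)
    ]
    return pd.DataFrame(
        recs,
        columns=[
            "participant_id",
            "method",
            "stimulus_id",
            "intensity",
            "response",
            "direction",
            "trial_index",
        ],
    )
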