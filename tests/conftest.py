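import numpy as np
import pandas as pd
import pytest

from coldsong import synthetic


@pytest.fixture(scope="session")
def survival_table():
    """Default study-design survival table: 19 lines x 2 sexes x 2 trts x 4 vials."""
    return synthetic.gen_survival_table(synthetic.SurvivalSimParams(seed=11))


@pytest.fixture(scope="session")
def courtship_table():
    return synthetic.gen_courtship_table(synthetic.CourtshipSimParams(seed=11))


@pytest.fixture(scope="session")
def song_params():
    return synthetic.SongSimParams(seed=11)


def make_survival_frame(rows):
    """rows: (line, sex, treatment, replicate, n_tested, n_survived)."""
    return pd.DataFrame(rows, columns=["line", "sex", "treatment", "replicate",
                                       "n_tested", "n_survived"])


def make_obs(rows):
    """rows: dicts with courtship-observation columns; defaults filled in."""
    defaults = {"line": "L1", "male_trt": "control", "female_trt": "control",
                "replicate": 1, "courted": True, "latency_s": 100.0,
                "duration_s": 200.0, "mated": True, "screen_length_s": 14_400.0}
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
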