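import pandas as pd
import pytest

from beautyvar import (RatingTable, SimulationConfig, default_archetypes,
                       simulate_ratings)


def make_table(rows):
    """rows: (participant, image, session, beauty[, typicality[, condition]])."""
    cols = ["participant_id", "image_id", "session", "beauty",
            "typicality", "condition"]
    padded = [list(r) + [None] * (6 - len(r)) for r in rows]
    return RatingTable(pd.DataFrame(padded, columns=cols))


@pytest.fixture
def tiny_table():
    """Three raters, one image, one session."""
    return make_table([("p1", "img1", 1, 1, 4),
                       ("p2", "img1", 1, 3, 4),
                       ("p3", "img1", 1, 5, 4)])


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_participants=60,
                            archetypes=default_archetypes(4, 4, 2),
                            seed=20240608)


@pytest.fixture(scope="session")
def sim_table(sim_config):
    """One moderately sized simulated study, shared across tests."""
    return simulate_ratings(sim_config)
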