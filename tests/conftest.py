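import matplotlib
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def normalized_table(rows):
    """Build a normalized viability table from (compound, dose_a, dose_b, survival)."""
    return pd.DataFrame(rows, columns=["compound_id", "dose_a_nM", "dose_b_nM", "survival"]).assign(
        n_replicates=3
    )


@pytest.fixture
def hill_agents():
    from synerscreen import AgentModel

    return AgentModel(100.0, 2.0), AgentModel(800.0, 1.0)
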