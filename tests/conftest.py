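import numpy as np
import pandas as pd
import pytest

from lfqpanel import SimulationConfig, simulate_study
from lfqpanel.quantify import quantify_study


@pytest.fixture
def tiny_metadata():
    """Two technical replicates for 2 samples per group."""
    rows = []
    for g in ("NC", "T2DM", "VD", "DVD"):
        for j in (1, 2):
            for r in (1, 2):
                rows.append({"sample": f"{g}{j}", "group": g, "replicate": r})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by several test modules (session-scoped
    for speed; tests must not mutate it)."""
    specs = tuple((f"SIM{i + 1:05d}", 0.95) for i in range(5))
    config = SimulationConfig(
        n_proteins=120, seed=4, marker_specs=specs, dep_fraction=0.1,
        group_specific_fraction=0.05, dep_log2fc_range=(2.0, 3.0),
        baseline_log2_sd=1.0,
    )
    table, metadata, truth = simulate_study(config)
    return table, metadata, truth


@pytest.fixture(scope="session")
def small_matrix(small_study):
    table, metadata, truth = small_study
    return quantify_study(table, metadata), metadata, truth


def make_labeled(rng, n_cases=12, n_controls=57, shift=1.0):
    from lfqpanel import LabeledScores

    scores = np.concatenate(
        [rng.normal(shift, 1.0, n_cases), rng.normal(0.0, 1.0, n_controls)]
    )
    labels = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    return LabeledScores(scores, labels)
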