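import numpy as np
import pytest

import srtrace as st


@pytest.fixture(scope="session")
def modular_graph():
    return st.build_graph("modular")


@pytest.fixture(scope="session")
def lattice_graph():
    return st.build_graph("lattice")


@pytest.fixture(scope="session")
def short_walk(modular_graph):
    return st.random_walk(modular_graph, 400, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects from the combined recency + SR-TD model."""
    from srtrace.synthetic_data import GenerativeConfig, simulate_population

    cfg = GenerativeConfig(n_subjects=6, n_trials=900, seed=314)
    sessions, truth, manifest = simulate_population(cfg)
    return sessions, truth, manifest
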