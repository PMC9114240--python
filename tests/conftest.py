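import numpy as np
import pytest

from tdsmc import (
    AttributeScheme,
    TDSSequence,
    chocolate_like_config,
    chocolate_scheme,
    extract_durations,
    simulate_panel,
)


@pytest.fixture(scope="session")
def scheme9():
    return chocolate_scheme()


@pytest.fixture(scope="session")
def scheme_small():
    """Four attributes in two groups, for compact fitting fixtures."""
    return AttributeScheme(
        labels=("A1", "A2", "A3", "A4"), group_of=(0, 0, 1, 1), group_names=("X", "Y")
    )


@pytest.fixture(scope="session")
def fig1_sequences():
    """A tiny panel whose 3rd panelist has attribute-A1 spells of 2, 3 and 3 s."""
    return [
        TDSSequence.from_runs("p1", [(1, 4), (2, 2)]),
        TDSSequence.from_runs("p2", [(0, 3), (1, 1), (3, 2)]),
        TDSSequence.from_runs("p3", [(0, 2), (1, 1), (0, 3), (2, 2), (0, 3)]),
    ]


@pytest.fixture(scope="session")
def choc_panel():
    """One simulated chocolate-like panel (54 panelists), shared across tests."""
    config = chocolate_like_config(seed=123)
    covariates, sequences, truth = simulate_panel(config)
    return config, covariates, sequences, truth


@pytest.fixture(scope="session")
def choc_durations(choc_panel):
    config, _, sequences, _ = choc_panel
    return extract_durations(sequences, config.scheme)


def random_sequences(rng: np.random.Generator, scheme, n_panelists, mean_runs=4):
    """Random panel that observes every attribute group at least once."""
    while True:
        seqs = []
        for i in range(n_panelists):
            n_runs = 1 + rng.poisson(mean_runs)
            attrs = rng.integers(0, scheme.n_attributes, size=n_runs)
            durs = 1 + rng.poisson(3.0, size=n_runs)
            seqs.append(
                TDSSequence.from_runs(f"p{i + 1}", list(zip(attrs.tolist(), durs.tolist())))
            )
        seen = {scheme.group_of[a] for s in seqs for a, _ in s.runs}
        if len(seen) == scheme.n_groups:
            return seqs
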