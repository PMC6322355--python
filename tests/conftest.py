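import numpy as np
import pytest

import mtindex as m


@pytest.fixture(scope="session")
def published_table() -> m.ScoreTable:
    """Packaged per-structure docking scores of the published screen."""
    return m.load_published_scores()


@pytest.fixture(scope="session")
def published_agg(published_table) -> m.AggregatedScores:
    return m.aggregate_ensemble(published_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


LIGAND_C1 = m.AtomSelection(resname="LIG", names=frozenset(["C1"]))
SERINE_OG = m.AtomSelection(resname="SER", names=frozenset(["OG"]))


@pytest.fixture()
def ligand_c1() -> m.AtomSelection:
    return LIGAND_C1


@pytest.fixture()
def serine_og() -> m.AtomSelection:
    return SERINE_OG
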