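import numpy as np
import pandas as pd
import pytest

from woundca.geometry import BOUNDARY_PAIRS
from woundca.synthetic import StudyConfig, generate_study, generate_worked_fixture


@pytest.fixture(scope="session")
def worked():
    """The shipped 9-gene worked example: (SignalMatrix, catalog, truth)."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_study():
    """A 600-gene synthetic study with planted patterns and enriched terms."""
    config = StudyConfig(n_genes=600, n_terms=24, term_size=20, seed=11)
    return config, *generate_study(config)


def boundary_side_accuracy(line, fc: pd.DataFrame, coords: pd.DataFrame) -> float:
    """Fraction of strictly-ordered genes a fitted boundary line separates correctly.

    Genes with FC_a > FC_b should land on one side of the a-vs-b boundary and
    genes with FC_a < FC_b on the other; the side-to-class assignment is the
    majority one, so a perfect separator scores 1.0 regardless of orientation.
    """
    a, b = BOUNDARY_PAIRS[line.boundary_id]
    vals = fc.to_numpy()
    strict = vals[:, a] != vals[:, b]
    above = vals[strict, a] > vals[strict, b]
    side = line.side(coords.to_numpy()[strict, :2]) > 0
    agree = (above == side).sum()
    return max(agree, strict.sum() - agree) / strict.sum()
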