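import warnings

import numpy as np
import pandas as pd
import pytest

from mimet import AbundanceTable, make_reference, methods_fixture, simulate_paired_cohort


@pytest.fixture(scope="session")
def fixture_ref():
    """Tiny hand-built reference with the canonical KO linkage examples."""
    return methods_fixture()


@pytest.fixture(scope="session")
def synth_ref():
    return make_reference(seed=1)


@pytest.fixture(scope="session")
def strong_cohort(synth_ref):
    """Strong planted signal: fold change 8, n = 30/30."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_paired_cohort(synth_ref, fold_change=8.0, seed=1)


@pytest.fixture(scope="session")
def null_cohort(synth_ref):
    """No planted signal (fold change 1): case/control exchangeable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_paired_cohort(synth_ref, fold_change=1.0, seed=2)


def make_table(values, features=None, samples=None, metadata=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"cpd:F{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return AbundanceTable(
        pd.DataFrame(values, index=features, columns=samples), metadata
    )


@pytest.fixture
def toy_table():
    return make_table([[1.0, 0.0, 3.0], [0.0, 2.0, 5.0]], features=["ko:Ka", "ko:Kb"])
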