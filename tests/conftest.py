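import numpy as np
import pandas as pd
import pytest

from omicscreen.datatypes import OmicsMatrix, SampleAnnotation
from omicscreen.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_proteins=300, n_surface=100, n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A desk-scale cohort shared across tests (read-only)."""
    return simulate_cohort(small_config)


@pytest.fixture()
def toy_annotations() -> list[SampleAnnotation]:
    return [
        SampleAnnotation("s1", "BPH", "B1"),
        SampleAnnotation("s2", "BPH", "B1"),
        SampleAnnotation("s3", "tumor", "B1"),
        SampleAnnotation("s4", "tumor", "B1"),
        SampleAnnotation("ref1", "tumor", "B1", reference_flag=True),
    ]


def make_matrix(values, features=None, samples=None, layer="proteome") -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples), layer)
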