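import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mmagc.omics_data import OmicsStudy

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_study(
    n_genes: int = 6,
    n_omics: int = 2,
    n_samples: int = 40,
    seed: int = 0,
    study_id: str = "study1",
) -> OmicsStudy:
    """Small random study with labelled genes/samples for unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    omics = [
        pd.DataFrame(rng.standard_normal((n_genes, n_samples)),
                     index=genes, columns=samples)
        for _ in range(n_omics)
    ]
    return OmicsStudy(study_id=study_id, omics=omics,
                      omics_names=[f"om{v + 1}" for v in range(n_omics)])


@pytest.fixture
def small_study() -> OmicsStudy:
    return make_study()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
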