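import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from onplskit import (
    ModelSpec,
    MultiBlockDataset,
    OmicsBlock,
    SampleDesign,
    SimSpec,
    simulate_multiomics,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


DEFAULT_MODEL_SPEC = ModelSpec(
    n_global=2,
    n_local={("proteins", "transcripts"): 1},
    n_unique=1,
)


@pytest.fixture
def default_model_spec() -> ModelSpec:
    return ModelSpec(
        n_global=2,
        n_local={("proteins", "transcripts"): 1},
        n_unique=1,
    )


@pytest.fixture
def design9() -> SampleDesign:
    """Three genotypes x three biological replicates."""
    ids = [f"{g}-{r}" for g in ("WT", "AS-SOD9", "AS-SOD24") for r in (1, 2, 3)]
    return SampleDesign(
        sample_ids=tuple(ids),
        genotype_of={s: s.rsplit("-", 1)[0] for s in ids},
        reference_genotype="WT",
        replicate_index={s: int(s.rsplit("-", 1)[1]) for s in ids},
    )


def make_block(values, sample_ids=None, variable_ids=None, name="blk", state="raw"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(m)]
    variable_ids = variable_ids or [f"v{j+1}" for j in range(n)]
    return OmicsBlock(
        name=name,
        data=pd.DataFrame(values, index=sample_ids, columns=variable_ids),
        state=state,
    )


@pytest.fixture
def noiseless_sim():
    """Default-geometry simulation with no noise: recovery must be exact."""
    return simulate_multiomics(SimSpec(noise_sd=0.0, within_genotype_sd=0.0, seed=0))


@pytest.fixture
def noisy_sim():
    """Default noisy simulation (measurement sd 0.2, score sd 0.1)."""
    return simulate_multiomics(SimSpec(seed=0))
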