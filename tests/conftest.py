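import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rhizofun import FunctionTable, OtuTable, SampleDesign
from rhizofun.config import default_function_tags

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def design20() -> SampleDesign:
    return SampleDesign.balanced()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_otu() -> OtuTable:
    counts = pd.DataFrame(
        {"s1": [10, 5, 0], "s2": [0, 5, 1]},
        index=["otu1", "otu2", "otu3"],
    )
    return OtuTable(counts)


@pytest.fixture
def functions20(design20, rng) -> FunctionTable:
    tags = default_function_tags()
    values = pd.DataFrame(
        rng.normal(size=(20, len(tags))),
        index=design20.sample_ids,
        columns=list(tags),
    )
    return FunctionTable(values, tags=pd.Series(tags))


@pytest.fixture
def otu20(design20, rng) -> OtuTable:
    """Random 60-taxon community over the standard 20-sample design."""
    base = rng.lognormal(0.0, 2.0, 60)
    p = base / base.sum()
    counts = np.column_stack(
        [rng.multinomial(20000, p) for _ in range(20)]
    )
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"OTU{i:02d}" for i in range(60)],
            columns=design20.sample_ids,
        )
    )
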