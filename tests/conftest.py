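import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from tagdge.cleaning import TagCountTable
from tagdge.quantify import ExpressionProfile
from tagdge.reference import GeneCatalog, TagIndex
from tagdge.simulate import SimulationConfig, generate_catalog, generate_truth


def random_tag(rng: np.random.Generator) -> str:
    return "CATG" + "".join(rng.choice(list("ACGT"), size=17))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=200,
        gene_length_range=(100, 800),
        library_sizes=(100_000,) * 4,
        error_rate=0.01,
        frac_no_catg=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config) -> GeneCatalog:
    return generate_catalog(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_catalog):
    return generate_truth(small_config, small_catalog)


@pytest.fixture(scope="session")
def small_index(small_catalog) -> TagIndex:
    return TagIndex.build(small_catalog)


def make_profile(counts: dict, total_clean: int, library_id: str = "lib") -> ExpressionProfile:
    return ExpressionProfile(
        library_id=library_id,
        counts=pd.Series(counts, dtype=np.int64),
        total_clean=total_clean,
    )
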