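import numpy as np
import pandas as pd
import pytest

from sptime.io import NormalizedMatrix, filter_genes, normalize_log_cpm
from sptime.synthetic import SyntheticConfig, generate_section, _default_plane
from sptime.spatialtime import assign_spatialtime


@pytest.fixture(scope="session")
def small_config():
    """500-spot section with a reduced gene panel; fast for unit tests."""
    return SyntheticConfig(
        n_rows=20,
        n_cols=25,
        n_marker_genes_per_domain=10,
        n_gradient_genes_per_class=15,
        n_noise_genes=150,
        module_spec={"BMP": (10, 0.60, 0.0), "MAPK": (10, 0.50, 2.0)},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_section(small_config):
    return generate_section(small_config, "control")


@pytest.fixture(scope="session")
def small_norm(small_section):
    section, _ = small_section
    return normalize_log_cpm(filter_genes(section))


@pytest.fixture(scope="session")
def small_st(small_section):
    section, _ = small_section
    return assign_spatialtime(section, _default_plane(section.coords))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_norm(values, prefix="s"):
    """Wrap a dense array as a NormalizedMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormalizedMatrix(
        values=values,
        spot_ids=[f"{prefix}{i:04d}" for i in range(n)],
        gene_ids=[f"g{j:04d}" for j in range(g)],
        provenance={"section_id": prefix},
    )
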