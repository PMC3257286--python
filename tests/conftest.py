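import numpy as np
import pytest

from bindkin import RateTable, SelectionConfig, SyntheticSpec, generate
from bindkin.tables_io import DescriptorTable


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic benchmark with low noise and known supports."""
    spec = SyntheticSpec(
        n_complexes=120, n_descriptors=12, block_size=3, block_rho=0.4,
        support_on=(0, 3), support_off=(6, 9),
        noise_on=0.2, noise_off=0.2, dg_noise=0.2, seed=7,
    )
    return generate(spec)


@pytest.fixture()
def tiny_rate_table():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((20, 5))
    y = 1.0 + 2.0 * X[:, 0] - 1.5 * X[:, 2] + rng.normal(0, 0.1, 20)
    base = DescriptorTable(
        ids=[f"cmp{i:02d}" for i in range(20)],
        descriptor_names=[f"d{j}" for j in range(5)],
        values=X,
    )
    return RateTable(base=base, response_name="log10_kon", response=y)


@pytest.fixture()
def fast_selection_config():
    return SelectionConfig(population=5, folds=5, speculative_rounds=3, seed=0)
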