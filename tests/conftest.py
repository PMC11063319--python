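import numpy as np
import pandas as pd
import pytest

from methdriver import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A compact study: enough structure for every stage, fast to build."""
    return SimulationConfig(
        n_probes_meth=300,
        n_genes=520,
        n_per_group=8,
        n_planted_dmps=20,
        n_planted_degs=20,
        n_driver_pairs=10,
        n_modules=2,
        module_size=120,
        missing_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def two_block_expr():
    """Two clean 120-gene co-expression blocks, within-cor 0.7, between 0."""

    def _make(seed: int, n_samples: int = 16, block: int = 120):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(2):
            f = rng.standard_normal(n_samples)
            rows.append(
                np.sqrt(0.7) * f[None, :]
                + np.sqrt(0.3) * rng.standard_normal((block, n_samples))
            )
        x = np.vstack(rows)
        return pd.DataFrame(
            x,
            index=[f"G{i:04d}" for i in range(2 * block)],
            columns=[f"S{j}" for j in range(n_samples)],
        )

    return _make
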