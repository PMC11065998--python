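import numpy as np
import pandas as pd
import pytest

from cfmm.simulate import SimulationConfig, build_genome


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort configuration shared by unit tests."""
    return SimulationConfig(seed=11, n_cases=6, n_controls=6,
                            n_fragments=60_000, n_dmrs=20, n_null_regions=30)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_fragments(chroms, starts, ends, n_cpg=None, n_meth=None):
    n = len(starts)
    return pd.DataFrame({
        "chrom": chroms if not isinstance(chroms, str) else [chroms] * n,
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
        "n_cpg": np.asarray(n_cpg if n_cpg is not None else [0] * n, dtype=np.int64),
        "n_meth": np.asarray(n_meth if n_meth is not None else [0] * n, dtype=np.int64),
    })
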