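import numpy as np
import pytest

import targetdecon as td


@pytest.fixture(scope="session")
def small_benchmark() -> td.Benchmark:
    """A compact corpus: 400 compounds, 12-protein panel, 3 phenotypes."""
    params = td.BenchmarkParams(n_compounds=400, n_proteins=12, n_phenotypes=3)
    return td.generate_benchmark(params, seed=7)


@pytest.fixture(scope="session")
def small_pipeline(small_benchmark) -> td.PipelineResult:
    """One full L1 pipeline run on the compact corpus."""
    return td.run_pipeline(small_benchmark, reg_type="l1", seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
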