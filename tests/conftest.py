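import numpy as np
import pytest

from pathclass.io import filter_benchmark
from pathclass.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small 3-class synthetic dataset, filtered, for integration tests."""
    spec = SyntheticSpec(
        n_classes=3,
        pathways_per_class=5,
        proteins_per_pathway=(3, 7),
        universe_size=30,
        signature_terms_per_class=3,
        sequence_length=(30, 80),
        seed=7,
    )
    ds = generate(spec)
    pathways = filter_benchmark(ds.pathways, ds.proteins)
    return ds, pathways


@pytest.fixture(scope="session")
def bench_dataset():
    """The default study conditions: 6 classes x 20 pathways, 200-term universe."""
    ds = generate(SyntheticSpec(seed=2024))
    pathways = filter_benchmark(ds.pathways, ds.proteins)
    return ds, pathways
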