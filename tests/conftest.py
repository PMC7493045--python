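import numpy as np
import pytest

from clonotrace.synthetic import CNASegmentSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast lineage configuration for unit tests."""
    return SimConfig(
        genome_length=20_000_000,
        n_chromosomes=2,
        divisions_to_founder=40,
        mu_division=1.0,
        neurosphere_divisions=3,
        mu_reprogramming=3.0,
        mu_culture_per_passage=1.0,
        n_passages=3,
        n_germline_snps=100,
        seed=11,
    )


@pytest.fixture
def gain_config():
    """Default-scale config with the shared 38-Mb single-copy gain."""
    return SimConfig(
        seed=5,
        cna_segments=(
            CNASegmentSpec("chr2", 5_000_000, 43_000_000, 3, "pre_existing"),
        ),
    )
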