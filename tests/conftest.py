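import warnings

import pytest

from tiergene.model import ModelConfig
from tiergene.synth import SynthConfig, generate_corpus
from tiergene.training import train_model

# study conditions for the shared small corpus and models
BENCH_CFG = dict(low_t=0.45, high_t=0.60, max_exon_len=300, d=40)


@pytest.fixture(scope="session")
def bench_cfg() -> ModelConfig:
    return ModelConfig(**BENCH_CFG)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SynthConfig(seed=11, n_regions=8, region_length=4000, genes_per_region=(1, 2)))


@pytest.fixture(scope="session")
def medium_corpus():
    """Large enough to train well-conditioned k=4 emission models."""
    return generate_corpus(SynthConfig(seed=31, n_regions=60, region_length=4000, genes_per_region=(2, 2)))


@pytest.fixture(scope="session")
def trained_model(medium_corpus, bench_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_model(medium_corpus, bench_cfg, strategy="mle", tiered=True)


@pytest.fixture(scope="session")
def collapsed_model(medium_corpus, bench_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_model(medium_corpus, bench_cfg, strategy="mle", tiered=False)
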