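import pytest
from hypothesis import HealthCheck, settings

import ctsearch as cs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


#: desk-scale test configuration: small slices, small vocabulary
def small_config(vocab_k: int = 64, **kw) -> cs.RunConfig:
    return cs.RunConfig(
        vocab_k=vocab_k,
        descriptor=cs.DescriptorConfig(patch=16, stride=8),
        **kw,
    )


@pytest.fixture(scope="session")
def small_cfg() -> cs.RunConfig:
    return small_config()


@pytest.fixture(scope="session")
def corpus20():
    """20 mixed-class phantom studies at desk scale."""
    studies, truth = cs.generate_corpus(20, base_seed=42, image_size=64, n_slices=2)
    return studies, truth


@pytest.fixture(scope="session")
def indexed20(corpus20, small_cfg):
    studies, truth = corpus20
    vocab, idx = cs.build_initial_index(studies, small_cfg)
    return studies, truth, vocab, idx
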