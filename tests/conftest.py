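import pytest

from emrkg import synthetic


@pytest.fixture(scope="session")
def gen_cfg():
    return synthetic.GeneratorConfig(n_docs=20, seed=42)


@pytest.fixture(scope="session")
def dicts(gen_cfg):
    return synthetic.generate_dictionaries(gen_cfg)


@pytest.fixture(scope="session")
def corpus(gen_cfg, dicts):
    return synthetic.generate_corpus(gen_cfg, dicts)


@pytest.fixture(scope="session")
def tag_sequences(gen_cfg, dicts):
    return synthetic.generate_tag_sequences(gen_cfg, dicts)
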