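import warnings

import pytest

import symscreen as ss


@pytest.fixture(scope="session")
def dsm5():
    return ss.load_bundled("dsm5_adhd")


@pytest.fixture(scope="session")
def table5():
    return ss.load_bundled("table5_inattention")


@pytest.fixture(scope="session")
def table6():
    return ss.load_bundled("table6_hyperactivity")


@pytest.fixture(scope="session")
def stub():
    return ss.StubEmbedder(seed=1)


@pytest.fixture(autouse=True)
def _quiet_triple_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="sentence yielded no retained dependency triples"
        )
        yield
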