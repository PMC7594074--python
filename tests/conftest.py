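import pytest

from fairmi import (
    assess_use_case,
    build_matrix,
    builtin_profiles,
    generate_evidence,
)


def assess_bundle(bundle, overrides=None):
    return assess_use_case(bundle.query, bundle.metadata, bundle.registry,
                           bundle.retrieval, bundle.f4_flag, overrides)


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def bundles(profiles):
    return {p.use_case: generate_evidence(p, seed=1) for p in profiles}


@pytest.fixture(scope="session")
def canonical_matrix(bundles):
    """The six builtin use cases assessed into one matrix."""
    return build_matrix([assess_bundle(b) for b in bundles.values()])
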