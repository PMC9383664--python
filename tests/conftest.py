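import pytest

from provbackbone import build_running_example


@pytest.fixture(scope="session")
def running_example():
    """The six-step digital-pathology chain (store, blueprint), seed 1."""
    return build_running_example(seed=1)


@pytest.fixture()
def example_store(running_example):
    store, _ = running_example
    return store


@pytest.fixture()
def example_blueprint(running_example):
    _, blueprint = running_example
    return blueprint


@pytest.fixture()
def example_bundles(running_example):
    """All six finalized bundles, in step order."""
    store, blueprint = running_example
    return [
        store.fetch(step.service_url, step.bundle_id) for step in blueprint.steps
    ]
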