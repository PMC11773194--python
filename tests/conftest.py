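import pytest

from instancemaps import FIXTURE_NAMES, build


@pytest.fixture(scope="session")
def fixture_maps():
    """All worked-example maps, built once per session."""
    return {name: build(name) for name in FIXTURE_NAMES}


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_map(request, fixture_maps):
    return fixture_maps[request.param]
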