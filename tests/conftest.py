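import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=30, derandomize=True)
settings.load_profile("suite")

from mitschema import build_reference_mit


@pytest.fixture(scope="session")
def reference():
    return build_reference_mit()
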