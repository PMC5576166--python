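import hypothesis
import pytest

from healthequity import load_mongolia_2014

hypothesis.settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def mongolia():
    """The packaged 22-region Mongolia 2014 table."""
    return load_mongolia_2014()
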