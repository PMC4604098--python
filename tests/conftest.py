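import pytest
from hypothesis import settings

from _helpers import dag_from_edges

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def diamond_dag():
    # d is_a b, d is_a c, b is_a a, c is_a a
    return dag_from_edges("abcd", [("d", "b"), ("d", "c"), ("b", "a"), ("c", "a")])
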