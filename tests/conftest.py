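import pytest

from ensimito.io import load_reference_annotation
from ensimito.synthetic import default_recipe, generate_mitogenome


@pytest.fixture(scope="session")
def reference_table():
    """The published 16144 bp annotation (coordinates only)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def bundle():
    """One planted synthetic mitogenome with known truth."""
    return generate_mitogenome(default_recipe(seed=7))
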