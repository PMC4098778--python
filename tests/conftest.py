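import pytest

from olipred.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_gen():
    """A desk-scale planted-motif dataset shared across tests."""
    spec = SyntheticSpec(
        n_pos=30, n_neg=60, length_range=(80, 200), seed=7,
        structure_mode="hairpin-toy",
    )
    return generate(spec)
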