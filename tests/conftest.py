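import pytest

from ghx.synthetic_data import GeneratorConfig, generate_dataset, make_reference


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean dataset (no decoys) shared across tests."""
    return generate_dataset(GeneratorConfig(n_class_a=20, n_class_b=20, seed=11))


@pytest.fixture(scope="session")
def decoy_dataset():
    """A dataset with 10% of each decoy type injected."""
    return generate_dataset(GeneratorConfig(
        n_class_a=25, n_class_b=25, seed=13,
        decoy_frac_no_qcgg=0.1, decoy_frac_loop_deleted=0.1, decoy_frac_truncated=0.1,
    ))


@pytest.fixture(scope="session")
def reference_model():
    _, model = make_reference(GeneratorConfig(seed=11))
    return model
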