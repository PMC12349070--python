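import pytest

from silcspp import chem, synthetic_data


@pytest.fixture(scope="session")
def ruleset():
    return chem.builtin_ruleset()


@pytest.fixture(scope="session")
def flax_spec():
    return synthetic_data.builtin_flax_spec()


@pytest.fixture(scope="session")
def flax_kinetics(flax_spec):
    return synthetic_data.simulate_kinetics(flax_spec)


@pytest.fixture(scope="session")
def clean_flax(flax_spec, flax_kinetics):
    """Noise-free synthetic feeding experiment with its ground truth."""
    features, design, truth = synthetic_data.emit_feature_table(
        flax_spec, flax_kinetics, cv=0.0, mz_sigma=0.0, rt_jitter=0.0, lod=0.0, seed=0
    )
    return features, design, truth
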