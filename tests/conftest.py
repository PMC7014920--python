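import numpy as np
import pytest

from cytomap.synthetic import area_template, build_laminar_template, generate_profile_sequence


@pytest.fixture(scope="session")
def dense_template():
    return area_template("granular_dense")


@pytest.fixture(scope="session")
def weak_template():
    return area_template("granular_weak")


@pytest.fixture(scope="session")
def dysgranular_template():
    return area_template("dysgranular")


@pytest.fixture
def step_template():
    return build_laminar_template([0.5, 1.0], [0.2, 0.6], 0.0)


@pytest.fixture
def two_area_sequence(dense_template, weak_template):
    """120 profiles, planted border at 60, fixed seed."""
    from cytomap.profiles import featurize_sequence

    seq, truth = generate_profile_sequence(
        [dense_template, weak_template], [60, 60], noise_sd=0.05, seed=42
    )
    featurize_sequence(seq)
    return seq, truth


@pytest.fixture
def null_sequence(dense_template):
    from cytomap.profiles import featurize_sequence

    seq, truth = generate_profile_sequence([dense_template], [120], noise_sd=0.05, seed=7)
    featurize_sequence(seq)
    return seq, truth
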