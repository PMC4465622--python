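import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def ontologies():
    from osteomorph import builtin_ontologies

    return builtin_ontologies()


@pytest.fixture
def bone_larva(ontologies):
    """One complete bone-stained larva on the stylized template."""
    from osteomorph import AnnotatedLarva
    from osteomorph.synthetic import bone_template_coords

    return AnnotatedLarva("L1", "control", "alizarin_red", bone_template_coords())
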