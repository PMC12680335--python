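import numpy as np
import pytest

from triadglm.design import ModelSpec, build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def joint_design():
    """Free fetal + complementary interaction: the paper-focused joint model."""
    return build_design(ModelSpec(fetal="free", parental_interaction="complementary"))


@pytest.fixture
def dose_design():
    return build_design(ModelSpec(fetal="dose", parental_interaction="none"))
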