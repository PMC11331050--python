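import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# scikit-image 0.26 renames some morphology parameters; the package handles
# both, and the deprecation chatter would otherwise drown test output
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
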