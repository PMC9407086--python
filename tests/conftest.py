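import numpy as np
import pytest

from ylineage.profiles import STRProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_profile(sample_id, population, calls):
    """Shorthand profile builder: calls values may be scalars or lists."""
    return STRProfile(
        sample_id=sample_id,
        population=population,
        calls={
            locus: (list(v) if isinstance(v, (list, tuple)) else [v])
            for locus, v in calls.items()
        },
    )


@pytest.fixture
def profile_factory():
    return make_profile
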