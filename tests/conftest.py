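import numpy as np
import pytest

from ctstain import PhantomSpec, extract_line_profile, generate_phantom_slice, normalise_cohort

# Compact phantoms keep detector tests fast; pixel size stays at the
# 7.5 um scanning resolution so gradient thresholds are exercised at the
# spacing they were designed for.


@pytest.fixture
def sat_spec():
    return PhantomSpec(
        mode="saturating", radius0_mm=0.9, I0=0.1, Imax=0.6, k0=1.0, c_k=0.3,
        noise_sigma=0.0, stain="I2KI", sample_id="sat",
    )


@pytest.fixture
def front_spec():
    return PhantomSpec(
        mode="front", radius0_mm=0.9, C=0.8, K=0.5, front_width_mm=0.2,
        I_in=0.1, I_out=0.65, noise_sigma=0.0, stain="PTA", sample_id="frt",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def profile_of(spec, t):
    """Normalised centre profile of a single phantom slice."""
    sl, truth = generate_phantom_slice(spec, t)
    p = normalise_cohort([extract_line_profile(sl)])[0]
    return p, sl, truth
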