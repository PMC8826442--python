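import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spongeground as sg
from spongeground import defaults as dflt

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def size_spec():
    return sg.SizeDistributionSpec()


@pytest.fixture(scope="session")
def categories():
    return dflt.DEFAULT_CATEGORIES


@pytest.fixture(scope="session")
def default_sources():
    return dflt.default_sources()


@pytest.fixture(scope="session")
def tef_scenarios():
    return dflt.TEF_SCENARIOS


@pytest.fixture(scope="session")
def adult_consumers():
    """Adult G. parva samples reconstituted with exact group moments."""
    groups = [
        g
        for g in dflt.REFERENCE_ISOTOPE_GROUPS
        if g.group in dflt.ADULT_GPARVA_GROUPS
    ]
    return sg.generate_isotopes(groups, seed=1, exact_moments=True)[["d13C", "d15N"]]


def make_image(lengths, area=1.0, category="c", n_juveniles=0, image_id="img"):
    from spongeground.survey import Observation, SurveyImage

    obs = [Observation(float(L), 0.8 * float(L), False) for L in lengths]
    obs += [Observation(np.nan, np.nan, True)] * n_juveniles
    return SurveyImage(
        image_id=image_id, area_m2=area, depth_m=700.0, category=category, observations=obs
    )


@pytest.fixture
def image_factory():
    return make_image
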