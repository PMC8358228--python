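import pytest

from scrollsaw.config import DEFAULT_GROUPS
from scrollsaw.evomodel import build_poisson, build_wag
from scrollsaw.simulate import SimConfig, sim_family


@pytest.fixture(scope="session")
def wag():
    return build_wag()


@pytest.fixture(scope="session")
def poisson():
    return build_poisson()


@pytest.fixture(scope="session")
def small_family():
    """A compact multi-paralog family (5 groups x 2 species x 3 paralogs)."""
    cfg = SimConfig(seed=11, groups=list(DEFAULT_GROUPS[:5]),
                    species_per_group=2, n_paralogs=3)
    return sim_family(cfg)
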