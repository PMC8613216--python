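import numpy as np
import pytest

from hrdcc.io import EventMatrix
from hrdcc.panels import default_templates, make_panel
from hrdcc.simulate import BLOOD_PROPORTIONS, MILK_PROPORTIONS, simulate_sample


@pytest.fixture(scope="session")
def blood_myeloid_panel():
    return make_panel("blood-5c")


@pytest.fixture(scope="session")
def blood_myeloid_templates(blood_myeloid_panel):
    return default_templates(blood_myeloid_panel)


@pytest.fixture(scope="session")
def blood_sample(blood_myeloid_panel, blood_myeloid_templates):
    """One realistic 20k-event blood myeloid acquisition (3% doublets,
    5% dead, 5% debris)."""
    return simulate_sample(
        blood_myeloid_panel, blood_myeloid_templates, BLOOD_PROPORTIONS,
        20_000, doublet_rate=0.03, dead_rate=0.05, debris_rate=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def milk_sample():
    pan = make_panel("milk-6c")
    tmpls = default_templates(pan)
    mix = {k: v * 0.92 for k, v in MILK_PROPORTIONS.items()}
    mix["MEC"] = 0.08
    return simulate_sample(pan, tmpls, mix, 20_000, doublet_rate=0.03,
                           dead_rate=0.05, debris_rate=0.05, seed=43)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    vals = np.abs(rng.normal(100, 20, size=(30, 4)))
    return EventMatrix(vals, ["FSC-A", "SSC-A", "CD45", "CD14"])
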