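import numpy as np
import pandas as pd
import pytest

import anchorgm as agm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160204)


@pytest.fixture(scope="session")
def tree13():
    """A fixed 13-tip pure-birth tree of unit depth."""
    return agm.yule_tree(13, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean simulated collection (4 species x 5 specimens)."""
    return agm.simulate_dataset(n_tips=4, n_per_species=5, seed=11)


@pytest.fixture(scope="session")
def small_shape(small_dataset):
    return agm.two_stage_alignment(small_dataset.specimens)


def random_configuration(rng, n=11, scale=50.0):
    """A random non-degenerate landmark configuration."""
    while True:
        coords = rng.uniform(-scale, scale, size=(n, 2))
        if agm.centroid_size(coords) > 1e-3:
            return coords


def mirror_specimen(scale=1.0, species="spX", sid="s1"):
    """A specimen whose left anchors are exact mirror images of the right ones."""
    template = agm.template_anchor().coords * scale
    anchors = {}
    for anchor_type, offset in (("ventral", 0.0), ("dorsal", 3.0)):
        right = template + offset
        left = right * np.array([-1.0, 1.0])
        anchors[(anchor_type, "right")] = agm.LandmarkConfiguration(
            right, id=sid, side="right", anchor_type=anchor_type
        )
        anchors[(anchor_type, "left")] = agm.LandmarkConfiguration(
            left, id=sid, side="left", anchor_type=anchor_type
        )
    return agm.SpecimenRecord(id=sid, species=species, anchors=anchors)
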