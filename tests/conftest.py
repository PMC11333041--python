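import numpy as np
import pytest

from cemap import GeneratorConfig, ImagingModel, generate_dataset
from cemap.synthetic import ContactGeometry, GroundTruth, PunctaLayout, SyntheticScene


def scene_with_disks(disks, half=3.0):
    """Expanded scene holding the given (u, v, radius) GJ disks."""
    geom = ContactGeometry(a=half, b=half, concavity=0.0)
    layout = PunctaLayout(
        gj=np.asarray(disks, dtype=float),
        glur2=np.zeros((0, 3)),
        min_edge_gap=0.1,
        aj_guard=0.05,
    )
    areas = layout.gj_areas()
    gt = GroundTruth(
        n_puncta=len(disks),
        punctum_areas_pre=areas / 15.21,
        punctum_areas=areas,
        contact_long_diameter_pre=2 * half / 3.9,
        contact_short_diameter_pre=2 * half / 3.9,
        contact_long_diameter=2 * half,
        contact_short_diameter=2 * half,
        glur2_count=0,
    )
    return SyntheticScene(geometry=geom, layout=layout, ground_truth=gt,
                          expanded=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_model():
    return ImagingModel()


@pytest.fixture(scope="session")
def enface_pairs():
    """Small rendered en-face dataset with GJ, AJ and GluR2 channels."""
    pairs, _ = generate_dataset(
        GeneratorConfig(),
        n_scenes=6,
        seed=11,
        channels=("Cx35.5", "Cx34.1", "N-cadherin", "GluR2"),
        view="en-face",
    )
    return pairs


@pytest.fixture(scope="session")
def noiseless_pairs():
    """Noise-free en-face scenes for exact-recovery checks."""
    pairs, _ = generate_dataset(
        GeneratorConfig(),
        n_scenes=3,
        seed=5,
        channels=("Cx35.5", "N-cadherin", "GluR2"),
        view="en-face",
        noise=False,
    )
    return pairs
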