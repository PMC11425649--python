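import numpy as np
import pytest

from tgsite.geometry import geometry_series
from tgsite.synthetic import (
    GeometryDistribution,
    GroundTruth,
    build_site,
    sample_frames,
)

# flagship synthetic conditions: a reference-like orientation mode (76°,
# 6.4 Å) alongside a dominant apo-like mode (~145°, long distance), two
# planted hydrogen bonds at the persistence levels discussed for the helix
# region (25%) and a strong bond (60%)
BIMODAL_COMPONENTS = (
    (0.55, 76.0, 5.0, 6.4, 0.5),
    (0.45, 145.0, 6.0, 10.5, 0.7),
)
SITE_SEED = 20
N_RECOVERY_FRAMES = 2000


@pytest.fixture(scope="session")
def pocket_site():
    return build_site(2, seed=SITE_SEED)


@pytest.fixture(scope="session")
def bimodal_truth(pocket_site):
    sers = [r.index for r in pocket_site.topology.residues if r.name == "SER"]
    asps = [r.index for r in pocket_site.topology.residues if r.name == "ASP"]
    return GroundTruth(
        geometry=GeometryDistribution(BIMODAL_COMPONENTS),
        hbond_occupancy={(sers[0], asps[0]): 0.25, (sers[1], asps[1]): 0.60},
        seed=SITE_SEED,
    )


@pytest.fixture(scope="session")
def bimodal_trajectory(pocket_site, bimodal_truth):
    return sample_frames(pocket_site, bimodal_truth, N_RECOVERY_FRAMES)


@pytest.fixture(scope="session")
def bimodal_records(bimodal_trajectory):
    return geometry_series(bimodal_trajectory, 2540, 2573)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
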