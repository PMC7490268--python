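"""Shared fixtures: small trees, simulated alignments, synthetic plates."""

import numpy as np
import pytest

from sporefit.repaint import crop_and_normalize, detect_wells
from sporefit.synth import CodonSimSpec, PlateSpec, generate_plate_image, simulate_codon_alignment
from sporefit.synth.plates import truth_mask_for_crop
from sporefit.trees import parse_newick

TREE_4TAXA = "((A:0.2,B:0.3):0.1,(C:0.15,D:0.25) #1:0.05);"
TREE_8TAXA = (
    "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
    "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1) #1:0.1):0.1);"
)
TREE_6TAXA = "((A:0.15,B:0.15):0.1,(C:0.15,D:0.15) #1:0.1,(E:0.2,F:0.2):0.05);"


@pytest.fixture(scope="session")
def tree4():
    return parse_newick(TREE_4TAXA)


@pytest.fixture(scope="session")
def tree8():
    return parse_newick(TREE_8TAXA)


@pytest.fixture(scope="session")
def tree6():
    return parse_newick(TREE_6TAXA)


@pytest.fixture(scope="session")
def m0_alignment(tree8):
    """A mid-sized alignment simulated under a single omega."""
    return simulate_codon_alignment(
        CodonSimSpec(
            tree=tree8, kappa=2.0, regime="M0", regime_params={"omega": 0.3},
            n_sites=400, seed=11,
        )
    )


def random_coverage_request(seed: int, n_wells: int = 96) -> np.ndarray:
    rng = np.random.default_rng(seed)
    h = rng.uniform(0, 60, n_wells)
    c = rng.uniform(0, 30, n_wells)
    s = h + c
    scale = np.where(s > 100, 95.0 / s, 1.0)
    return np.column_stack([h * scale, c * scale])


def make_plate(seed: int, **spec_kwargs):
    """Standard 96-well synthetic plate with a mixed coverage request."""
    spec = PlateSpec(seed=seed, **spec_kwargs)
    req = random_coverage_request(seed, spec.n_wells)
    image, truth = generate_plate_image(spec, req)
    return spec, req, image, truth


def annotated_crops(seed: int, n: int = 10, **spec_kwargs):
    """(crops, truth masks) from one synthetic plate."""
    _, _, image, truth = make_plate(seed, **spec_kwargs)
    regions = detect_wells(image)[:n]
    crops = [crop_and_normalize(image, r) for r in regions]
    masks = [truth_mask_for_crop(truth, c) for c in crops]
    return crops, masks


@pytest.fixture(scope="session")
def default_plate():
    return make_plate(seed=42)
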