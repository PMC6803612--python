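import numpy as np
import pytest

from petrad import PhantomConfig, generate_cohort
from petrad.image_io import VolumePair
from petrad.segmentation import segment_isocontour


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-patient phantom cohort shared across tests."""
    cfg = PhantomConfig(n_mutant=3, n_wild=3, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def uniform_lesion():
    """A uniform SUV-10 ball in a 0.5 background, with its segmented ROI."""
    pet = np.full((20, 20, 20), 0.5)
    zz, yy, xx = np.ogrid[:20, :20, :20]
    ball = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 5**2
    pet[ball] = 10.0
    ct = np.zeros_like(pet)
    pair = VolumePair(pet=pet, ct=ct, spacing=(2.0, 2.0, 2.0), patient_id="U1")
    roi = segment_isocontour(pet, (10, 10, 10))
    return pair, roi, ball


def make_pet(values, background=0.0, pad=1):
    """Embed a 2-D array as one hot slice of a 3-D PET grid."""
    values = np.asarray(values, dtype=float)
    grid = np.full(
        (1 + 2 * pad, values.shape[0] + 2 * pad, values.shape[1] + 2 * pad), background
    )
    grid[pad, pad:-pad, pad:-pad] = values
    return grid
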