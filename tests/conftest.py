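import numpy as np
import pytest

from organseg.phantom import OrganSpec, PhantomSpec, default_spec
from organseg.volumes import LabelVolume, VoxelVolume


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """A small, fast phantom spec: 3 mice x 2 scans on a 32x32x48 grid."""
    organs = (
        OrganSpec(1, "heart", (16.0, 16.0, 12.0), (5.0, 4.0, 4.0), 300.0),
        OrganSpec(2, "liver", (16.0, 16.0, 30.0), (6.0, 7.0, 8.0), 220.0),
    )
    return PhantomSpec(
        grid_shape=(32, 32, 48),
        organs=organs,
        body_center=(16.0, 16.0, 24.0),
        body_semi_axes=(15.0, 13.0, 22.0),
        n_mice=3,
        scans_per_mouse=2,
        jitter_shift_vx=1.5,
        jitter_rot_deg=4.0,
        shape_variability=0.05,
        annotator2_bias={2: 1},
        annotator_noise_sd=0.0,
        mets_per_organ=3,
        mets_background=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    from organseg.phantom import build_cohort

    return build_cohort(tiny_spec)


@pytest.fixture(scope="session")
def study_spec() -> PhantomSpec:
    """The standard study conditions (6 mice x 2 scans, 4 organs)."""
    return default_spec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, shape=(12, 14, 10), p=0.2,
                nonempty=True) -> np.ndarray:
    while True:
        m = rng.random(shape) < p
        if m.any() or not nonempty:
            return m


@pytest.fixture()
def label_pair(rng):
    """A ground-truth label volume and a dilated second annotation."""
    from organseg.phantom import simulate_annotator

    data = np.zeros((16, 16, 16), dtype=np.int32)
    data[4:9, 4:9, 4:9] = 1
    data[10:14, 10:14, 10:14] = 2
    truth = LabelVolume(data, (240.0, 240.0, 240.0), {1: "a", 2: "b"})
    other = simulate_annotator(truth, {1: 1}, 0.0, seed=0)
    return truth, other
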