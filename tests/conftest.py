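import numpy as np
import pytest

from delinmetrics import (
    Delineation,
    GroupParams,
    ObserverRecord,
    PhantomParams,
    SliceStack,
    StudyDataset,
    generate_phantom,
)


def square(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """Axis-aligned square/rectangle vertices (counter-clockwise)."""
    return np.array([[x0, y0], [x0, y1], [x1, y1], [x1, y0]], dtype=float)


def make_stack(set_id="s", n_slices=4, size=24, independent=False, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    imgs = [rng.integers(0, 4000, size=(size, size), dtype=np.uint16) for _ in range(n_slices)]
    masks = [np.ones((size, size), dtype=bool) for _ in range(n_slices)]
    return SliceStack(
        set_id=set_id,
        width=size,
        height=size,
        images={"T1": imgs},
        brain_masks=masks,
        independent_slices=independent,
        slice_location_labels=labels,
    )


@pytest.fixture(scope="session")
def toy_dataset():
    """Hand-built 5-observer study on one 4-slice 24x24 stack.

    Geometry (filled rasterized areas):
      E1: square (4,4)-(9,9)   -> 36 px, slices 0 and 1
      E2: square (6,6)-(11,11) -> 36 px, slices 0 and 1 (overlap with E1: 16)
      E3: square (16,16)-(19,19) -> 16 px, slice 1 only (disjoint from E1/E2)
      N1: square (4,4)-(9,9)   -> 36 px, slices 0 and 2
      N2: square (14,4)-(19,9) -> 36 px, slice 0 only (disjoint from N1)
    """
    stack = make_stack()

    def delins(oid, sq, slices):
        return [
            Delineation(observer_id=oid, set_id="s", slice_index=k, vertices=sq)
            for k in slices
        ]

    observers = [
        ObserverRecord("E1", "expert", delins("E1", square(4, 4, 9, 9), [0, 1]),
                       {"s": [0, 1, 2, 3]}),
        ObserverRecord("E2", "expert", delins("E2", square(6, 6, 11, 11), [0, 1]),
                       {"s": [0, 1, 1, 2, 3]}),
        ObserverRecord("E3", "expert", delins("E3", square(16, 16, 19, 19), [1]),
                       {"s": [0, 1, 2, 1, 2, 3]}),
        ObserverRecord("N1", "novice", delins("N1", square(4, 4, 9, 9), [0, 2]),
                       {"s": [0, 1, 2, 3]}),
        ObserverRecord("N2", "novice", delins("N2", square(14, 4, 19, 9), [0]),
                       {"s": [3, 2, 1, 0]}),
    ]
    ds = StudyDataset(stacks=[stack], observers=observers)
    ds.validate()
    return ds


SMALL = dict(
    n_slices=15,
    width=128,
    height=128,
    brain_ellipse=(54.0, 57.0),
    tumor_center=(75, 57, 7),
    tumor_semi_axes=(20.0, 15.0, 4.0),
)


@pytest.fixture(scope="session")
def small_phantom():
    """One 128x128, 15-slice phantom with ground truth (seed 11)."""
    params = PhantomParams(**SMALL)
    stack, gt = generate_phantom(params, seed=11, set_id="p")
    return params, stack, gt


@pytest.fixture(scope="session")
def zero_noise_groups():
    expert = GroupParams(jitter_sd=0.0, detect_floor=1.0, area_bias=1.0, revisit_rate=0.0)
    novice = GroupParams(jitter_sd=0.0, detect_floor=1.0, area_bias=1.0, revisit_rate=0.0)
    return expert, novice
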