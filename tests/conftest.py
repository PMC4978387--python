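import numpy as np
import pytest

import sfm


@pytest.fixture(scope="session")
def geometry66():
    """Default-size geometry: 33 ROIs per hemisphere."""
    return sfm.generate_geometry(33, seed=0)


@pytest.fixture(scope="session")
def scene66():
    """Default synthetic scene (66 ROIs, 64 sensors), shared across tests."""
    return sfm.generate_scene(33, 64, seed=1)


@pytest.fixture()
def toy_geometry():
    """Hand-checkable 4-ROI geometry: two homotopic pairs, simple distances."""
    centers = np.array(
        [[10.0, 0.0, 0.0], [10.0, 30.0, 0.0], [-10.0, 0.0, 0.0], [-10.0, 30.0, 0.0]]
    )
    diff = centers[:, None, :] - centers[None, :, :]
    euclid = np.linalg.norm(diff, axis=2)
    fiber = euclid * 1.3
    np.fill_diagonal(fiber, 0.0)
    return sfm.ROIGeometry(
        centers=centers,
        sizes=np.array([2.0, 4.0, 3.0, 5.0]),
        euclid_dist=euclid,
        fiber_dist=fiber,
        hemisphere=np.array(["R", "R", "L", "L"]),
        homotopic=np.array([2, 3, 0, 1]),
    )


@pytest.fixture()
def toy_raw(toy_geometry):
    F = np.array(
        [
            [0.0, 8.0, 2.0, 4.0],
            [8.0, 0.0, 6.0, 0.0],
            [2.0, 6.0, 0.0, 10.0],
            [4.0, 0.0, 10.0, 0.0],
        ]
    )
    lengths = np.where(F > 0, toy_geometry.fiber_dist, 0.0)
    return sfm.RawConnectome(
        fiber_counts=F, roi_sizes=toy_geometry.sizes, fiber_lengths=lengths
    )
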