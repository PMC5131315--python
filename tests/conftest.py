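import numpy as np
import pytest

from calcimem.io import GroupTag, Topology, Trajectory


def make_topology(n_atoms: int, tags=None, resnames=None, resids=None) -> Topology:
    """Minimal topology for hand-built trajectories."""
    tags = tags if tags is not None else [GroupTag.OTHER] * n_atoms
    return Topology(
        names=np.array([f"A{i}" for i in range(n_atoms)], dtype=object),
        resnames=np.array(resnames if resnames is not None else ["UNK"] * n_atoms, dtype=object),
        resids=np.array(resids if resids is not None else np.arange(1, n_atoms + 1), dtype=int),
        elements=np.array(["C"] * n_atoms, dtype=object),
        tags=np.array(tags, dtype=object),
    )


def make_trajectory(positions, box, tags=None, resids=None, times=None) -> Trajectory:
    """Trajectory from an (F, N, 3) array and one box."""
    positions = np.asarray(positions, float)
    if positions.ndim == 2:
        positions = positions[None]
    F, N, _ = positions.shape
    topo = make_topology(N, tags=tags, resids=resids)
    boxes = np.tile(np.asarray(box, float), (F, 1))
    times = np.arange(F, dtype=float) if times is None else np.asarray(times, float)
    return Trajectory(topo, positions, boxes, times)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
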