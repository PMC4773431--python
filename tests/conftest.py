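import numpy as np
import pytest

from embryotrack.model import Centre, CentreSet, LineageForest, VoxelGrid


@pytest.fixture
def iso_spacing():
    return (1.37, 1.37, 1.37)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_blob(shape, centre_vox, sigma_um, spacing, amplitude=100.0):
    """Render one Gaussian blob on a zero background (test phantom)."""
    zz, yy, xx = np.indices(shape, dtype=float)
    d2 = (((zz - centre_vox[0]) * spacing[0]) ** 2
          + ((yy - centre_vox[1]) * spacing[1]) ** 2
          + ((xx - centre_vox[2]) * spacing[2]) ** 2)
    return amplitude * np.exp(-d2 / (2.0 * sigma_um ** 2))


@pytest.fixture
def blob_grid(iso_spacing):
    values = gaussian_blob((24, 24, 24), (12, 12, 12), 3.0, iso_spacing, 150.0)
    return VoxelGrid(values, iso_spacing)


def straight_track_forest(n_frames=8, step=(1.0, 0.0, 0.0), start=(5.0, 5.0, 5.0)):
    """One cell moving in a straight line, one frame per step."""
    f = LineageForest()
    pos = np.asarray(start, dtype=float)
    for t in range(n_frames):
        f.add_centre(Centre(id=t, t=t, pos=tuple(pos + t * np.asarray(step))))
        if t > 0:
            f.add_link(t - 1, t)
    return f


def random_forest(rng, n_roots=20, n_frames=10, box=100.0, division_prob=0.05):
    """Random but invariant-satisfying lineage forest for round-trip tests."""
    f = LineageForest()
    next_id = 0
    alive = []
    for _ in range(n_roots):
        f.add_centre(Centre(id=next_id, t=0, pos=tuple(rng.uniform(0, box, 3))))
        alive.append(next_id)
        next_id += 1
    for t in range(1, n_frames):
        new_alive = []
        for cid in alive:
            n_kids = 2 if rng.random() < division_prob else 1
            base = np.asarray(f.centres[cid].pos)
            for _ in range(n_kids):
                pos = np.clip(base + rng.normal(0, 1.5, 3), 0, box)
                f.add_centre(Centre(id=next_id, t=t, pos=tuple(pos),
                                    virtual=bool(rng.random() < 0.02)))
                f.add_link(cid, next_id)
                new_alive.append(next_id)
                next_id += 1
        alive = new_alive
    f.validate()
    return f
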