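import numpy as np
import pytest

from phstab.structio import AtomRecord, Trajectory


def make_topology(n_atoms, chain="A", resname="GLY", atom_name="CA", element="C"):
    return [
        AtomRecord(chain, i + 1, resname, atom_name, element) for i in range(n_atoms)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_trajectory(rng):
    """10-frame, 6-atom random-walk trajectory for oracle comparisons."""
    topo = make_topology(6)
    ref = rng.uniform(-5, 5, size=(6, 3))
    frames = ref[None] + rng.normal(0, 0.5, size=(10, 6, 3))
    return Trajectory(topo, frames, frame_interval=5.0)


def hbond_triad_coords(d_da: float, angle_deg: float) -> np.ndarray:
    """Donor (origin), hydrogen (1 Å along +x), acceptor placed so that the
    donor-acceptor distance is d_da and the D-H-A angle is angle_deg."""
    donor = np.zeros(3)
    hydrogen = np.array([1.0, 0.0, 0.0])
    phi = np.radians(180.0 - angle_deg)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    w = hydrogen - donor
    b = 2.0 * float(w @ u)
    c = float(w @ w) - d_da**2
    L = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    acceptor = hydrogen + L * u
    return np.stack([donor, hydrogen, acceptor])


def hbond_triad_topology():
    return [
        AtomRecord("A", 1, "SER", "OG", "O"),
        AtomRecord("A", 1, "SER", "HG", "H"),
        AtomRecord("A", 2, "GLU", "OE1", "O"),
    ]
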