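import numpy as np
import pytest

from quasicryst.model_io import ChainTopology, MoleculeTable, SimulationBox, SnapshotFrame


@pytest.fixture
def pair_topology():
    """Minimal two-atom chain topology for vector-level unit tests."""
    return ChainTopology(residue_selector="resname XX",
                         backbone_atoms=("A", "B"),
                         anchor_orient=(1, 2), anchor_tilt=(1, 2), mid_atom=1)


def make_pair_frame(vectors, origins=None, box=None):
    """Frame of 2-atom 'molecules' with prescribed chain vectors."""
    vectors = np.atleast_2d(np.asarray(vectors, float))
    n = len(vectors)
    origins = (np.zeros((n, 3)) if origins is None
               else np.atleast_2d(np.asarray(origins, float)))
    coords = np.empty((2 * n, 3))
    coords[0::2] = origins
    coords[1::2] = origins + vectors
    table = MoleculeTable(np.arange(2 * n).reshape(n, 2),
                          np.full((n, 2), 12.011))
    frame = SnapshotFrame(time=0.0, coords=coords,
                          box=box or SimulationBox(50, 50, 50))
    return frame, table


@pytest.fixture
def rng():
    return np.random.default_rng(20230302)
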