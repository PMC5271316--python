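import numpy as np
import pytest

from fieldhb.io import FieldSpec
from fieldhb.synthetic import KineticGroundTruth, ToyAtom, ToyFrameSpec


@pytest.fixture
def field_12ghz():
    """The 12.5 GHz driving field at the study amplitude."""
    return FieldSpec(E0=4.2, freq=1.25e10)


@pytest.fixture
def standard_truth():
    """The reference Gillespie fixture for rate-recovery checks."""
    return KineticGroundTruth(k1=0.4, k1p=0.05, k2=0.7, k2p=0.05,
                              k_escape=0.02, n_pairs=5000, t_total=150.0,
                              dt=0.5, seed=11)


def make_triplet_spec(r, angle_deg, donor_water=True, acceptor_water=False,
                      box=30.0):
    """Toy frame with one donor–H–acceptor triplet at exact geometry.

    A second hydrogen completes the water donor; one extra protein heavy
    atom makes shell/heavy-atom selections non-degenerate.
    """
    from fieldhb.synthetic import hbond_triplet_positions

    pos = hbond_triplet_positions(r, angle_deg)
    d_res = ("TIP3", 10) if donor_water else ("ALA", 1)
    a_res = ("TIP3", 11) if acceptor_water else ("ALA", 1)
    atoms = [
        ToyAtom("OW" if donor_water else "OG", d_res[0], d_res[1],
                -0.834 if donor_water else -0.5, "O"),
        ToyAtom("HW1" if donor_water else "HG", d_res[0], d_res[1],
                0.417 if donor_water else 0.3, "H"),
        ToyAtom("OW" if acceptor_water else "O", a_res[0], a_res[1],
                -0.834 if acceptor_water else -0.5, "O"),
        ToyAtom("CA", "ALA", 1, 0.1, "C"),
    ]
    coords = np.zeros((1, 4, 3))
    coords[0, :3] = pos + 5.0     # keep away from the origin corner
    coords[0, 3] = pos[2] + 5.0 + np.array([2.5, 0.7, 0.4])
    return ToyFrameSpec(atoms=atoms, positions=coords,
                        box=np.array([box, box, box]))


@pytest.fixture
def triplet_spec_factory():
    return make_triplet_spec
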