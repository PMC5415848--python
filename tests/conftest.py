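import numpy as np
import pytest

from helixread.synthetic import EXTENDED_PHI_PSI, HELIX_PHI_PSI, make_ideal_chain

H3_10MER = "ARTKQTARKS"


@pytest.fixture(scope="session")
def helix_chain():
    return make_ideal_chain(H3_10MER, *HELIX_PHI_PSI)


@pytest.fixture(scope="session")
def extended_chain():
    return make_ideal_chain(H3_10MER, *EXTENDED_PHI_PSI)


def as_mdtraj(chain):
    """Convert a PeptideChain to a single-frame mdtraj Trajectory (nm)."""
    import mdtraj as md
    from mdtraj.core import element

    top = md.Topology()
    ch = top.add_chain()
    xyz = []
    for res in chain:
        r = top.add_residue(res.name, ch)
        for name in ("N", "CA", "C", "O"):
            el = {"N": element.nitrogen, "O": element.oxygen}.get(name, element.carbon)
            top.add_atom(name, el, r)
            xyz.append(res[name] / 10.0)
    return md.Trajectory(np.asarray(xyz)[None], top)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
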