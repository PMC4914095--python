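import numpy as np
import pytest

from kturnlab import (
    SimulationParams,
    make_annotation,
    simulate_structure,
)

MINIMAL_PDB = """\
ATOM      1  O2'   G N   5      -2.900   0.000   0.000  1.00 20.00           O
ATOM      2  N3    A B  14       0.000   0.000   0.000  1.00 20.00           N
ATOM      3  N1    A B  14       2.300   0.000   0.000  1.00 20.00           N
END
"""

ALTLOC_PDB = """\
ATOM      1  N3 A  A B  14       0.000   0.000   0.000  0.60 20.00           N
ATOM      2  N3 B  A B  14       9.000   9.000   9.000  0.40 20.00           N
END
"""

ALTLOC_TIE_PDB = """\
ATOM      1  N3 B  A B  14       9.000   9.000   9.000  0.50 20.00           N
ATOM      2  N3 A  A B  14       0.000   0.000   0.000  0.50 20.00           N
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def n3_instance():
    inst, _ = simulate_structure("N3", SimulationParams(seed=11, jitter_sd=0.0))
    return inst


@pytest.fixture
def n1_instance():
    inst, _ = simulate_structure("N1", SimulationParams(seed=12, jitter_sd=0.0))
    return inst


@pytest.fixture
def annotation():
    return make_annotation("fixture")


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-50, 50, size=3)
    return rot, trans


def apply_rigid_motion(instance, rot, trans):
    for res in instance.residues.values():
        for name in res.atoms:
            res.atoms[name] = rot @ res.atoms[name] + trans
    return instance
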