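"""Synthetic inputs: idealized k-turn cores and 3b,3n-controlled alignments.

The structure generator emits the minimal atom set the classifier needs
(plus full base atoms at 3b,3n so basepair-family typing can be exercised),
laid out so that every diagnostic distance hits its class target exactly at
zero jitter:

* N3 class: -1n O2' bonded to A2b N3 (2.9 A, N1 at 5.2 A), A2b N6 - G2n N3
  bonded (2.9 A), C1'-C1' widths 8.93 / 9.59 / 10.55 A at 2b2n / 3b3n / 4b4n.
* N1 class: -1n O2' bonded to A2b N1 (2.9 A, N3 at 5.2 A), N6 - N3 broken
  (4.6 A), widths 10.17 / 11.30 / 10.55 A.

The width targets are the class means observed across k-turn crystal
structures.  Noise is i.i.d. per-coordinate Gaussian jitter; nothing about
the backbone, sugar puckers or crystal packing is modeled, so these cores
probe the classifier's distance logic, not crystallographic reality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .seqprofile import Alignment, Freq4x4
from .structure_io import (
    KTurnAnnotation,
    KTurnInstance,
    ResidueAtoms,
    build_structure,
    write_structure,
)

CLASS_TARGETS = {
    "N3": {
        "d_O2p_N3": 2.9, "d_O2p_N1": 5.2, "d_N6_N3": 2.9, "d_L1_A1n": 2.7,
        "c1c1_2b2n": 8.93, "c1c1_3b3n": 9.59, "c1c1_4b4n": 10.55,
    },
    "N1": {
        "d_O2p_N3": 5.2, "d_O2p_N1": 2.9, "d_N6_N3": 4.6, "d_L1_A1n": 2.7,
        "c1c1_2b2n": 10.17, "c1c1_3b3n": 11.30, "c1c1_4b4n": 10.55,
    },
}

#: default 3b,3n identity per class (A*G is an N3 cell, U*G an N1 cell)
CLASS_DEFAULT_PAIR = {"N3": ("A", "G"), "N1": ("U", "G")}

#: conserved scaffold identities for the remaining positions
SCAFFOLD_IDENTITIES = {
    "-1b": "C", "-1n": "G", "L1": "G", "L2": "A", "L3": "A",
    "1b": "G", "1n": "A", "2b": "A", "2n": "G", "4b": "C", "4n": "G",
}

RESIDUE_NUMBERING = {
    # bulged strand, chain B, 5'->3'
    "-1b": ("B", 9), "L1": ("B", 10), "L2": ("B", 11), "L3": ("B", 12),
    "1b": ("B", 13), "2b": ("B", 14), "3b": ("B", 15), "4b": ("B", 16),
    # non-bulged strand, chain N, 5'->3' (antiparallel)
    "4n": ("N", 1), "3n": ("N", 2), "2n": ("N", 3), "1n": ("N", 4),
    "-1n": ("N", 5),
}


@dataclass
class SimulationParams:
    n: int = 1
    seed: int = 0
    jitter_sd: float = 0.0  # Angstrom, per coordinate
    freq: Optional[Freq4x4] = None
    flank_template: Optional[str] = None
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


# ---------------------------------------------------------------------------
# base geometry used for the 3b,3n pair
# ---------------------------------------------------------------------------

# planar base frames (x, y); the Watson-Crick edge is idealized onto the
# vertical line x = 4.0 with donors/acceptors at y = 0 and +/- 2.2
_PURINE_RING = {
    "N9": (0.0, 0.0), "C8": (-0.3, 1.3), "C4": (1.3, -0.4), "C5": (1.6, 1.0),
    "C2": (3.2, -1.3), "C6": (3.2, 1.3), "N7": (2.0, 2.6), "N3": (2.0, -2.6),
}
_PYRIMIDINE_RING = {
    "N1": (0.0, 0.0), "C2": (1.3, -0.7), "C4": (2.9, 1.2),
    "C5": (1.9, 2.2), "C6": (0.6, 1.9),
}
_BASE_FRAMES = {
    "A": {**_PURINE_RING, "N1": (4.0, 0.0), "N6": (4.0, 2.2)},
    "G": {**_PURINE_RING, "N1": (4.0, 0.0), "O6": (4.0, 2.2), "N2": (4.0, -2.2)},
    "C": {**_PYRIMIDINE_RING, "N3": (4.0, 0.0), "N4": (4.0, 2.2), "O2": (4.0, -2.2)},
    "U": {**_PYRIMIDINE_RING, "N3": (4.0, 0.0), "O4": (4.0, 2.2), "O2": (4.0, -2.2)},
}

_WC_SPAN = 10.9  # glycosidic-N separation putting facing WC edges 2.9 A apart


def _set_c1c1(c1_b: np.ndarray, c1_n: np.ndarray, target: float):
    """Move both C1' symmetrically along their joining line to the target
    separation (preserves which side of the pair axis each sits on)."""
    mid = 0.5 * (c1_b + c1_n)
    e = c1_n - c1_b
    e = e / np.linalg.norm(e)
    return mid - 0.5 * target * e, mid + 0.5 * target * e


def _wc_pair_atoms(base_b: str, base_n: str, c1c1: float):
    """A cis Watson-Crick-edge/Watson-Crick-edge pair of the two bases,
    built by mirroring the partner frame across the pair axis."""
    atoms_b = {k: np.array([x, y, 0.0]) for k, (x, y) in _BASE_FRAMES[base_b].items()}
    atoms_n = {
        k: np.array([_WC_SPAN - x, y, 0.0])
        for k, (x, y) in _BASE_FRAMES[base_n].items()
    }
    # both C1' on the same (-y) side of the glycosidic-N axis -> cis
    c1_b = np.array([(_WC_SPAN - c1c1) / 2.0, -1.1, 0.0])
    c1_n = np.array([(_WC_SPAN + c1c1) / 2.0, -1.1, 0.0])
    atoms_b["C1'"], atoms_n["C1'"] = _set_c1c1(c1_b, c1_n, c1c1)
    return atoms_b, atoms_n


def _trans_hs_pair_atoms(c1c1: float):
    """A trans Hoogsteen/sugar-edge A*G pair: the adenine Hoogsteen edge
    (N7, N6) hydrogen bonds to the guanine sugar edge (N3, N2), with the
    C1' atoms on opposite sides of the glycosidic-N axis."""
    atoms_a = {
        "N9": (0.0, 0.0), "C8": (0.2, 1.3), "N7": (1.5, 2.0), "C5": (2.4, 1.0),
        "C6": (3.8, 1.2), "N6": (4.6, 2.3), "N1": (4.4, 0.0), "C2": (3.6, -1.2),
        "N3": (2.3, -1.4), "C4": (1.4, -0.3), "C1'": (-0.8, -1.2),
    }
    atoms_g = {
        "N3": (1.5, 4.9), "N2": (4.6, 5.2), "C2": (2.9, 5.5), "N1": (3.5, 6.7),
        "C6": (2.7, 7.8), "O6": (3.2, 9.0), "C5": (1.3, 7.7), "N7": (0.3, 8.6),
        "C8": (-0.9, 7.9), "C4": (0.6, 6.2), "N9": (-0.3, 6.2), "C1'": (0.5, 7.4),
    }
    atoms_a = {k: np.array([x, y, 0.0]) for k, (x, y) in atoms_a.items()}
    atoms_g = {k: np.array([x, y, 0.0]) for k, (x, y) in atoms_g.items()}
    atoms_a["C1'"], atoms_g["C1'"] = _set_c1c1(
        atoms_a["C1'"], atoms_g["C1'"], c1c1
    )
    return atoms_a, atoms_g


def _pair_3b3n_atoms(base_b: str, base_n: str, c1c1: float):
    if (base_b, base_n) == ("A", "G"):
        return _trans_hs_pair_atoms(c1c1)
    return _wc_pair_atoms(base_b, base_n, c1c1)


# ---------------------------------------------------------------------------
# the template
# ---------------------------------------------------------------------------

@dataclass
class GeometryTemplate:
    """Idealized coordinates of one k-turn core, meeting its class targets
    exactly (verified to 1e-6 A at zero jitter)."""

    cls: str
    pair_3b3n: tuple[str, str]
    targets: Mapping[str, float]
    atoms: dict[str, dict[str, np.ndarray]]
    identities: dict[str, str]


def make_template(
    cls: str, pair_3b3n: Optional[tuple[str, str]] = None
) -> GeometryTemplate:
    if cls not in CLASS_TARGETS:
        raise ValueError(f"class must be N3 or N1, got {cls!r}")
    t = CLASS_TARGETS[cls]
    pair = tuple(pair_3b3n) if pair_3b3n else CLASS_DEFAULT_PAIR[cls]

    atoms: dict[str, dict[str, np.ndarray]] = {}

    # core cluster (z = 0): A2b base edge, the -1n O2' donor, G2n
    atoms["2b"] = {
        "N3": np.array([0.0, 0.0, 0.0]),
        "N1": np.array([2.3, 0.0, 0.0]),
        "N6": np.array([3.2, 1.2, 0.0]),
        "C1'": np.array([0.0, -5.0, 0.0]),
    }
    if cls == "N3":
        o2p = np.array([-t["d_O2p_N3"], 0.0, 0.0])  # 2.9 to N3, 5.2 to N1
    else:
        o2p = np.array([2.3 + t["d_O2p_N1"], 0.0, 0.0])  # 2.9 to N1, 5.2 to N3
    atoms["-1n"] = {"O2'": o2p, "C1'": o2p + np.array([0.0, -1.5, 0.0])}
    g2n_n3 = atoms["2b"]["N6"] + np.array([t["d_N6_N3"], 0.0, 0.0])
    atoms["2n"] = {
        "N3": g2n_n3,
        "N1": g2n_n3 + np.array([1.0, 2.0, 0.0]),
        "C1'": np.array([t["c1c1_2b2n"], -5.0, 0.0]),
    }
    l1_o2p = np.array([-8.0, 3.0, 0.0])
    atoms["L1"] = {"O2'": l1_o2p, "C1'": l1_o2p + np.array([0.0, -1.5, 0.0])}
    atoms["1n"] = {
        "N1": l1_o2p + np.array([t["d_L1_A1n"], 0.0, 0.0]),
        "C1'": l1_o2p + np.array([t["d_L1_A1n"], -1.5, 0.0]),
    }

    # 3b,3n pair, offset to z = 8 so its atoms cannot contact the core
    pair_b, pair_n = _pair_3b3n_atoms(pair[0], pair[1], t["c1c1_3b3n"])
    offset = np.array([0.0, 0.0, 8.0])
    atoms["3b"] = {k: v + offset for k, v in pair_b.items()}
    atoms["3n"] = {k: v + offset for k, v in pair_n.items()}

    # 4b,4n C1' pair at z = 16
    atoms["4b"] = {"C1'": np.array([0.0, 0.0, 16.0])}
    atoms["4n"] = {"C1'": np.array([t["c1c1_4b4n"], 0.0, 16.0])}

    # remaining scaffold positions carry a C1' marker only
    for i, label in enumerate(("-1b", "L2", "L3", "1b")):
        atoms[label] = {"C1'": np.array([4.0 * i, 0.0, -8.0])}

    identities = dict(SCAFFOLD_IDENTITIES)
    identities["3b"], identities["3n"] = pair
    return GeometryTemplate(
        cls=cls, pair_3b3n=pair, targets=t, atoms=atoms, identities=identities
    )


def make_annotation(instance_id: str) -> KTurnAnnotation:
    return KTurnAnnotation(
        instance_id,
        {lab: (ch, num, "") for lab, (ch, num) in RESIDUE_NUMBERING.items()},
    )


def _instance_from_atoms(
    atoms: Mapping[str, Mapping[str, np.ndarray]],
    identities: Mapping[str, str],
    instance_id: str,
    source: str,
) -> KTurnInstance:
    residues = {
        label: ResidueAtoms(
            label=label,
            residue_name=identities[label],
            base=identities[label],
            atoms={name: np.array(pos) for name, pos in atom_map.items()},
        )
        for label, atom_map in atoms.items()
    }
    return KTurnInstance(instance_id=instance_id, residues=residues, source=source)


def simulate_structure(
    cls: str,
    params: SimulationParams,
    pair_3b3n: Optional[tuple[str, str]] = None,
    pdb_path=None,
) -> tuple[KTurnInstance, KTurnAnnotation]:
    """One jittered copy of the class template (optionally written as PDB).

    Jitter is i.i.d. spherical Gaussian per atom, seeded; at jitter_sd = 0
    the template distances are reproduced exactly.
    """
    template = make_template(cls, pair_3b3n)
    rng = np.random.default_rng(params.seed)
    atoms = {
        label: {
            name: pos + rng.normal(0.0, params.jitter_sd, size=3)
            for name, pos in atom_map.items()
        }
        for label, atom_map in template.atoms.items()
    }
    instance_id = f"sim-{cls}-{params.seed}"
    annotation = make_annotation(instance_id)
    instance = _instance_from_atoms(
        atoms, template.identities, instance_id, source="synthetic"
    )
    if pdb_path is not None:
        st = build_structure(atoms, template.identities, annotation, name=instance_id)
        write_structure(st, pdb_path)
    return instance, annotation


def simulate_structures(
    cls: str,
    n: int,
    jitter_sd: float,
    seed: int,
    pair_3b3n: Optional[tuple[str, str]] = None,
) -> list[KTurnInstance]:
    """n independent copies; copy i uses a child seed derived from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [
        simulate_structure(
            cls,
            SimulationParams(n=1, seed=int(s), jitter_sd=jitter_sd),
            pair_3b3n=pair_3b3n,
        )[0]
        for s in seeds
    ]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

#: synthetic aligned k-turn region; lowercase b and n mark the 3b and 3n
#: columns, every other column is a fixed flank residue
DEFAULT_SCAFFOLD = "GCCGAUGAbGCGAAAGCnCGAUCGGC"

#: A Kt-7-like 3b,3n distribution (percent).  The dominant U.G cell and the
#: A.G minority are set to the published survey values; the remaining mass
#: is split over plausible minor cells so that the population aggregates
#: (99.41% N1-conferring, 99.70% ion-foldable) come out at the survey level.
KT7_LIKE_FREQ_PERCENT = {
    "UG": 92.06,
    "CA": 4.00,
    "CC": 2.00,
    "CU": 1.00,
    "GG": 0.35,
    "AG": 0.29,
    "GC": 0.20,
    "UU": 0.10,
}


def kt7_like_freq() -> Freq4x4:
    return Freq4x4.from_fractions(KT7_LIKE_FREQ_PERCENT)


def simulate_alignment(params: SimulationParams) -> Alignment:
    """n scaffold rows with 3b,3n drawn i.i.d. from the target Freq4x4.

    Optional per-column substitution noise replaces flank residues with a
    random base at ``substitution_rate``.
    """
    if params.freq is None:
        raise ValueError("simulate_alignment requires params.freq")
    scaffold = params.flank_template or DEFAULT_SCAFFOLD
    if scaffold.count("b") != 1 or scaffold.count("n") != 1:
        raise ValueError("flank_template must mark 3b and 3n with one 'b' and one 'n'")
    col_b = scaffold.index("b")
    col_n = scaffold.index("n")
    probs = params.freq.fractions().ravel()
    rng = np.random.default_rng(params.seed)
    draws = rng.choice(16, size=params.n, p=probs)
    bases = "ACGU"
    ids = [f"seq{i + 1}" for i in range(params.n)]
    rows = []
    template = list(scaffold)
    flank_idx = [
        i for i, c in enumerate(scaffold) if i not in (col_b, col_n)
    ]
    for k in range(params.n):
        row = template.copy()
        row[col_b] = bases[draws[k] // 4]
        row[col_n] = bases[draws[k] % 4]
        if params.substitution_rate > 0:
            for i in flank_idx:
                if rng.random() < params.substitution_rate:
                    row[i] = bases[rng.integers(4)]
        rows.append("".join(row))
    return Alignment(ids=ids, rows=rows)


def scaffold_columns(scaffold: str = DEFAULT_SCAFFOLD) -> tuple[int, int]:
    """1-based (col_3b, col_3n) of a placeholder scaffold."""
    return scaffold.index("b") + 1, scaffold.index("n") + 1
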