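"""Structural observables of the k-turn core.

The conformational class of a kinked k-turn is read off the hydrogen bond
donated by the -1n ribose O2': its acceptor is either N3 or N1 of the
conserved adenine at 2b, defining the N3 and N1 classes.  The switch
between them rotates the A2b base, so the secondary observable is the
A2b N6 - G2n N3 distance (bonded in N3, typically > 4 A in N1), and the
local helix width (C1'-C1' across the 2b*2n and 3b*3n pairs) moves with it.
Crystal structures in the relevant resolution range carry no hydrogens, so
hydrogen bonds are called on heavy-atom donor-acceptor distance alone, with
an explicit ambiguous zone between the bonded and broken cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteInstanceError
from .structure_io import KTurnInstance

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Distance cutoffs, Angstrom.

    bonded_max: heavy-atom donor-acceptor distance at or below which a
        hydrogen bond is called.
    broken_min: distance at or above which the bond is called absent
        (structures report > 4 A as not hydrogen bonded); between the two
        cutoffs the call is explicitly ambiguous.
    ambiguity_margin: if both candidate O2' acceptors are within bonded_max,
        the shorter wins only if it is shorter by at least this margin.
    width_floor: C1'-C1' distances below this are physically implausible
        and flagged.
    """

    bonded_max: float = 3.5
    broken_min: float = 4.0
    ambiguity_margin: float = 0.3
    width_floor: float = 4.0

    def __post_init__(self) -> None:
        if not self.bonded_max < self.broken_min:
            raise ValueError("bonded_max must be smaller than broken_min")


DEFAULT_PARAMS = GeometryParams()

PAIR_LABELS = ("2b2n", "3b3n", "4b4n")

#: glycosidic nitrogen per base (purines N9, pyrimidines N1)
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: heavy atoms that can take part in inter-base hydrogen bonds
POLAR_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "N7", "O6"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}

#: base -> edge -> atoms (Leontis-Westhof edges; shared atoms sit on both)
BASE_EDGES = {
    "A": {
        "WC": ("N1", "N6"),
        "Hoogsteen": ("N6", "N7"),
        "sugar": ("N3", "O2'"),
    },
    "G": {
        "WC": ("N1", "N2", "O6"),
        "Hoogsteen": ("N7", "O6"),
        "sugar": ("N2", "N3", "O2'"),
    },
    "C": {
        "WC": ("N3", "N4", "O2"),
        "Hoogsteen": ("N4",),
        "sugar": ("O2", "O2'"),
    },
    "U": {
        "WC": ("N3", "O4", "O2"),
        "Hoogsteen": ("O4",),
        "sugar": ("O2", "O2'"),
    },
}

EDGE_NAMES = ("WC", "Hoogsteen", "sugar")


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCall:
    donor_heavy: str
    acceptor: str
    distance: float
    verdict: str  # bonded | not_bonded | ambiguous


@dataclass
class ConformationCall:
    instance_id: str
    d_O2p_N3: Optional[float] = None
    d_O2p_N1: Optional[float] = None
    d_N6_N3: Optional[float] = None
    d_L1_A1n: Optional[float] = None
    cls: str = "ambiguous"  # N3 | N1 | ambiguous | extended
    pair_3b3n: tuple[Optional[str], Optional[str]] = (None, None)
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class WidthRecord:
    instance_id: str
    pair_label: str
    c1c1: float
    cls: str = ""
    implausible: bool = False


@dataclass
class BasePairFamily:
    instance_id: str
    pair_label: str
    orientation: Optional[str]  # cis | trans | None
    edge_b: Optional[str]
    edge_n: Optional[str]
    n_hbonds: int
    bonds: list[HBondCall] = field(default_factory=list)

    @property
    def family(self) -> str:
        if self.n_hbonds < 1 or self.orientation is None:
            return "undetermined"
        return f"{self.orientation}-{self.edge_b}/{self.edge_n}"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points, Angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def call_hbond(
    donor_heavy: Sequence[float],
    acceptor: Sequence[float],
    params: GeometryParams = DEFAULT_PARAMS,
    donor_name: str = "donor",
    acceptor_name: str = "acceptor",
) -> HBondCall:
    """Call a hydrogen bond from the heavy-atom donor-acceptor distance."""
    d = distance(donor_heavy, acceptor)
    if d <= params.bonded_max:
        verdict = "bonded"
    elif d >= params.broken_min:
        verdict = "not_bonded"
    else:
        verdict = "ambiguous"
    return HBondCall(donor_name, acceptor_name, d, verdict)


def _require(kti: KTurnInstance, label: str, atom: str) -> np.ndarray:
    if not kti.has_atom(label, atom):
        raise IncompleteInstanceError(
            f"{kti.instance_id}: missing atom {label}.{atom}"
        )
    return kti.atom(label, atom)


# ---------------------------------------------------------------------------
# N3 / N1 classification
# ---------------------------------------------------------------------------

def classify_conformation(
    kti: KTurnInstance, params: GeometryParams = DEFAULT_PARAMS
) -> ConformationCall:
    """Assign a k-turn copy to the N3 or N1 class.

    The primary observable is which ring nitrogen of A2b (N3 or N1) accepts
    the -1n O2' proton.  If neither distance is within ``bonded_max`` the
    core is not kinked and the call is ``extended``.  If both are bonded the
    shorter wins, unless the difference is inside ``ambiguity_margin``.  The
    secondary A2b N6 - G2n N3 bond must agree with the call (present for N3,
    absent for N1); disagreement downgrades the call to ``ambiguous`` with
    both observables reported.
    """
    o2p = _require(kti, "-1n", "O2'")
    n3 = _require(kti, "2b", "N3")
    n1 = _require(kti, "2b", "N1")
    n6 = _require(kti, "2b", "N6")
    g2n_n3 = _require(kti, "2n", "N3")

    d_n3 = distance(o2p, n3)
    d_n1 = distance(o2p, n1)
    secondary = call_hbond(n6, g2n_n3, params, "2b.N6", "2n.N3")

    d_l1 = None
    if kti.has_atom("L1", "O2'") and kti.has_atom("1n", "N1"):
        d_l1 = distance(kti.atom("L1", "O2'"), kti.atom("1n", "N1"))

    call = ConformationCall(
        instance_id=kti.instance_id,
        d_O2p_N3=d_n3,
        d_O2p_N1=d_n1,
        d_N6_N3=secondary.distance,
        d_L1_A1n=d_l1,
        pair_3b3n=kti.pair_3b3n,
    )

    n3_bonded = d_n3 <= params.bonded_max
    n1_bonded = d_n1 <= params.bonded_max
    if not n3_bonded and not n1_bonded:
        call.cls = "extended"
        call.notes.append("neither O2' acceptor within bonded_max: core not kinked")
        return call
    if n3_bonded and n1_bonded:
        if abs(d_n3 - d_n1) < params.ambiguity_margin:
            call.cls = "ambiguous"
            call.notes.append("both acceptors bonded within the ambiguity margin")
            return call
        primary = "N3" if d_n3 < d_n1 else "N1"
        call.notes.append("both acceptors bonded; shorter distance wins")
    else:
        primary = "N3" if n3_bonded else "N1"

    expected = "bonded" if primary == "N3" else "not_bonded"
    if secondary.verdict != expected:
        call.cls = "ambiguous"
        call.notes.append(
            f"secondary N6-N3 check ({secondary.distance:.2f} A, "
            f"{secondary.verdict}) disagrees with primary {primary} call"
        )
        return call
    call.cls = primary
    return call


# ---------------------------------------------------------------------------
# helix widths
# ---------------------------------------------------------------------------

def helix_width(
    kti: KTurnInstance,
    pair_label: str,
    cls: str = "",
    params: GeometryParams = DEFAULT_PARAMS,
) -> WidthRecord:
    """C1'-C1' distance across a named basepair (2b2n, 3b3n or 4b4n)."""
    if pair_label not in PAIR_LABELS:
        raise ValueError(f"pair_label must be one of {PAIR_LABELS}")
    b_label, n_label = pair_label[:2], pair_label[2:]
    c1b = _require(kti, b_label, "C1'")
    c1n = _require(kti, n_label, "C1'")
    w = distance(c1b, c1n)
    return WidthRecord(
        instance_id=kti.instance_id,
        pair_label=pair_label,
        c1c1=w,
        cls=cls,
        implausible=w < params.width_floor,
    )


def width_statistics(
    records: Iterable[WidthRecord],
    collapse: Optional[callable] = None,
) -> pd.DataFrame:
    """Mean / sample SD / n of C1'-C1' widths per (class, pair) group.

    Each crystallographically independent copy is one datum.  Passing
    ``collapse`` (a function instance_id -> k-turn key) first averages the
    copies of each k-turn, the alternative weighting when a structure
    contributes many copies.  Groups with n = 1 report SD as NaN (absent),
    not zero.  SD is the sample estimator (ddof = 1).
    """
    records = list(records)
    if not records:
        raise ValueError("width_statistics: no records supplied")
    df = pd.DataFrame(
        {
            "instance_id": [r.instance_id for r in records],
            "cls": [r.cls for r in records],
            "pair_label": [r.pair_label for r in records],
            "c1c1": [r.c1c1 for r in records],
        }
    )
    if collapse is not None:
        df["kturn"] = df["instance_id"].map(collapse)
        df = (
            df.groupby(["cls", "pair_label", "kturn"], as_index=False)["c1c1"]
            .mean()
        )
    out = (
        df.groupby(["cls", "pair_label"])["c1c1"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out.attrs["sd_estimator"] = "sample (ddof=1)"
    return out


# ---------------------------------------------------------------------------
# Leontis-Westhof family of the 3b,3n pair
# ---------------------------------------------------------------------------

def _edge_of_atom(base: str, atom: str) -> list[str]:
    return [e for e in EDGE_NAMES if atom in BASE_EDGES[base][e]]


def _majority_edge(
    base: str, bonds: list[tuple[str, HBondCall]]
) -> Optional[str]:
    """Majority edge over the bonded atoms; ties go to the edge holding the
    shortest bond."""
    votes: dict[str, int] = {e: 0 for e in EDGE_NAMES}
    shortest: dict[str, float] = {e: math.inf for e in EDGE_NAMES}
    for atom, hb in bonds:
        for edge in _edge_of_atom(base, atom):
            votes[edge] += 1
            shortest[edge] = min(shortest[edge], hb.distance)
    best = max(votes.values())
    if best == 0:
        return None
    tied = [e for e in EDGE_NAMES if votes[e] == best]
    return min(tied, key=lambda e: shortest[e])


def _cis_or_trans(
    n_b: np.ndarray, c1_b: np.ndarray, n_n: np.ndarray, c1_n: np.ndarray
) -> Optional[str]:
    """cis if the two C1' atoms lie on the same side of the axis joining the
    glycosidic nitrogens, trans otherwise."""
    axis = n_n - n_b
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None
    u = axis / norm
    v_b = c1_b - n_b
    v_n = c1_n - n_n
    p_b = v_b - np.dot(v_b, u) * u
    p_n = v_n - np.dot(v_n, u) * u
    if np.linalg.norm(p_b) < 1e-9 or np.linalg.norm(p_n) < 1e-9:
        return None
    return "cis" if float(np.dot(p_b, p_n)) > 0.0 else "trans"


def classify_bp_family(
    kti: KTurnInstance,
    pair_label: str = "3b3n",
    params: GeometryParams = DEFAULT_PARAMS,
) -> BasePairFamily:
    """Type a basepair by interacting edges and glycosidic orientation.

    Inter-base hydrogen bonds are enumerated over the polar base atoms with
    :func:`call_hbond`; each base's bonded atoms vote for an edge, and the
    cis/trans orientation comes from the sides of the C1'-glycosidic-N
    vectors about the axis joining the two glycosidic nitrogens.  This
    simplified typing separates the two families seen at 3b,3n in k-turns
    (trans-Hoogsteen/sugar vs cis-WC/WC); with no inter-base bond, or with
    base atoms absent, the verdict is undetermined.
    """
    b_label, n_label = pair_label[:2], pair_label[2:]
    base_b, base_n = kti.base(b_label), kti.base(n_label)
    result = BasePairFamily(
        kti.instance_id, pair_label, None, None, None, n_hbonds=0
    )
    if base_b not in POLAR_ATOMS or base_n not in POLAR_ATOMS:
        return result

    bonds_b: list[tuple[str, HBondCall]] = []
    bonds_n: list[tuple[str, HBondCall]] = []
    for ab in POLAR_ATOMS[base_b] + ("O2'",):
        if not kti.has_atom(b_label, ab):
            continue
        for an in POLAR_ATOMS[base_n] + ("O2'",):
            if not kti.has_atom(n_label, an):
                continue
            hb = call_hbond(
                kti.atom(b_label, ab),
                kti.atom(n_label, an),
                params,
                f"{b_label}.{ab}",
                f"{n_label}.{an}",
            )
            if hb.verdict == "bonded":
                bonds_b.append((ab, hb))
                bonds_n.append((an, hb))
                result.bonds.append(hb)
    result.n_hbonds = len(result.bonds)
    if result.n_hbonds < 1:
        return result

    gly_b, gly_n = GLYCOSIDIC_N[base_b], GLYCOSIDIC_N[base_n]
    needed = [
        (b_label, gly_b), (b_label, "C1'"), (n_label, gly_n), (n_label, "C1'")
    ]
    if not all(kti.has_atom(l, a) for l, a in needed):
        return result
    result.edge_b = _majority_edge(base_b, bonds_b)
    result.edge_n = _majority_edge(base_n, bonds_n)
    result.orientation = _cis_or_trans(
        kti.atom(b_label, gly_b),
        kti.atom(b_label, "C1'"),
        kti.atom(n_label, gly_n),
        kti.atom(n_label, "C1'"),
    )
    return result
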