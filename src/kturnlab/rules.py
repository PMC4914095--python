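"""The 3b,3n sequence -> (conformation, ion-induced folding) rule table.

The basepair adjacent to the tandem G*A pairs (position 3b,3n) is the main
determinant of which conformational class a k-turn adopts and of whether it
folds on addition of metal ions alone.  Folding follows a closed-form rule
(3b = C or 3n = G folds, except a Watson-Crick 3b,3n pair never does);
conformation has no such closed form and is served as a 4x4 look-up table
built from classified crystal structures.  The default table ships as an
editable data file so cells can be overridden as new structures appear.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

BASES = ("A", "C", "G", "U")
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class Pair3b3n:
    """An ordered 3b,3n base combination; written U*G means 3b=U, 3n=G."""

    b: str
    n: str

    def __post_init__(self) -> None:
        if self.b not in BASES or self.n not in BASES:
            raise ValueError(f"invalid 3b,3n pair ({self.b}, {self.n})")

    def __str__(self) -> str:
        sep = "-" if (self.b, self.n) in WATSON_CRICK else "."
        return f"{self.b}{sep}{self.n}"

    @classmethod
    def parse(cls, text: str) -> "Pair3b3n":
        letters = [c for c in text.upper().replace("T", "U") if c in BASES]
        if len(letters) != 2:
            raise ValueError(f"cannot parse 3b,3n pair from {text!r}")
        return cls(letters[0], letters[1])


ALL_PAIRS = tuple(Pair3b3n(b, n) for b in BASES for n in BASES)


@dataclass
class RuleCell:
    pair: Pair3b3n
    conformation: str  # N3 | N1 | unknown
    folds_in_ions: str  # yes | no
    evidence: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = ""
    exception_notes: str = ""

    def __post_init__(self) -> None:
        if self.conformation == "unknown" and self.evidence:
            raise ValueError(f"{self.pair}: unknown cell must carry no evidence")


class RuleTable:
    """16 RuleCells indexed by (3b, 3n); rows and columns ordered A, C, G, U."""

    def __init__(self, cells: Iterable[RuleCell]):
        self._cells: dict[tuple[str, str], RuleCell] = {}
        for cell in cells:
            key = (cell.pair.b, cell.pair.n)
            if key in self._cells:
                raise ValueError(f"duplicate cell for {cell.pair}")
            self._cells[key] = cell
        missing = [p for p in ALL_PAIRS if (p.b, p.n) not in self._cells]
        if missing:
            raise ValueError(f"rule table incomplete, missing {missing}")

    def __getitem__(self, pair: Pair3b3n) -> RuleCell:
        return self._cells[(pair.b, pair.n)]

    def cells(self) -> list[RuleCell]:
        return [self._cells[(p.b, p.n)] for p in ALL_PAIRS]

    def unknown_pairs(self) -> list[Pair3b3n]:
        return [c.pair for c in self.cells() if c.conformation == "unknown"]

    def to_frame(self) -> pd.DataFrame:
        """4x4 conformation array, rows 3b and columns 3n in A,C,G,U order."""
        data = {
            b: [self._cells[(b, n)].conformation for n in BASES] for b in BASES
        }
        return pd.DataFrame(data, index=list(BASES)).T.rename_axis(
            index="3b", columns="3n"
        )

    def render(self) -> str:
        """Text rendering of the array with the folding rule as cell suffix."""
        lines = ["3b\\3n  " + "  ".join(f"{n:>12s}" for n in BASES)]
        for b in BASES:
            row = []
            for n in BASES:
                cell = self._cells[(b, n)]
                row.append(f"{cell.conformation}/{cell.folds_in_ions:>3s}".rjust(12))
            lines.append(f"{b:<5s}  " + "  ".join(row))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# closed-form rules
# ---------------------------------------------------------------------------

def is_watson_crick(pair: Pair3b3n) -> bool:
    """True for the ascending-diagonal pairs A-U, U-A, G-C, C-G only;
    the G*U/U*G wobbles do not count as Watson-Crick here."""
    return (pair.b, pair.n) in WATSON_CRICK


def predict_folding(pair: Pair3b3n) -> str:
    """Whether a k-turn with this 3b,3n pair folds in metal ions alone.

    3b = C or 3n = G confer ion-induced folding, but a Watson-Crick 3b,3n
    pair never folds (the Watson-Crick rule dominates, so C-G does not fold).
    """
    if is_watson_crick(pair):
        return "no"
    if pair.b == "C" or pair.n == "G":
        return "yes"
    return "no"


def predict_conformation(pair: Pair3b3n, table: Optional[RuleTable] = None) -> str:
    """Look up the N3/N1 conformation conferred by a 3b,3n pair."""
    if table is None:
        table = default_rule_table()
    return table[pair].conformation


# ---------------------------------------------------------------------------
# the packaged default table
# ---------------------------------------------------------------------------

def _parse_evidence(text: str) -> list[tuple[str, str]]:
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            source, _, cls = chunk.rpartition("=")
            out.append((source, cls))
    return out


def load_rule_table(path=None) -> RuleTable:
    """Load a rule table from a TSV file (columns b, n, conformation,
    provenance, evidence, notes); defaults to the packaged table."""
    if path is None:
        text = resources.files("kturnlab.data").joinpath("rule_table.tsv").read_text()
    else:
        text = Path(path).read_text()
    cells = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        parts = (line.split("\t") + [""] * 6)[:6]
        b, n, conformation, provenance, evidence, notes = (p.strip() for p in parts)
        pair = Pair3b3n(b, n)
        cells.append(
            RuleCell(
                pair=pair,
                conformation=conformation,
                folds_in_ions=predict_folding(pair),
                evidence=_parse_evidence(evidence),
                provenance=provenance,
                exception_notes=notes,
            )
        )
    return RuleTable(cells)


_DEFAULT: Optional[RuleTable] = None


def default_rule_table() -> RuleTable:
    """The packaged 4x4 table; two cells have no structure and stay unknown."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_rule_table()
    return _DEFAULT


# ---------------------------------------------------------------------------
# building a table from classified structures
# ---------------------------------------------------------------------------

def build_rule_table(calls: Iterable) -> RuleTable:
    """Fill a 4x4 table from classified k-turn copies by per-cell majority.

    ``calls`` are ConformationCall-like objects with ``pair_3b3n``, ``cls``
    and ``instance_id``.  Unanimous cells get that class; split cells get
    the majority with the minority recorded in exception_notes; an exact tie
    sets the cell unknown with a tie warning; empty cells stay unknown.
    Ambiguous/extended calls carry no class information and are skipped.
    """
    per_cell: dict[tuple[str, str], list] = {}
    for call in calls:
        if call.cls not in ("N3", "N1"):
            continue
        b, n = call.pair_3b3n
        per_cell.setdefault((b, n), []).append(call)

    cells = []
    for pair in ALL_PAIRS:
        members = per_cell.get((pair.b, pair.n), [])
        if not members:
            cells.append(
                RuleCell(pair, "unknown", predict_folding(pair), [], "no evidence")
            )
            continue
        counts = Counter(c.cls for c in members)
        evidence = [(c.instance_id, c.cls) for c in members]
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            cells.append(
                RuleCell(
                    pair, "unknown", predict_folding(pair), [],
                    provenance="tie",
                    exception_notes=(
                        f"tie warning: {dict(counts)} split evenly; "
                        f"evidence {evidence} set aside"
                    ),
                )
            )
            continue
        winner = top[0][0]
        minority = [(iid, cls) for iid, cls in evidence if cls != winner]
        notes = ""
        if minority:
            notes = "minority calls: " + "; ".join(
                f"{iid}={cls}" for iid, cls in minority
            )
        cells.append(
            RuleCell(
                pair, winner, predict_folding(pair), evidence,
                provenance="built from classified structures",
                exception_notes=notes,
            )
        )
    return RuleTable(cells)


def evidence_calls(table: Optional[RuleTable] = None) -> list:
    """Expand a table's per-cell evidence back into classification calls
    (the round-trip companion of :func:`build_rule_table`)."""
    from .geometry import ConformationCall  # local import to avoid a cycle

    if table is None:
        table = default_rule_table()
    calls = []
    for cell in table.cells():
        for source, cls in cell.evidence:
            calls.append(
                ConformationCall(
                    instance_id=source,
                    cls=cls,
                    pair_3b3n=(cell.pair.b, cell.pair.n),
                )
            )
    return calls
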