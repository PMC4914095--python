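"""Population-scale profiling of 3b,3n sequences from alignments.

Given a multiple sequence alignment of a k-turn region and the two
alignment columns holding positions 3b and 3n, this module tabulates the
4x4 base-combination frequencies and, through the rule table, aggregates
them into the predicted population fractions of N3 vs N1 conformation and
of ion-induced foldability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .errors import AlignmentError, FormatError, ProfileError
from .rules import ALL_PAIRS, BASES, Pair3b3n, RuleTable, default_rule_table, predict_folding

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("ragged alignment")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class PairObservation:
    sequence_id: str
    pair: Optional[Pair3b3n]  # None when excluded
    exclusion_reason: Optional[str] = None  # gap | ambiguous


@dataclass
class Freq4x4:
    """Counts and fractions of 3b,3n pairs over an alignment.

    ``counts`` is a 4x4 integer array, rows 3b and columns 3n in A,C,G,U
    order.  Fractions are over the included observations; excluded rows
    (gap or ambiguity at either column) are tallied separately.
    """

    counts: np.ndarray
    n_excluded: int = 0
    excluded_reasons: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 4x4 array")

    @property
    def n_included(self) -> int:
        return int(self.counts.sum())

    def fraction(self, pair: Pair3b3n) -> float:
        i, j = BASES.index(pair.b), BASES.index(pair.n)
        return float(self.counts[i, j]) / self.n_included

    def percent(self, pair: Pair3b3n) -> float:
        return 100.0 * self.fraction(pair)

    def fractions(self) -> np.ndarray:
        return self.counts / self.n_included

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        values = self.fractions() * (100.0 if percent else 1.0)
        return pd.DataFrame(values, index=list(BASES), columns=list(BASES)).rename_axis(
            index="3b", columns="3n"
        )

    @classmethod
    def from_fractions(
        cls, fractions: Union[Mapping[str, float], np.ndarray], scale: int = 10**6
    ) -> "Freq4x4":
        """Build a target distribution from specified fractions (or percents,
        auto-detected by their sum); used to parameterize the generator."""
        arr = np.zeros((4, 4), dtype=float)
        if isinstance(fractions, Mapping):
            for key, value in fractions.items():
                pair = Pair3b3n.parse(key)
                arr[BASES.index(pair.b), BASES.index(pair.n)] = float(value)
        else:
            arr[:] = np.asarray(fractions, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("fractions must have a positive sum")
        if abs(total - 100.0) < 1e-6:
            arr /= 100.0
        elif abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 1 (or 100%)")
        return cls(counts=np.round(arr * scale).astype(int))


@dataclass
class PredictionSummary:
    """Aggregate rule-table predictions for a sequence population (percent)."""

    fraction_N3: float
    fraction_N1: float
    fraction_unknown: float
    fraction_folds: float
    fraction_nonfolds: float
    per_cell: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# reading alignments
# ---------------------------------------------------------------------------

def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _sniff_format(path: Path) -> str:
    head = path.read_text(errors="replace")[:512].lstrip()
    if head.startswith("# STOCKHOLM"):
        return "stockholm"
    if head.upper().startswith(("CLUSTAL", "MUSCLE")):
        return "clustal"
    if head.startswith(">"):
        return "fasta"
    raise FormatError(f"cannot auto-detect alignment format of {path}")


def read_alignment(path, format: str = "auto") -> Alignment:
    """Read a FASTA/Stockholm/Clustal alignment; rows are length-checked,
    upper-cased and T is normalized to U."""
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"alignment file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt not in {"fasta", "stockholm", "clustal"}:
        raise FormatError(f"unknown alignment format {fmt!r}")
    if fmt == "fasta":
        # read per-record so a ragged file can name the offender
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no sequences found")
        width = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != width:
                raise AlignmentError(
                    f"{path}: record {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {width}"
                )
        ids = [rec.id for rec in records]
        rows = [_normalize(str(rec.seq)) for rec in records]
    else:
        try:
            msa = AlignIO.read(str(path), fmt)
        except ValueError as exc:
            raise AlignmentError(f"{path}: {exc}") from exc
        ids = [rec.id for rec in msa]
        rows = [_normalize(str(rec.seq)) for rec in msa]
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def extract_pairs(aln: Alignment, col_3b: int, col_3n: int) -> list[PairObservation]:
    """Read the 3b and 3n residues of every row (1-based alignment columns).

    A gap at either column excludes the row with reason ``gap``; any other
    non-ACGU character excludes it with reason ``ambiguous``.
    """
    for name, col in (("col_3b", col_3b), ("col_3n", col_3n)):
        if not 1 <= col <= aln.width:
            raise AlignmentError(
                f"{name}={col} outside alignment columns 1..{aln.width}"
            )
    out = []
    for sid, row in zip(aln.ids, aln.rows):
        b, n = row[col_3b - 1], row[col_3n - 1]
        if b in GAP_CHARS or n in GAP_CHARS:
            out.append(PairObservation(sid, None, "gap"))
        elif b not in BASES or n not in BASES:
            out.append(PairObservation(sid, None, "ambiguous"))
        else:
            out.append(PairObservation(sid, Pair3b3n(b, n)))
    return out


def profile(observations: Iterable[PairObservation]) -> Freq4x4:
    """Tally included observations into the 4x4 array."""
    counts = np.zeros((4, 4), dtype=int)
    excluded = Counter()
    for obs in observations:
        if obs.pair is None:
            excluded[obs.exclusion_reason] += 1
        else:
            counts[BASES.index(obs.pair.b), BASES.index(obs.pair.n)] += 1
    if counts.sum() == 0:
        raise ProfileError("no included observations to profile")
    return Freq4x4(counts, n_excluded=sum(excluded.values()), excluded_reasons=excluded)


def summarize(freq: Freq4x4, table: Optional[RuleTable] = None) -> PredictionSummary:
    """Aggregate cell fractions into predicted population properties."""
    if table is None:
        table = default_rule_table()
    rows = []
    totals = {"N3": 0.0, "N1": 0.0, "unknown": 0.0, "yes": 0.0, "no": 0.0}
    for pair in ALL_PAIRS:
        frac = freq.percent(pair)
        conf = table[pair].conformation
        fold = predict_folding(pair)
        totals[conf] += frac
        totals[fold] += frac
        rows.append(
            {
                "pair": str(pair),
                "percent": frac,
                "conformation": conf,
                "folds_in_ions": fold,
            }
        )
    return PredictionSummary(
        fraction_N3=totals["N3"],
        fraction_N1=totals["N1"],
        fraction_unknown=totals["unknown"],
        fraction_folds=totals["yes"],
        fraction_nonfolds=totals["no"],
        per_cell=pd.DataFrame(rows),
    )


def render_summary(summary: PredictionSummary, title: str = "") -> str:
    """Two-bar textual report: conformation (N3/N1/unknown) and folding
    (folds/non-folds), the larger fraction of each bar labeled."""

    def bar(parts: list[tuple[str, float]], width: int = 40) -> str:
        cells = []
        for name, frac in parts:
            n = int(round(width * frac / 100.0))
            cells.append(name[0].lower() * n)
        return "".join(cells)[:width].ljust(width, " ")

    conf = [
        ("N3", summary.fraction_N3),
        ("N1", summary.fraction_N1),
        ("unknown", summary.fraction_unknown),
    ]
    fold = [
        ("folds", summary.fraction_folds),
        ("x-nonfolds", summary.fraction_nonfolds),
    ]
    conf_top = max(conf, key=lambda t: t[1])
    fold_top = max(fold, key=lambda t: t[1])
    lines = []
    if title:
        lines.append(title)
    lines.append(
        f"conformation |{bar(conf)}| {conf_top[0]} "
        f"{conf_top[1]:.1f}%  (N3 {summary.fraction_N3:.2f} / "
        f"N1 {summary.fraction_N1:.2f} / unknown {summary.fraction_unknown:.2f})"
    )
    lines.append(
        f"ion folding  |{bar(fold)}| {fold_top[0].lstrip('x-')} "
        f"{fold_top[1]:.1f}%  (folds {summary.fraction_folds:.2f} / "
        f"non-folds {summary.fraction_nonfolds:.2f})"
    )
    return "\n".join(lines)


# alias matching the field naming used for the published bar plots
render_figure = render_summary
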