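"""Reading RNA coordinate files and extracting annotated k-turn cores.

A k-turn copy is addressed by the standard position nomenclature (-1b/-1n
flanking the bulge on the canonical-helix side, L1-L3 the bulge, 1b/1n and
2b/2n the tandem G*A/A*G pairs, 3b/3n and 4b/4n continuing into the
non-canonical helix).  The caller supplies the mapping from nomenclature
labels to (chain, author residue number, insertion code); this module loads
the coordinates (PDB or mmCIF, via gemmi) and pulls out exactly the named
atoms the downstream geometry needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np

from .errors import AnnotationError, FormatError, ParseError

NOMENCLATURE_LABELS = (
    "-1b", "-1n", "L1", "L2", "L3",
    "1b", "1n", "2b", "2n", "3b", "3n", "4b", "4n",
)

#: labels that must be annotated for a conformational classification
MINIMUM_LABELS = ("-1n", "1n", "2b", "2n", "3b", "3n")

#: atoms extract_instance must find, per label (O2' also accepted as O2*)
REQUIRED_ATOMS: dict[str, tuple[str, ...]] = {
    "-1n": ("O2'",),
    "L1": ("O2'",),
    "1n": ("N1",),
    "2b": ("N1", "N3", "N6", "C1'"),
    "2n": ("N1", "N3", "C1'"),
    "3b": ("C1'",),
    "3n": ("C1'",),
    "4b": ("C1'",),
    "4n": ("C1'",),
}


def _load_modified_base_table() -> dict[str, str]:
    text = resources.files("kturnlab.data").joinpath("modified_bases.tsv").read_text()
    table = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            code, parent = line.split("\t")
            table[code.strip()] = parent.strip()
    return table


MODIFIED_BASES = _load_modified_base_table()


def normalize_residue_name(name: str) -> Optional[str]:
    """Map a residue name to its parent base A/C/G/U, or None if unknown."""
    name = name.strip().upper()
    if name in {"A", "C", "G", "U"}:
        return name
    # DNA-style names occasionally appear in hybrid files
    if name in {"DA", "DC", "DG"}:
        return name[1]
    if name in {"T", "DT", "DU"}:
        return "U"
    return MODIFIED_BASES.get(name)


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from a coordinate file (author numbering)."""

    chain_id: str
    residue_number: int
    insertion_code: str  # "" when absent
    residue_name: str
    atom_name: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not (-1e-6 <= self.occupancy <= 1.0 + 1e-6):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class KTurnAnnotation:
    """Maps nomenclature labels to (chain, residue number, insertion code)."""

    instance_id: str
    position_map: Mapping[str, tuple[str, int, str]]

    def __post_init__(self) -> None:
        missing = [lab for lab in MINIMUM_LABELS if lab not in self.position_map]
        if missing:
            raise AnnotationError(
                f"{self.instance_id}: annotation lacks required labels {missing}"
            )
        unknown = [lab for lab in self.position_map if lab not in NOMENCLATURE_LABELS]
        if unknown:
            raise AnnotationError(f"{self.instance_id}: unknown labels {unknown}")
        targets = list(self.position_map.values())
        if len(set(targets)) != len(targets):
            raise AnnotationError(
                f"{self.instance_id}: two labels map to the same residue"
            )


@dataclass
class ResidueAtoms:
    """The extracted atoms of one annotated position."""

    label: str
    residue_name: str
    base: Optional[str]  # normalized A/C/G/U, None if unknown
    atoms: dict[str, np.ndarray]

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name]


@dataclass
class KTurnInstance:
    """Named-atom coordinates for one crystallographically independent k-turn copy."""

    instance_id: str
    residues: dict[str, ResidueAtoms]
    source: str = ""
    incomplete: bool = False
    missing_atoms: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def base(self, label: str) -> Optional[str]:
        res = self.residues.get(label)
        return None if res is None else res.base

    def atom(self, label: str, atom_name: str) -> np.ndarray:
        return self.residues[label].atoms[atom_name]

    def has_atom(self, label: str, atom_name: str) -> bool:
        res = self.residues.get(label)
        return res is not None and atom_name in res.atoms

    @property
    def pair_3b3n(self) -> tuple[Optional[str], Optional[str]]:
        return (self.base("3b"), self.base("3n"))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _resolve_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            return gemmi.CoorFormat.Pdb
        if suffix in {".cif", ".mmcif"}:
            return gemmi.CoorFormat.Mmcif
        # sniff the content
        try:
            head = path.read_text(errors="replace")[:2048]
        except OSError as exc:
            raise ParseError(f"cannot read {path}: {exc}") from exc
        return (
            gemmi.CoorFormat.Mmcif
            if head.lstrip().startswith(("data_", "#"))
            else gemmi.CoorFormat.Pdb
        )
    raise FormatError(f"unknown structure format {fmt!r} (use pdb, mmcif or auto)")


def _dedupe_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer per atom; ties go to the
    alphabetically first alt_loc."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = (*rec.residue_key, rec.atom_name)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if (rec.occupancy, _altloc_rank(rec)) > (cur.occupancy, _altloc_rank(cur)):
                best[key] = rec
    return [best[k] for k in order]


def _altloc_rank(rec: AtomRecord) -> float:
    # higher is better; blank altloc sorts before "A"
    return -ord(rec.alt_loc) if rec.alt_loc else 1.0


def load_structure(path, format: str = "auto") -> list[list[AtomRecord]]:
    """Read a PDB/mmCIF file and return AtomRecords grouped by model.

    All ATOM/HETATM records are returned; alternate locations are resolved
    to the highest-occupancy conformer (ties broken alphabetically).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    coor_format = _resolve_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    models: list[list[AtomRecord]] = []
    for model in st:
        records: list[AtomRecord] = []
        for chain in model:
            for residue in chain:
                icode = residue.seqid.icode.strip()
                for atom in residue:
                    records.append(
                        AtomRecord(
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            insertion_code=icode,
                            residue_name=residue.name,
                            atom_name=atom.name,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                            ),
                            occupancy=float(atom.occ),
                            alt_loc=(
                                atom.altloc
                                if atom.altloc not in ("", " ", "\x00")
                                else ""
                            ),
                        )
                    )
        models.append(_dedupe_altlocs(records))
    if not models:
        raise ParseError(f"{path}: no models found")
    return models


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_instance(
    atoms: Sequence[AtomRecord],
    annotation: KTurnAnnotation,
    source: str = "",
) -> KTurnInstance:
    """Pull the named atoms of one annotated k-turn copy out of a model.

    Atom names are matched exactly, with the legacy O2* spelling accepted
    for O2'.  A missing required atom flags the instance incomplete (the
    missing names are listed); an annotated residue that is absent from the
    structure raises :class:`AnnotationError`.
    """
    by_residue: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for rec in atoms:
        by_residue.setdefault(rec.residue_key, []).append(rec)

    residues: dict[str, ResidueAtoms] = {}
    warnings: list[str] = []
    missing: list[str] = []
    for label, key in annotation.position_map.items():
        chain, resnum, icode = key
        recs = by_residue.get((chain, int(resnum), icode or ""))
        if not recs:
            raise AnnotationError(
                f"{annotation.instance_id}: annotated residue for label {label!r} "
                f"({chain} {resnum}{icode or ''}) not found in structure"
            )
        resname = recs[0].residue_name
        base = normalize_residue_name(resname)
        if base is None:
            warnings.append(f"{label}: unknown residue {resname!r} (kept, flagged)")
        atom_map: dict[str, np.ndarray] = {}
        for rec in recs:
            name = "O2'" if rec.atom_name in ("O2*", "O2'") else rec.atom_name
            name = "C1'" if name == "C1*" else name
            atom_map.setdefault(name, rec.position)
        residues[label] = ResidueAtoms(label, resname, base, atom_map)
        for req in REQUIRED_ATOMS.get(label, ()):
            if req not in atom_map:
                missing.append(f"{label}.{req}")

    if residues.get("2b") is not None and residues["2b"].base not in (None, "A"):
        warnings.append(f"2b is {residues['2b'].base}, expected the conserved A")
    if residues.get("2n") is not None and residues["2n"].base not in (None, "G"):
        warnings.append(f"2n is {residues['2n'].base}, expected the conserved G")

    return KTurnInstance(
        instance_id=annotation.instance_id,
        residues=residues,
        source=source,
        incomplete=bool(missing),
        missing_atoms=missing,
        warnings=warnings,
    )


def enumerate_instances(
    models: Sequence[Sequence[AtomRecord]],
    annotations: Iterable[KTurnAnnotation],
    source: str = "",
) -> list[KTurnInstance]:
    """One KTurnInstance per (model, annotation) pair.

    Crystallographically independent copies are never merged or averaged;
    each enters downstream statistics as its own datum.
    """
    annotations = list(annotations)
    instances: list[KTurnInstance] = []
    multi = len(models) > 1
    for m_idx, model in enumerate(models, start=1):
        for ann in annotations:
            iid = f"{ann.instance_id}/model{m_idx}" if multi else ann.instance_id
            inst = extract_instance(model, ann, source=f"{source}#model{m_idx}")
            inst.instance_id = iid
            instances.append(inst)
    return instances


# ---------------------------------------------------------------------------
# annotation files (TSV with columns instance_id, label, chain, resnum, icode
# -- or an equivalent JSON list)
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[KTurnAnnotation]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"annotation file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith(("[", "{")):
        return _annotations_from_json(text, path)
    return _annotations_from_tsv(text, path)


def _annotations_from_json(text: str, path: Path) -> list[KTurnAnnotation]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if isinstance(payload, dict):
        payload = [payload]
    out = []
    for entry in payload:
        pm = {
            lab: (str(v[0]), int(v[1]), str(v[2]) if len(v) > 2 and v[2] else "")
            for lab, v in entry["position_map"].items()
        }
        out.append(KTurnAnnotation(entry["instance_id"], pm))
    return out


def _annotations_from_tsv(text: str, path: Path) -> list[KTurnAnnotation]:
    rows = [ln.split("\t") for ln in text.splitlines() if ln.strip()]
    if not rows:
        raise ParseError(f"{path}: empty annotation file")
    header = [h.strip().lower() for h in rows[0]]
    expected = ["instance_id", "label", "chain", "resnum", "icode"]
    if header[: len(expected)] != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {header}")
    maps: dict[str, dict[str, tuple[str, int, str]]] = {}
    for row in rows[1:]:
        iid, label, chain, resnum = (c.strip() for c in row[:4])
        icode = row[4].strip() if len(row) > 4 else ""
        maps.setdefault(iid, {})[label] = (chain, int(resnum), icode)
    return [KTurnAnnotation(iid, pm) for iid, pm in maps.items()]


def write_annotations(annotations: Iterable[KTurnAnnotation], path) -> None:
    lines = ["instance_id\tlabel\tchain\tresnum\ticode"]
    for ann in annotations:
        for label, (chain, resnum, icode) in ann.position_map.items():
            lines.append(f"{ann.instance_id}\t{label}\t{chain}\t{resnum}\t{icode}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# writing coordinates (used chiefly by the synthetic generator)
# ---------------------------------------------------------------------------

def build_structure(
    atoms_by_position: Mapping[str, Mapping[str, np.ndarray]],
    residue_names: Mapping[str, str],
    annotation: KTurnAnnotation,
    name: str = "kturn",
) -> gemmi.Structure:
    """Assemble a gemmi Structure from per-position atom maps."""
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for label, atom_map in atoms_by_position.items():
        chain_id, resnum, icode = annotation.position_map[label]
        chain = chains.setdefault(chain_id, gemmi.Chain(chain_id))
        res = gemmi.Residue()
        res.name = residue_names.get(label, "N")
        res.seqid = gemmi.SeqId(int(resnum), icode if icode else " ")
        for atom_name, pos in atom_map.items():
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*np.asarray(pos, dtype=float))
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure(st: gemmi.Structure, path, format: str = "auto") -> None:
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        # quantize to the PDB fixed-point precision so the two serializations
        # of one model read back as identical coordinates
        st = st.clone()
        for model in st:
            for chain in model:
                for residue in chain:
                    for atom in residue:
                        atom.pos = gemmi.Position(
                            round(atom.pos.x, 3),
                            round(atom.pos.y, 3),
                            round(atom.pos.z, 3),
                        )
        st.make_mmcif_document().write_file(str(path))
    else:
        raise FormatError(f"unknown structure format {fmt!r}")
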