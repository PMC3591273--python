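"""Structure I/O: PDB reading/writing, radius assignment, residue selection.

The parser is a deliberately small fixed-column PDB reader covering the
record types this package consumes (ATOM/HETATM/MODEL/ENDMDL/TER/END).
It is cross-validated against an independent parser in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "ResidueSelector",
    "PDBParseError",
    "SelectionError",
    "UnknownElementError",
    "read_pdb",
    "write_pdb",
    "write_multi_model_pdb",
    "assign_radii",
    "load_radius_table",
    "resolve_selector",
    "DEFAULT_RADIUS_TABLE",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Standard amino-acid residue names (used to tell protein HETATMs apart
# from ligands; selenomethionine etc. included).
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; carries the line number."""


class SelectionError(KeyError):
    """Raised when a ResidueSelector does not resolve in a Structure."""


class UnknownElementError(KeyError):
    """Raised when radius assignment meets an element absent from the table."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vdw_radius: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_hydrophobic(self) -> bool:
        """True for carbon and sulfur atoms."""
        return self.element in ("C", "S")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered list of atoms from one PDB MODEL."""

    atoms: list
    model_id: int = 1
    source_label: str = ""

    def __post_init__(self) -> None:
        if not any(not a.is_hydrogen for a in self.atoms):
            raise ValueError("structure must contain at least one heavy atom")
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name, a.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen], dtype=float)

    def heavy_radii(self) -> np.ndarray:
        return np.array(
            [a.vdw_radius for a in self.atoms if not a.is_hydrogen], dtype=float
        )

    def with_coords(self, new_coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same atom metadata)."""
        new_coords = np.asarray(new_coords, dtype=float)
        if new_coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=new_coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, model_id=self.model_id, source_label=self.source_label)

    def residues(self) -> dict:
        """Mapping residue_key -> list of atoms, in order of first appearance."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out


@dataclass(frozen=True)
class ResidueSelector:
    chain_id: str
    residue_number: int
    insertion_code: str = ""

    @classmethod
    def parse(cls, text: str) -> "ResidueSelector":
        """Parse 'CHAIN:RESNUM' or 'CHAIN:RESNUM<icode>' (e.g. 'A:52', 'A:52A')."""
        try:
            chain, res = text.split(":")
        except ValueError as exc:
            raise ValueError(f"selector {text!r} is not CHAIN:RESNUM") from exc
        icode = ""
        if res and res[-1].isalpha():
            res, icode = res[:-1], res[-1]
        return cls(chain_id=chain, residue_number=int(res), insertion_code=icode)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"


def _infer_element(atom_name_raw: str, residue_name: str) -> str:
    """Infer the element from a PDB atom-name field (columns 13-16)."""
    name = atom_name_raw
    # Column 13 blank => single-letter element right-justified in 13-14.
    stripped = name.strip()
    if not stripped:
        return ""
    if len(name) >= 2 and name[0] != " ":
        two = name[:2].strip().upper()
        # Names like '1HB', 'HG21' on hydrogens; digits never start elements.
        if two[0].isdigit():
            return "H" if "H" in two else two.lstrip("0123456789")
        if two in ("CL", "BR", "FE", "ZN", "MG", "MN", "SE", "NA", "CA", "NI", "CU"):
            # 'CA' as an element only occurs for calcium HETATMs.
            if two == "CA" and residue_name in STANDARD_AA:
                return "C"
            return two
        return stripped[0].upper()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serials can overflow/asterisk in large files; non-essential
    name = line[12:16]
    alt_loc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed residue number {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field") from exc
    try:
        occ = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
    except ValueError:
        occ = 1.0
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element or element.isdigit():
        element = _infer_element(name, residue_name)
    if not element:
        raise PDBParseError(f"line {lineno}: cannot determine element for atom {name!r}")
    return Atom(
        serial=serial,
        name=name.strip(),
        element=element,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        insertion_code=icode,
        alt_loc=alt_loc,
        occupancy=occ,
        coords=np.array([x, y, z]),
        is_hetatm=line.startswith("HETATM"),
    )


def _dedupe_altlocs(atoms: list) -> list:
    """Keep one atom per (chain, resnum, icode, name): highest occupancy,
    ties broken by alphabetical alt_loc. Deterministic."""
    best: dict = {}
    order: list = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.alt_loc)) > (b.occupancy, _altloc_rank(b.alt_loc)):
                best[key] = a
    return [best[k] for k in order]


def _altloc_rank(alt: str) -> float:
    # higher rank wins; blank beats 'A' beats 'B' ... so that on equal
    # occupancy the alphabetically-first alt_loc is kept
    if not alt:
        return 1.0
    return -ord(alt)


def read_pdb(text_or_path, model_policy: str = "first") -> list:
    """Read PDB text or a file path into a list of Structure (one per MODEL).

    Waters (HETATM HOH/WAT/DOD) are dropped; hydrogens are retained but
    flagged; for alt_loc duplicates the highest-occupancy copy is kept
    (ties: alphabetical alt_loc).

    Parameters
    ----------
    text_or_path : str or Path
        Raw PDB text, or a path to a PDB file.
    model_policy : {'first', 'all'}
        Whether to return only the first MODEL or all of them.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    label = "<string>"
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str) and "\n" not in text_or_path and text_or_path.strip()
        and (text_or_path.endswith(".pdb") or Path(text_or_path).exists())
    ):
        path = Path(text_or_path)
        if not path.exists():
            raise FileNotFoundError(f"PDB file not found: {path}")
        text = path.read_text()
        label = str(path)
    else:
        text = str(text_or_path)
    if not text.strip():
        raise PDBParseError("empty PDB input")

    structures: list = []
    current_atoms: list = []
    model_id = 1
    in_model = False
    saw_atom_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            try:
                model_id = int(line[10:14])
            except ValueError:
                model_id = len(structures) + 1
            in_model = True
            current_atoms = []
        elif rec == "ENDMDL":
            if current_atoms:
                structures.append(_finish_model(current_atoms, model_id, label))
            in_model = False
            current_atoms = []
            if model_policy == "first" and structures:
                return structures[:1]
        elif rec in ("ATOM  ", "HETATM"):
            saw_atom_record = True
            atom = _parse_atom_line(line, lineno)
            if atom.is_hetatm and atom.residue_name in _WATER_NAMES:
                continue
            current_atoms.append(atom)
    if current_atoms:
        structures.append(_finish_model(current_atoms, model_id if in_model else 1, label))
    if not saw_atom_record:
        raise PDBParseError("no ATOM records found")
    if not structures:
        raise PDBParseError("no atoms retained after filtering")
    if model_policy == "first":
        return structures[:1]
    return structures


def _finish_model(atoms: list, model_id: int, label: str) -> Structure:
    return Structure(atoms=_dedupe_altlocs(atoms), model_id=model_id, source_label=label)


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name
    if len(name) < 4:
        # element-aligned padding per PDB convention
        name = f" {name:<3s}" if len(a.element) == 1 else f"{name:<4s}"
    record = "HETATM" if a.is_hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4.4s}{a.alt_loc or ' ':1.1s}"
        f"{a.residue_name:>3.3s} {a.chain_id:1.1s}{a.residue_number:>4d}"
        f"{a.insertion_code or ' ':1.1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
    )


def write_pdb(structure: Structure, path=None) -> str:
    """Serialize a Structure as PDB text; optionally write to path."""
    lines = [
        _format_atom_line(a, i + 1) for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_multi_model_pdb(structures: Sequence[Structure], path=None) -> str:
    """Serialize an ensemble as a multi-model PDB."""
    lines: list = []
    for i, s in enumerate(structures, start=1):
        lines.append(f"MODEL {i:>8d}")
        lines.extend(_format_atom_line(a, j + 1) for j, a in enumerate(s.atoms))
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def load_radius_table(path=None) -> dict:
    """Load a vdW radius table. Default: Bondi (1964) set shipped as data."""
    if path is None:
        src = resources.files("pocketeer.data").joinpath("bondi_1964.yaml")
        data = yaml.safe_load(src.read_text())
    else:
        data = yaml.safe_load(Path(path).read_text())
    radii = {str(k).upper(): float(v) for k, v in data["radii"].items()}
    return {"name": data.get("name", "custom"), "radii": radii}


DEFAULT_RADIUS_TABLE = load_radius_table()


def assign_radii(structure: Structure, radius_set: Optional[dict] = None) -> Structure:
    """Return a copy with vdw_radius set from the table.

    Hydrogens get radius 0 and are ignored by grid occupancy.
    Unknown heavy-atom elements raise UnknownElementError listing offenders.
    """
    table = (radius_set or DEFAULT_RADIUS_TABLE)["radii"]
    unknown = sorted(
        {a.element for a in structure.atoms if not a.is_hydrogen and a.element not in table}
    )
    if unknown:
        offenders = [
            f"{a.chain_id}:{a.residue_number}{a.insertion_code}/{a.name}"
            for a in structure.atoms
            if a.element in unknown
        ]
        raise UnknownElementError(
            f"elements {unknown} not in radius table; atoms: {', '.join(offenders[:20])}"
        )
    atoms = [
        replace(a, vdw_radius=0.0 if a.is_hydrogen else table[a.element])
        for a in structure.atoms
    ]
    return Structure(atoms=atoms, model_id=structure.model_id, source_label=structure.source_label)


def strip_ligands(structure: Structure) -> Structure:
    """Drop all HETATM atoms that are not standard amino acids.

    Pocket detection must run on the protein with any inhibitor removed.
    """
    atoms = [a for a in structure.atoms if not (a.is_hetatm and a.residue_name not in STANDARD_AA)]
    if not atoms:
        raise ValueError("no atoms left after stripping ligands")
    return Structure(atoms=atoms, model_id=structure.model_id, source_label=structure.source_label)


def resolve_selector(structure: Structure, selector: ResidueSelector) -> list:
    """All heavy atoms of the selected residue; SelectionError if absent."""
    atoms = [
        a
        for a in structure.atoms
        if not a.is_hydrogen
        and a.chain_id == selector.chain_id
        and a.residue_number == selector.residue_number
        and a.insertion_code == (selector.insertion_code or "")
    ]
    if not atoms:
        raise SelectionError(
            f"residue {selector} not found in structure {structure.source_label!r}"
        )
    return atoms
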