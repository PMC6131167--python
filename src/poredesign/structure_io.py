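"""Molecular structure model and PDB input/output.

A :class:`Structure` is an ordered collection of residues, each an ordered
collection of atoms with element, Cartesian coordinates (Å) and an optional
van der Waals radius.  Parsing of PDB files is delegated to ``gemmi``;
writing emits fixed-column PDB v3.3 records directly so the round-trip
precision (3 decimals) is explicit.

Conventions
-----------
* Coordinates are Å everywhere; residue numbering is the author numbering
  of the source file (no renumbering).
* Alternate locations: the first-listed altloc of each atom is kept.
* Hydrogens in crystal structures are ignored by clash/geometry operations
  (radii are heavy-atom based); water hydrogens matter only for the
  hydrogen-bond operator in :mod:`poredesign.pore_profile`.
* Only model 1 of multi-model files is read unless ``model_index`` says
  otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "BONDI_RADII",
    "BACKBONE_ATOMS",
    "StructureFormatError",
    "UnknownElementError",
    "read_structure",
    "write_structure",
    "assign_vdw_radii",
    "extract_protein_and_waters",
]

#: Bondi (1964) van der Waals radii, Å.  Heavy-atom based; hydrogens are
#: carried at 1.10 Å but excluded from clash and pore-geometry operations.
BONDI_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AMINO_ACIDS_3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL"})


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or is empty."""


class UnknownElementError(KeyError):
    """Raised when an atom's element has no entry in the radius table."""


@dataclass
class Atom:
    """A single atom: label, element, position (Å) and vdW radius (Å)."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        self.element = self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.vdw_radius)


@dataclass
class Residue:
    """One residue: chain, author sequence number, type and its atoms."""

    chain_id: str
    seq_number: int
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.aa_type = self.aa_type.upper()

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_number)

    @property
    def is_water(self) -> bool:
        return self.aa_type in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.aa_type in AMINO_ACIDS_3

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.seq_number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        out = []
        for a in self.atoms:
            if a.is_backbone:
                continue
            if a.is_hydrogen and not include_hydrogens:
                continue
            out.append(a)
        return out

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_number, self.aa_type, [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """An ordered collection of residues read from (or destined for) a PDB file."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate residue identifier {k}")
                seen.add(k)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, chain_id: str, seq_number: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_number == seq_number:
                return r
        raise KeyError(f"no residue {chain_id}/{seq_number}")

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid]

    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def atoms(self, heavy_only: bool = False) -> list[Atom]:
        out: list[Atom] = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                out.append(a)
        return out

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.atoms(heavy_only=heavy_only)
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])

    def ca_coordinates(self) -> np.ndarray:
        cas = [r.atom("CA").position for r in self.protein_residues() if r.has_atom("CA")]
        if not cas:
            return np.zeros((0, 3))
        return np.array(cas)

    def copy(self) -> "Structure":
        s = Structure.__new__(Structure)
        s.residues = [r.copy() for r in self.residues]
        s.title = self.title
        s.source_id = self.source_id
        return s

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        s = self.copy()
        for r in s.residues:
            for a in r.atoms:
                a.position = R @ a.position + t
        return s


# ---------------------------------------------------------------------------
# I/O


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read ATOM/HETATM records of one model of a PDB file.

    The first-listed altloc of each atom is kept; later altlocs are dropped.

    Parameters
    ----------
    path:
        PDB-format text file.
    model_index:
        Which MODEL to read (0-based).  Default: the first.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or model_index >= len(st):
        raise StructureFormatError(f"{path} has no model index {model_index}")
    model = st[model_index]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms: list[Atom] = []
            seen_altloc_names: set[str] = set()
            for at in res:
                if at.altloc not in ("", "\x00", " "):
                    # keep only the first-listed altloc per atom name
                    if at.name in seen_altloc_names:
                        continue
                    seen_altloc_names.add(at.name)
                elem = at.element.name.upper()
                if not elem or elem == "X":
                    elem = _element_from_name(at.name)
                atoms.append(Atom(at.name, elem, np.array([at.pos.x, at.pos.y, at.pos.z])))
            residues.append(Residue(chain.name, res.seqid.num, res.name, atoms))
    if not residues or not any(r.atoms for r in residues):
        raise StructureFormatError(f"{path}: selected model is empty")
    title = st.name or ""
    return Structure(residues=residues, title=title, source_id=path.stem)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in BONDI_RADII:
        return stripped[:2].upper()
    if stripped:
        return stripped[0].upper()
    raise StructureFormatError(f"cannot infer element from atom name {name!r}")


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as fixed-column PDB v3.3 ATOM/HETATM records."""
    if not structure.residues:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    serial = 1
    for res in structure.residues:
        record = "HETATM" if not res.is_amino_acid else "ATOM  "
        for a in res.atoms:
            name = a.name
            # PDB atom-name alignment: 1-char elements start in column 14.
            if len(name) < 4 and len(a.element) == 1:
                name = f" {name}"
            x, y, z = a.position
            lines.append(
                f"{record}{serial % 100000:5d} {name:<4s}{'':1s}{res.aa_type:>3s} "
                f"{res.chain_id[:1] or 'A':1s}{res.seq_number:4d}{'':4s}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}{'':10s}{a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Property assignment


def assign_vdw_radii(
    structure: Structure, radius_table: Mapping[str, float] | None = None
) -> Structure:
    """Attach a van der Waals radius to every atom (in place; returns input).

    Uses the Bondi set by default.  Unknown elements raise
    :class:`UnknownElementError` naming the offending atom.
    """
    table = {k.upper(): v for k, v in (radius_table or BONDI_RADII).items()}
    for res in structure.residues:
        for a in res.atoms:
            try:
                a.vdw_radius = table[a.element]
            except KeyError:
                raise UnknownElementError(
                    f"no vdW radius for element {a.element!r} "
                    f"(atom {a.name} in {res.aa_type} {res.chain_id}{res.seq_number})"
                ) from None
    return structure


def extract_protein_and_waters(structure: Structure) -> tuple[Structure, np.ndarray]:
    """Split a structure into its protein part and ordered water oxygens.

    Returns the protein-only structure and an (n, 3) array of water oxygen
    coordinates sorted by ascending axial (z) coordinate, ready to be turned
    into a :class:`~poredesign.design_engine.WaterWire`.
    """
    protein = [r for r in structure.residues if r.is_amino_acid]
    oxygens = []
    for r in structure.water_residues():
        for a in r.atoms:
            if a.element == "O":
                oxygens.append(a.position)
    prot = Structure.__new__(Structure)
    prot.residues = protein
    prot.title = structure.title
    prot.source_id = structure.source_id
    if oxygens:
        arr = np.array(oxygens)
        arr = arr[np.argsort(arr[:, 2], kind="stable")]
    else:
        arr = np.zeros((0, 3))
    return prot, arr
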