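"""Water-wire-constrained redesign of pore-lining residues.

The redesign places a single-file water wire (the template geometry taken
from an aquaporin) at the pore constriction and then repacks a chosen set
of pore-lining positions with a hydrophobic alphabet, subject to:

* no steric clash between selected side chains (soft vdW overlap factor),
* no side-chain heavy atom inside the vdW exclusion zone of any wire
  oxygen (the wire must stay intact, so the pore cannot be occluded),
* at least half of the positions carrying long side chains
  (Trp/Phe/Tyr/Met), which safeguards against trivial all-alanine packings,

while maximising the summed side-chain/wire 12-6 Lennard-Jones interaction
energy (energies are non-positive, so the optimum is the *least binding*
feasible packing - the design goal is a pore wall that leaves the water
wire alone).  Selection is a mixed-integer linear program with one binary
per (position, rotamer) candidate.

Designs are generated iteratively: repeated MILP solves under no-good cuts
(and optional seeded candidate subsampling) propose mutation sets, each is
rebuilt into a full-atom structure, re-profiled, and retained if its
constriction diameter falls in the requested window or if it binds the
wire less than the wild type does.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

from .pore_profile import (
    ConstrictionGeometry,
    OccludedPoreError,
    PoreAxis,
    PoreProfile,
    compute_profile,
    find_constriction,
)
from .structure_io import Atom, BONDI_RADII, Residue, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "WaterWire",
    "RotamerLibrary",
    "DesignSpec",
    "DesignCandidate",
    "WireGeometryWarning",
    "InfeasibleDesignError",
    "load_water_wire",
    "place_water_wire",
    "build_rotamer",
    "detect_clash",
    "wire_exclusion_ok",
    "interaction_energy",
    "enumerate_candidates",
    "select_rotamers_milp",
    "build_design_structure",
    "generate_designs",
    "accept_design",
    "long_chain_fraction",
    "default_rotamer_library",
    "LONG_AAS",
    "ALLOWED_AAS",
]

#: hydrophobic design alphabet; long = bulky side chains required at >= 50%
ALLOWED_AAS = ("TRP", "PHE", "TYR", "MET", "LEU", "ILE", "VAL", "ALA")
LONG_AAS = ("TRP", "PHE", "TYR", "MET")

WIRE_SPACING_MIN = 2.4  # Å, single-file water O-O spacing window
WIRE_SPACING_MAX = 3.5
WATER_O_RADIUS = BONDI_RADII["O"]

#: per-element 12-6 Lennard-Jones parameters for the wire interaction score:
#: (epsilon kcal/mol, r_min Å); geometric-mean epsilon, arithmetic-mean r_min
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (0.11, 4.00),
    "N": (0.20, 3.66),
    "O": (0.12, 3.50),
    "S": (0.45, 4.00),
}
LJ_CUTOFF = 10.0  # Å

DEFAULT_CLASH_OVERLAP = 0.85


class WireGeometryWarning(UserWarning):
    """Water-wire spacing outside the single-file window [2.4, 3.5] Å."""


class InfeasibleDesignError(RuntimeError):
    """The rotamer-selection MILP has no feasible assignment."""


# ---------------------------------------------------------------------------
# Water wires


@dataclass
class WaterWire:
    """Ordered water-oxygen coordinates of a single-file wire."""

    oxygens: np.ndarray  # (n, 3) Å
    label: str = ""
    spacing_ok: bool = True

    def __post_init__(self) -> None:
        self.oxygens = np.atleast_2d(np.asarray(self.oxygens, float))
        if self.oxygens.size and self.oxygens.shape[1] != 3:
            raise ValueError("wire oxygens must be an (n, 3) array")

    def __len__(self) -> int:
        return len(self.oxygens)

    def spacings(self) -> np.ndarray:
        if len(self) < 2:
            return np.zeros(0)
        return np.linalg.norm(np.diff(self.oxygens, axis=0), axis=1)

    def end_to_end(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(self.oxygens[-1] - self.oxygens[0]))

    def pairwise_distances(self) -> np.ndarray:
        d = self.oxygens[:, None, :] - self.oxygens[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def principal_axis(self) -> np.ndarray:
        if len(self) < 2:
            raise ValueError("need at least 2 oxygens for a wire axis")
        centred = self.oxygens - self.oxygens.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        u = vt[0]
        if np.dot(u, self.oxygens[-1] - self.oxygens[0]) < 0:
            u = -u
        return u


def _check_spacing(wire: WaterWire) -> WaterWire:
    sp = wire.spacings()
    if len(sp) and (sp.min() < WIRE_SPACING_MIN or sp.max() > WIRE_SPACING_MAX):
        wire.spacing_ok = False
        warnings.warn(
            f"wire O-O spacing outside [{WIRE_SPACING_MIN}, {WIRE_SPACING_MAX}] Å "
            f"(range {sp.min():.2f}-{sp.max():.2f} Å)",
            WireGeometryWarning,
            stacklevel=3,
        )
    return wire


def load_water_wire(path: str | Path) -> WaterWire:
    """Load a water wire from a PDB (HOH oxygens) or XYZ file.

    Input order is preserved; axial reordering happens at placement.
    An empty file is an error; spacing outside the single-file window
    [2.4, 3.5] Å raises :class:`WireGeometryWarning` but loading proceeds
    with ``spacing_ok = False``.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty water-wire file")
    coords: list[list[float]] = []
    if text.splitlines()[0][:6] in ("ATOM  ", "HETATM", "TITLE ", "REMARK", "CRYST1", "MODEL "):
        from .structure_io import read_structure

        st = read_structure(path)
        for res in st.water_residues():
            for a in res.atoms:
                if a.element == "O":
                    coords.append(list(a.position))
    else:  # XYZ: optional count/comment header, then "El x y z" rows
        for line in text.splitlines():
            parts = line.split()
            if len(parts) == 4 and parts[0].upper().startswith("O"):
                coords.append([float(v) for v in parts[1:4]])
    if not coords:
        raise ValueError(f"{path}: no water oxygens found")
    return _check_spacing(WaterWire(np.array(coords), label=path.stem))


def place_water_wire(
    wire: WaterWire,
    structure: Structure,
    axis: PoreAxis,
    constriction: ConstrictionGeometry,
) -> WaterWire:
    """Rigidly place a wire on the pore axis at the constriction.

    The wire's principal axis is rotated onto the pore axis and its
    centroid moved to the constriction centre (the open-region centre of
    the constriction slice, at its z).  Of the two axial orientations the
    one with smaller summed vdW overlap against the protein heavy atoms is
    kept.  Only a rigid transform is applied, so all pairwise oxygen
    distances are preserved; oxygens are reordered by ascending axial
    coordinate afterwards.
    """
    if len(wire) == 0:
        raise ValueError("cannot place an empty wire")
    frame = axis.frame()  # rows ex, ey, ez
    cx, cy = constriction.slice.center
    target = axis.origin + frame.T @ np.array([cx, cy, constriction.slice.z])

    if len(wire) == 1:
        return WaterWire(np.array([target]), wire.label, wire.spacing_ok)

    u = wire.principal_axis()
    centred = wire.oxygens - wire.oxygens.mean(axis=0)

    prot = structure.coordinates(heavy_only=True)
    radii = np.array([a.vdw_radius or BONDI_RADII.get(a.element, 1.7) for a in structure.atoms(heavy_only=True)])

    best = None
    for sign in (+1.0, -1.0):
        R = _rotation_between(u, sign * axis.direction)
        placed = centred @ R.T + target
        overlap = _summed_overlap(placed, prot, radii)
        if best is None or overlap < best[0] - 1e-12:
            best = (overlap, placed)
    placed = best[1]
    zproj = (placed - axis.origin) @ axis.direction
    placed = placed[np.argsort(zproj, kind="stable")]

    if len(prot):
        prot_z = (prot - axis.origin) @ axis.direction
        if wire.end_to_end() > float(prot_z.max() - prot_z.min()):
            warnings.warn(
                "wire is longer than the pore's axial extent; placement returned anyway",
                WireGeometryWarning,
                stacklevel=2,
            )
    return WaterWire(placed, wire.label, wire.spacing_ok)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180°: rotate about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(p, a)) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        p = p - np.dot(p, a) * a
        p /= np.linalg.norm(p)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _summed_overlap(points: np.ndarray, prot: np.ndarray, radii: np.ndarray) -> float:
    if len(prot) == 0:
        return 0.0
    total = 0.0
    for p in points:
        d = np.linalg.norm(prot - p, axis=1)
        pen = (radii + WATER_O_RADIUS) - d
        total += float(np.clip(pen, 0.0, None).sum())
    return total


# ---------------------------------------------------------------------------
# Rotamer construction

#: chi-angle count per design amino acid
N_CHIS = {"ALA": 0, "VAL": 1, "LEU": 2, "ILE": 2, "MET": 3, "PHE": 2, "TYR": 2, "TRP": 2}

# CB improper geometry (L-amino acid): torsion C-N-CA-CB, angle N-CA-CB
_CB_BOND = 1.53
_CB_ANGLE = 110.4
_CB_TORSION = 122.6

# side-chain templates: (atom, element, (refA, refB, refC), bond Å, angle °, torsion)
# torsion is ("chi", k, offset_deg) -> chis[k] + offset, or ("fix", value)
_Chi = tuple
_TEMPLATES: dict[str, list[tuple]] = {
    "ALA": [],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.54, 110.5, ("chi", 0, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.54, 110.5, ("chi", 0, 122.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 0, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 1, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 1, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 0, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.54, 110.5, ("chi", 0, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.51, 113.8, ("chi", 1, 0.0)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 0, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 1, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 2, 0.0)),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 0, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 1, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 1, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 121.2, ("fix", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 121.2, ("fix", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 0, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 1, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 1, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, ("fix", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.2, ("fix", 180.0)),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, ("fix", 0.0)),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, ("fix", 180.0)),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.6, ("fix", 180.0)),
        ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.37, 121.1, ("fix", 0.0)),
    ],
}
_TEMPLATES["TYR"] = _TEMPLATES["PHE"] + [
    ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 119.9, ("fix", 180.0)),
]


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D with |CD| = bond, angle(B,C,D) = angle and IUPAC torsion(A,B,C,D)."""
    theta = math.radians(angle)
    chi = -math.radians(torsion)  # frame handedness: negate for IUPAC sign
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("reference atoms for internal-coordinate placement are collinear")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi), bond * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """IUPAC dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def build_rotamer(residue_backbone: Residue, aa_type: str, chis: Sequence[float]) -> Residue:
    """Build a full side chain on an existing backbone from ideal geometry.

    The CB is placed tetrahedrally from N, CA, C (L-configuration) and the
    remaining atoms follow the internal-coordinate template of ``aa_type``
    with the supplied chi dihedrals.  Deterministic.
    """
    aa_type = aa_type.upper()
    if aa_type not in _TEMPLATES:
        raise ValueError(f"unsupported design amino acid {aa_type!r}")
    if len(chis) != N_CHIS[aa_type]:
        raise ValueError(
            f"{aa_type} needs {N_CHIS[aa_type]} chi angles, got {len(chis)}"
        )
    try:
        n = residue_backbone.atom("N").position
        ca = residue_backbone.atom("CA").position
        c = residue_backbone.atom("C").position
    except KeyError as exc:
        raise ValueError(f"backbone N/CA/C required to build a rotamer: {exc}") from exc

    res = Residue(
        residue_backbone.chain_id,
        residue_backbone.seq_number,
        aa_type,
        [a.copy() for a in residue_backbone.atoms if a.is_backbone],
    )
    pos: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
    if aa_type != "GLY":
        cb = _nerf(c, n, ca, _CB_BOND, _CB_ANGLE, _CB_TORSION)
        pos["CB"] = cb
        res.atoms.append(Atom("CB", "C", cb))
    for name, elem, (ra, rb, rc), bond, angle, tors in _TEMPLATES[aa_type]:
        if tors[0] == "chi":
            value = float(chis[tors[1]]) + tors[2]
        else:
            value = tors[1]
        p = _nerf(pos[ra], pos[rb], pos[rc], bond, angle, value)
        pos[name] = p
        res.atoms.append(Atom(name, elem, p))
    return res


# ---------------------------------------------------------------------------
# Rotamer library


@dataclass
class RotamerLibrary:
    """Discrete side-chain conformations: chi tuples (degrees) per amino acid."""

    rotamers: dict[str, list[tuple[float, ...]]]

    def __post_init__(self) -> None:
        for aa, rots in self.rotamers.items():
            if not rots:
                raise ValueError(f"amino acid {aa} has no rotamers")
            for chis in rots:
                for chi in chis:
                    if not (-180.0 < chi <= 180.0):
                        raise ValueError(f"chi angle {chi} outside (-180, 180] for {aa}")

    def __getitem__(self, aa: str) -> list[tuple[float, ...]]:
        return self.rotamers[aa.upper()]

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self.rotamers


def default_rotamer_library() -> RotamerLibrary:
    """Coarse backbone-independent library.

    Aliphatic chis sample {-60, 60, 180}°; the ring chi2 of Trp/Phe/Tyr is
    limited to {-90, 90}° (ring flips are near-degenerate).  Small by
    design - richer libraries can be supplied via :class:`RotamerLibrary`
    or :func:`dense_rotamer_library`.
    """
    aliphatic = (-60.0, 60.0, 180.0)
    ring2 = (-90.0, 90.0)
    lib: dict[str, list[tuple[float, ...]]] = {"ALA": [()]}
    lib["VAL"] = [(c1,) for c1 in aliphatic]
    lib["LEU"] = [(c1, c2) for c1 in aliphatic for c2 in aliphatic]
    lib["ILE"] = [(c1, c2) for c1 in aliphatic for c2 in aliphatic]
    lib["MET"] = [(c1, c2, c3) for c1 in aliphatic for c2 in aliphatic for c3 in aliphatic]
    for ring_aa in ("PHE", "TYR", "TRP"):
        lib[ring_aa] = [(c1, c2) for c1 in aliphatic for c2 in ring2]
    return RotamerLibrary(lib)


def dense_rotamer_library(chi1_step: float = 30.0) -> RotamerLibrary:
    """Like the default library but with dense aromatic chi1 sampling.

    Tightly packed pore walls often admit bulky side chains only at
    intermediate chi1 values; this grid samples aromatic chi1 every
    ``chi1_step`` degrees and ring chi2 every 30° in (-90, 90].
    """
    lib = dict(default_rotamer_library().rotamers)
    chi1 = [round(-180.0 + chi1_step * i, 3) for i in range(int(round(360.0 / chi1_step)))]
    chi1 = [c if c != -180.0 else 180.0 for c in chi1]
    ring2 = (-60.0, -30.0, 30.0, 60.0, 90.0)
    for ring_aa in ("PHE", "TYR", "TRP"):
        lib[ring_aa] = [(c1, c2) for c1 in chi1 for c2 in ring2]
    return RotamerLibrary(lib)


# ---------------------------------------------------------------------------
# Geometry checks and scoring


def detect_clash(
    group_a: Residue | Sequence[Atom],
    group_b: Residue | Structure | Sequence[Atom],
    overlap: float = DEFAULT_CLASH_OVERLAP,
) -> bool:
    """True iff any heavy-atom pair across the two groups is closer than
    ``overlap`` x the sum of its vdW radii.

    The two groups are assumed to belong to different residues (bonded and
    1-3 pairs occur only within a residue, which is never compared against
    itself: identical residue objects return False).
    """
    atoms_a = _heavy_atoms_of(group_a)
    atoms_b = _heavy_atoms_of(group_b)
    if group_a is group_b:
        return False
    if not atoms_a or not atoms_b:
        return False
    pa = np.array([a.position for a in atoms_a])
    ra = np.array([_radius(a) for a in atoms_a])
    pb = np.array([b.position for b in atoms_b])
    rb = np.array([_radius(b) for b in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    thresh = overlap * (ra[:, None] + rb[None, :])
    return bool(np.any(d < thresh))


def _heavy_atoms_of(group) -> list[Atom]:
    if isinstance(group, Residue):
        return group.heavy_atoms()
    if isinstance(group, Structure):
        return group.atoms(heavy_only=True)
    return [a for a in group if not a.is_hydrogen]


def _radius(a: Atom) -> float:
    if a.vdw_radius is not None:
        return a.vdw_radius
    try:
        return BONDI_RADII[a.element]
    except KeyError:
        raise KeyError(f"no vdW radius for atom {a.name} ({a.element})") from None


def wire_exclusion_ok(rotamer: Residue, wire: WaterWire) -> bool:
    """True iff every heavy atom clears every wire oxygen by the sum of
    their vdW radii (the wire must not be sterically displaced)."""
    if len(wire) == 0:
        return True
    atoms = rotamer.heavy_atoms()
    if not atoms:
        return True
    p = np.array([a.position for a in atoms])
    r = np.array([_radius(a) for a in atoms])
    d = np.linalg.norm(p[:, None, :] - wire.oxygens[None, :, :], axis=-1)
    return bool(np.all(d > (r[:, None] + WATER_O_RADIUS)))


def interaction_energy(rotamer: Residue | Sequence[Atom], wire: WaterWire) -> float:
    """Summed 12-6 Lennard-Jones energy (kcal/mol) between the residue's
    heavy atoms and the wire oxygens; more negative = stronger binding."""
    atoms = _heavy_atoms_of(rotamer)
    if not atoms or len(wire) == 0:
        return 0.0
    e_o, rmin_o = LJ_PARAMS["O"]
    total = 0.0
    for a in atoms:
        if a.element not in LJ_PARAMS:
            continue
        eps_a, rmin_a = LJ_PARAMS[a.element]
        eps = math.sqrt(eps_a * e_o)
        rmin = 0.5 * (rmin_a + rmin_o)
        d = np.linalg.norm(wire.oxygens - a.position, axis=1)
        d = d[d <= LJ_CUTOFF]
        if len(d) == 0:
            continue
        q = (rmin / d) ** 6
        total += float(np.sum(eps * (q * q - 2.0 * q)))
    return total


# ---------------------------------------------------------------------------
# Design specification and candidates


@dataclass
class DesignSpec:
    """What to redesign and under which constraints."""

    positions: list[tuple[str, int]]
    allowed_aas: tuple[str, ...] = ALLOWED_AAS
    long_aas: tuple[str, ...] = LONG_AAS
    min_long_fraction: float = 0.5
    d_min: float = 0.0
    d_max: float = 4.0
    clash_overlap: float = DEFAULT_CLASH_OVERLAP
    restarts: int = 10
    seed: int = 0
    subsample: float = 0.75  # candidate fraction kept per restart after the first

    def __post_init__(self) -> None:
        self.allowed_aas = tuple(a.upper() for a in self.allowed_aas)
        self.long_aas = tuple(a.upper() for a in self.long_aas)
        if not 0.0 <= self.min_long_fraction <= 1.0:
            raise ValueError("min_long_fraction must be in [0, 1]")
        if not 0.0 <= self.d_min < self.d_max:
            raise ValueError("need 0 <= d_min < d_max")
        if not set(self.long_aas) <= set(self.allowed_aas):
            raise ValueError("long_aas must be a subset of allowed_aas")


@dataclass
class DesignCandidate:
    """A mutation set with its rotamers, scores and re-profiled geometry."""

    mutations: dict[tuple[str, int], str]
    rotamers: dict[tuple[str, int], tuple[float, ...]]
    wire_interaction_energy: float = 0.0
    constriction: ConstrictionGeometry | None = None
    accepted: bool = False
    class_label: str | None = None
    structure: Structure | None = None
    profile: PoreProfile | None = None

    def __post_init__(self) -> None:
        if set(self.mutations) != set(self.rotamers):
            raise ValueError("mutations and rotamers must share the same positions")

    @property
    def diameter(self) -> float | None:
        return None if self.constriction is None else self.constriction.diameter


def accept_design(candidate: DesignCandidate, spec: DesignSpec) -> bool:
    """Pore-size window acceptance: d_min <= diameter <= d_max.

    With ``d_min = 0`` this reproduces the plain "smaller than d_max" mode
    (a zero-diameter pore is occluded, never accepted).
    """
    if candidate.constriction is None:
        return False
    d = candidate.constriction.diameter
    if d <= 0.0:
        return False
    return spec.d_min <= d <= spec.d_max


def long_chain_fraction(candidate: DesignCandidate, spec: DesignSpec) -> float:
    """Fraction of design positions carrying a long (bulky) side chain."""
    if not candidate.mutations:
        raise ValueError("candidate has no mutations")
    n_long = sum(1 for aa in candidate.mutations.values() if aa in spec.long_aas)
    return n_long / len(candidate.mutations)


# ---------------------------------------------------------------------------
# Candidate enumeration and MILP selection


def enumerate_candidates(
    structure: Structure,
    spec: DesignSpec,
    library: RotamerLibrary,
    wire: WaterWire,
) -> dict[tuple[str, int], list[tuple[str, tuple[float, ...], Residue, float]]]:
    """Per-position candidate rotamers surviving the hard pre-filters.

    Each candidate is (aa_type, chis, built residue, wire interaction
    energy).  A candidate is dropped if it violates the wire vdW exclusion
    or clashes with the fixed environment (all residues outside the design
    set, excluding the position's sequence neighbours' bonded context).
    """
    design_keys = set(spec.positions)
    env_by_pos: dict[tuple[str, int], list[Atom]] = {}
    for key in spec.positions:
        env: list[Atom] = []
        for res in structure.residues:
            if res.is_water:
                continue
            if res.key in design_keys:
                continue  # design positions are repacked; their WT side chains vanish
            if res.chain_id == key[0] and abs(res.seq_number - key[1]) <= 1:
                continue  # bonded neighbours: covalent context, not clashes
            env.extend(res.heavy_atoms())
        env_by_pos[key] = env

    out: dict[tuple[str, int], list[tuple[str, tuple[float, ...], Residue, float]]] = {}
    for key in spec.positions:
        backbone = structure.residue(*key)
        cands = []
        for aa in spec.allowed_aas:
            if aa not in library:
                continue
            for chis in library[aa]:
                rot = build_rotamer(backbone, aa, chis)
                assign_vdw_radii_residue(rot)
                if not wire_exclusion_ok(rot, wire):
                    continue
                if detect_clash(rot.side_chain_atoms() + [a for a in rot.atoms if a.name == "CB"],
                                env_by_pos[key], spec.clash_overlap):
                    continue
                cands.append((aa, tuple(chis), rot, interaction_energy(rot, wire)))
        out[key] = cands
    return out


def assign_vdw_radii_residue(res: Residue) -> Residue:
    for a in res.atoms:
        if a.vdw_radius is None:
            a.vdw_radius = BONDI_RADII.get(a.element)
    return res


def select_rotamers_milp(
    structure: Structure,
    spec: DesignSpec,
    candidates: Mapping[tuple[str, int], Sequence[tuple[str, tuple[float, ...], Residue, float]]],
    wire: WaterWire,
    forbidden_mutation_sets: Iterable[Mapping[tuple[str, int], str]] = (),
    min_count_of: Mapping[str, int] | None = None,
) -> DesignCandidate:
    """Select one rotamer per position by mixed-integer linear programming.

    Binary x[p, r] per candidate; exactly one per position; clashing pairs
    mutually excluded; long-side-chain count >= min_long_fraction x
    |positions|; objective maximises the summed wire interaction energy
    (all terms <= 0, so the least-binding feasible packing wins).
    ``forbidden_mutation_sets`` adds no-good cuts banning previously found
    amino-acid assignments; ``min_count_of`` adds per-amino-acid minimum
    selection counts (the iterative driver uses this to ratchet bulk).
    """
    positions = list(spec.positions)
    for p in positions:
        if p not in candidates or len(candidates[p]) == 0:
            raise InfeasibleDesignError(f"position {p} has no surviving rotamer candidate")

    index: list[tuple[tuple[str, int], int]] = []
    offsets: dict[tuple[str, int], int] = {}
    for p in positions:
        offsets[p] = len(index)
        for r in range(len(candidates[p])):
            index.append((p, r))
    n = len(index)
    energies = np.array([candidates[p][r][3] for p, r in index])

    rows_a: list[np.ndarray] = []
    lo: list[float] = []
    hi: list[float] = []

    # exactly one candidate per position
    for p in positions:
        row = np.zeros(n)
        row[offsets[p] : offsets[p] + len(candidates[p])] = 1.0
        rows_a.append(row)
        lo.append(1.0)
        hi.append(1.0)

    # pairwise clash exclusion (vectorised over candidate pairs)
    n_clash = 0
    atom_data: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for p in positions:
        coords, radii, owner = [], [], []
        for r, (_, _, res, _) in enumerate(candidates[p]):
            for a in res.heavy_atoms():
                coords.append(a.position)
                radii.append(_radius(a))
                owner.append(r)
        atom_data[p] = (np.array(coords), np.array(radii), np.array(owner))
    for i, p in enumerate(positions):
        cp, rp_, op_ = atom_data[p]
        for q in positions[i + 1 :]:
            cq, rq_, oq_ = atom_data[q]
            d = np.linalg.norm(cp[:, None, :] - cq[None, :, :], axis=-1)
            viol = d < spec.clash_overlap * (rp_[:, None] + rq_[None, :])
            if not viol.any():
                continue
            ii, jj = np.nonzero(viol)
            clash_pairs = set(zip(op_[ii].tolist(), oq_[jj].tolist()))
            for rp, rq in sorted(clash_pairs):
                row = np.zeros(n)
                row[offsets[p] + rp] = 1.0
                row[offsets[q] + rq] = 1.0
                rows_a.append(row)
                lo.append(-np.inf)
                hi.append(1.0)
                n_clash += 1

    # composition: enough long side chains
    long_mask = np.array([1.0 if candidates[p][r][0] in spec.long_aas else 0.0 for p, r in index])
    rows_a.append(long_mask)
    lo.append(spec.min_long_fraction * len(positions))
    hi.append(np.inf)

    # per-amino-acid minimum counts (bulk ratchet of the iterative driver)
    for aa, m in (min_count_of or {}).items():
        if m <= 0:
            continue
        row = np.array([1.0 if candidates[p][r][0] == aa else 0.0 for p, r in index])
        rows_a.append(row)
        lo.append(float(m))
        hi.append(np.inf)

    # no-good cuts on amino-acid assignments
    for banned in forbidden_mutation_sets:
        row = np.zeros(n)
        for j, (p, r) in enumerate(index):
            if banned.get(p) == candidates[p][r][0]:
                row[j] = 1.0
        rows_a.append(row)
        lo.append(-np.inf)
        hi.append(len(positions) - 1.0)

    A = np.vstack(rows_a)
    res = milp(
        c=-energies,  # maximise sum of (non-positive) energies
        constraints=LinearConstraint(A, lo, hi),
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleDesignError(
            f"rotamer MILP infeasible: {len(positions)} positions, {n} candidates, "
            f"{n_clash} clash constraints, long fraction >= {spec.min_long_fraction}"
        )
    x = np.round(res.x).astype(int)

    mutations: dict[tuple[str, int], str] = {}
    rotamers: dict[tuple[str, int], tuple[float, ...]] = {}
    energy = 0.0
    for j, (p, r) in enumerate(index):
        if x[j]:
            aa, chis, _, e = candidates[p][r]
            mutations[p] = aa
            rotamers[p] = chis
            energy += e
    return DesignCandidate(mutations=mutations, rotamers=rotamers, wire_interaction_energy=energy)


# ---------------------------------------------------------------------------
# Iterative design generation


def build_design_structure(
    structure: Structure, candidate: DesignCandidate
) -> Structure:
    """Full-atom mutant: WT scaffold with design side chains swapped in."""
    mutant = structure.copy()
    for key, aa in candidate.mutations.items():
        backbone = mutant.residue(*key)
        rot = build_rotamer(backbone, aa, candidate.rotamers[key])
        assign_vdw_radii_residue(rot)
        idx = next(i for i, r in enumerate(mutant.residues) if r.key == key)
        mutant.residues[idx] = rot
    return mutant


def generate_designs(
    structure: Structure,
    spec: DesignSpec,
    library: RotamerLibrary | None = None,
    wire: WaterWire | None = None,
    axis: PoreAxis | None = None,
    step: float = 0.5,
    probe_spacing: float = 0.25,
) -> list[DesignCandidate]:
    """Iterative MILP design with a design-assessment step per iteration.

    Each restart solves the rotamer MILP (under no-good cuts banning
    previous mutation sets and, after the first restart, seeded candidate
    subsampling), rebuilds the solution into a full-atom structure and
    re-profiles it.  A bulk ratchet adapts the proposals to the pore-size
    window: while solutions re-profile wider than ``d_max`` the minimum
    required count of the bulkiest allowed residue is raised by one, and
    lowered again if a solution undershoots ``d_min`` - the least-binding
    packing consistent with the current bulk level is proposed each time.
    A candidate is retained iff it passes :func:`accept_design` or binds
    the wire less than the wild-type side chains do.

    Deterministic for a fixed ``spec.seed``.  Returns candidates sorted by
    constriction diameter (ascending); an empty list (with a logged
    diagnostic summary) if nothing is retained.
    """
    if spec.restarts < 1:
        raise ValueError("spec.restarts must be >= 1")
    library = library or default_rotamer_library()
    if wire is None:
        raise ValueError("a placed WaterWire is required")
    if axis is None:
        from .pore_profile import compute_pore_axis

        axis = compute_pore_axis(structure)

    all_candidates = enumerate_candidates(structure, spec, library, wire)
    wt_energy = sum(
        interaction_energy(assign_vdw_radii_residue(structure.residue(*p).copy()), wire)
        for p in spec.positions
    )

    # bulk ratchet operates on the bulkiest amino acid that is actually available
    bulk_order = ("TRP", "TYR", "PHE", "MET", "LEU", "ILE", "VAL", "ALA")
    bulky_aa = next((aa for aa in bulk_order if aa in spec.allowed_aas), None)
    bulky_count = 0
    last_feasible_bulk = 0
    max_bulky = len(spec.positions)

    rng = np.random.default_rng(spec.seed)
    retained: list[DesignCandidate] = []
    seen_mutation_sets: list[dict[tuple[str, int], str]] = []
    n_infeasible = 0
    n_rejected = 0

    for restart in range(spec.restarts):
        if restart == 0 or spec.subsample >= 1.0:
            cands = all_candidates
        else:
            cands = {}
            for p, lst in all_candidates.items():
                if len(lst) <= 1:
                    cands[p] = lst
                    continue
                k = max(1, int(round(spec.subsample * len(lst))))
                keep = rng.choice(len(lst), size=k, replace=False)
                cands[p] = [lst[i] for i in sorted(keep)]
        min_counts = {bulky_aa: bulky_count} if bulky_aa else None
        try:
            cand = select_rotamers_milp(
                structure, spec, cands, wire, seen_mutation_sets, min_count_of=min_counts
            )
        except InfeasibleDesignError:
            try:  # subsampling may have discarded the only packable rotamers
                cand = select_rotamers_milp(
                    structure, spec, all_candidates, wire, seen_mutation_sets,
                    min_count_of=min_counts,
                )
            except InfeasibleDesignError:
                n_infeasible += 1
                # ratchet overshot what packing allows: bisect back
                bulky_count = (last_feasible_bulk + bulky_count) // 2
                continue
        seen_mutation_sets.append(dict(cand.mutations))
        last_feasible_bulk = bulky_count

        mutant = build_design_structure(structure, cand)
        profile = compute_profile(mutant, axis=axis, step=step, probe_spacing=probe_spacing)
        try:
            constriction = find_constriction(profile)
        except OccludedPoreError:
            n_rejected += 1
            if bulky_count > 0:
                bulky_count -= 1
            continue
        cand.structure = mutant
        cand.profile = profile
        cand.constriction = constriction
        cand.accepted = accept_design(cand, spec)

        # design assessment: adapt the bulk level toward the window
        # (~0.6 Å of closure per added bulky residue on typical scaffolds)
        if constriction.diameter > spec.d_max:
            excess = constriction.diameter - spec.d_max
            bulky_count = min(max_bulky, bulky_count + max(1, int(excess / 0.6)))
        elif constriction.diameter < spec.d_min and bulky_count > 0:
            bulky_count -= 1

        if cand.accepted or cand.wire_interaction_energy > wt_energy:
            if not any(c.mutations == cand.mutations for c in retained):
                retained.append(cand)
        else:
            n_rejected += 1

    retained.sort(key=lambda c: (c.diameter if c.diameter is not None else math.inf))
    if not retained:
        logger.info(
            "generate_designs retained nothing: %d restarts, %d infeasible, "
            "%d rejected by window/energy (WT wire energy %.3f kcal/mol)",
            spec.restarts,
            n_infeasible,
            n_rejected,
            wt_energy,
        )
    return retained
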