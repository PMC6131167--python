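"""Self-contained synthetic test inputs.

Everything the geometry, design and transport modules consume can be
generated here at run time, seeded and deterministic:

* idealized beta-barrel scaffolds with full N/CA/C/O backbones and pseudo
  side chains (single CB-like centroid atoms), optionally pinched inward
  over a central band to create a constriction of known location,
* analytic cavities (cylinder, elliptic cylinder, hourglass of revolution)
  whose open cross-sections have closed-form axes, for exact profile
  oracles,
* straight or helical single-file water wires with exact O-O spacing,
* the three archetype pore-closure topologies (off-center, single-plane
  uniform, cork-screw) as ready-made design candidates,
* double-exponential stopped-flow light-scattering traces with additive
  Gaussian noise.

The barrels are geometric stand-ins for a real porin scaffold at desk
scale: they have no hydrogen-bond network, no loops and no sequence, which
is exactly what makes their pore geometry analytically known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design_engine import DesignCandidate, WaterWire, WIRE_SPACING_MAX, WIRE_SPACING_MIN
from .pore_profile import compute_pore_axis, compute_profile, find_constriction
from .structure_io import Atom, Residue, Structure, assign_vdw_radii

__all__ = [
    "BarrelParams",
    "TraceParams",
    "make_barrel",
    "make_cylinder_cavity",
    "make_elliptic_cavity",
    "make_hourglass_cavity",
    "make_water_wire",
    "make_archetype_design",
    "make_stopped_flow_trace",
]


# ---------------------------------------------------------------------------
# Barrels


@dataclass
class BarrelParams:
    """Geometry of an idealized antiparallel beta-barrel pore."""

    n_strands: int = 14
    barrel_radius: float = 12.0  # Å, CA cylinder radius
    height: float = 30.0  # Å
    rise_per_residue: float = 3.3  # Å along the strand
    inward_positions: frozenset[int] | None = None  # seq numbers; None = alternate rings
    constriction_bulge: float = 0.0  # Å of radial inward displacement
    bulge_band: float = 6.0  # Å axial band receiving the bulge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 8:
            raise ValueError("n_strands must be >= 8")
        if self.barrel_radius <= 5.0:
            raise ValueError("barrel_radius must exceed 5 Å")
        if self.constriction_bulge >= self.barrel_radius:
            raise ValueError("constriction_bulge must be smaller than barrel_radius")
        # tightest ring is the bulged one; below ~2.5 Å the strands collide
        r_min = self.barrel_radius - self.constriction_bulge
        chord = 2.0 * r_min * math.sin(math.pi / self.n_strands)
        if chord < 2.5:
            raise ValueError(
                f"strand overlap: inter-strand chord {chord:.2f} Å < 2.5 Å "
                f"({self.n_strands} strands on bulged radius {r_min} Å)"
            )


# canonical backbone template (ideal L-residue); _CANON_CB is the improper
# construction of design_engine applied to it, so rebuilding a side chain on
# a template-derived backbone reproduces the intended CB direction exactly
_CANON_N = np.array([1.458, 0.0, 0.0])
_CANON_CA = np.zeros(3)
_CANON_C = np.array([-0.551, 1.420, 0.0])


def _canon_cb() -> np.ndarray:
    from .design_engine import _CB_ANGLE, _CB_BOND, _CB_TORSION, _nerf

    return _nerf(_CANON_C, _CANON_N, _CANON_CA, _CB_BOND, _CB_ANGLE, _CB_TORSION)


_CANON_CB = None  # filled lazily to avoid an import cycle at module load


def _backbone_atoms(
    ca: np.ndarray, strand_dir: np.ndarray, cb_dir: np.ndarray
) -> list[Atom]:
    """N/CA/C/O oriented so a rebuilt side chain points along ``cb_dir``.

    The canonical backbone template is rigidly rotated so its CB direction
    maps exactly onto ``cb_dir`` while its N->C vector follows the strand
    direction as closely as the fixed CB/backbone geometry allows.
    """
    global _CANON_CB
    if _CANON_CB is None:
        _CANON_CB = _canon_cb()

    d = _unit(np.asarray(cb_dir, float))
    k = _unit(np.asarray(strand_dir, float))

    e1 = _unit(_CANON_CB - _CANON_CA)
    nc = _CANON_C - _CANON_N
    e2 = _unit(nc - np.dot(nc, e1) * e1)
    e3 = np.cross(e1, e2)
    f1 = d
    k_perp = k - np.dot(k, f1) * f1
    if np.linalg.norm(k_perp) < 1e-8:  # strand parallel to CB: pick any normal
        k_perp = np.array([0.0, 0.0, 1.0]) - f1[2] * f1
        if np.linalg.norm(k_perp) < 1e-8:
            k_perp = np.array([1.0, 0.0, 0.0]) - f1[0] * f1
    f2 = _unit(k_perp)
    f3 = np.cross(f1, f2)
    R = np.column_stack([f1, f2, f3]) @ np.column_stack([e1, e2, e3]).T

    n_pos = ca + R @ (_CANON_N - _CANON_CA)
    c_pos = ca + R @ (_CANON_C - _CANON_CA)
    o_dir = _unit((_CANON_C - _CANON_CA) + (_CANON_C - _CANON_N))
    o_pos = c_pos + 1.23 * (R @ o_dir)
    return [
        Atom("N", "N", n_pos),
        Atom("CA", "C", ca),
        Atom("C", "C", c_pos),
        Atom("O", "O", o_pos),
    ]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_barrel(params: BarrelParams) -> Structure:
    """Idealized antiparallel barrel with pseudo side chains.

    CA atoms sit on a cylinder of ``barrel_radius``; each residue carries a
    full backbone (oriented so a rebuilt side chain points the right way)
    plus one CB pseudo-atom pointing inward (for ``inward_positions``) or
    outward.  Residues whose z falls within ``bulge_band`` of the barrel
    midplane are displaced inward by ``constriction_bulge``, creating a
    constriction at the band centre.  Deterministic for fixed parameters.
    """
    n_res = int(math.floor(params.height / params.rise_per_residue)) + 1
    residues: list[Residue] = []
    seq = 0
    for s in range(params.n_strands):
        theta = 2.0 * math.pi * s / params.n_strands
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward radial
        direction = 1.0 if s % 2 == 0 else -1.0  # antiparallel strands
        k = np.array([0.0, 0.0, direction])
        for j in range(n_res):
            seq += 1
            z = -params.height / 2.0 + j * params.rise_per_residue
            if direction < 0:
                z = params.height / 2.0 - j * params.rise_per_residue
            radius = params.barrel_radius
            if abs(z) <= params.bulge_band / 2.0 and params.constriction_bulge > 0:
                radius -= params.constriction_bulge
            ca = radius * u + np.array([0.0, 0.0, z])
            if params.inward_positions is None:
                inward = j % 2 == 0  # beta alternation: whole rings face in or out
            else:
                inward = seq in params.inward_positions
            cb_dir = -u if inward else u
            atoms = _backbone_atoms(ca, k, cb_dir)
            atoms.append(Atom("CB", "C", ca + 1.53 * cb_dir))
            residues.append(Residue("A", seq, "ALA", atoms))

    # seal the inter-strand seams (the sheet's hydrogen-bonded wall) with
    # filler pseudo-atoms in non-protein residues so geometry operations on
    # protein residues never see them
    filler_atoms: list[Atom] = []
    z_lo, z_hi = -params.height / 2.0, params.height / 2.0
    for s in range(params.n_strands):
        theta = 2.0 * math.pi * (s + 0.5) / params.n_strands
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        for z in np.arange(z_lo, z_hi + 0.75, 1.5):
            radius = params.barrel_radius + 1.2  # just outside the CA cylinder
            if abs(z) <= params.bulge_band / 2.0 and params.constriction_bulge > 0:
                radius -= params.constriction_bulge
            filler_atoms.append(Atom("W", "C", radius * u + np.array([0.0, 0.0, float(z)])))
    residues.append(Residue("X", 1, "UNK", filler_atoms))

    structure = Structure(residues=residues, title="synthetic idealized barrel", source_id="barrel")
    return assign_vdw_radii(structure)


# ---------------------------------------------------------------------------
# Analytic cavities (exact oracles)


def _wall_structure(rings: list[tuple[float, np.ndarray]], atom_radius: float) -> Structure:
    """Residues of single CA atoms at given (z, ring-of-centres) positions."""
    residues = []
    seq = 0
    for z, centres in rings:
        for c in centres:
            seq += 1
            a = Atom("CA", "C", np.array([c[0], c[1], z]))
            a.vdw_radius = atom_radius
            residues.append(Residue("A", seq, "ALA", [a]))
    return Structure(residues=residues, title="synthetic analytic cavity", source_id="cavity")


def make_cylinder_cavity(
    radius: float, height: float = 20.0, atom_radius: float = 1.7, spacing: float = 0.8
) -> Structure:
    """Smooth cylindrical cavity: open cross-section is a circle of ``radius``.

    Wall atom centres sit at ``radius + atom_radius`` so the vdW inner
    surface is the analytic cylinder.
    """
    rc = radius + atom_radius
    n_az = max(8, int(math.ceil(2 * math.pi * rc / spacing)))
    angles = 2 * math.pi * np.arange(n_az) / n_az
    ring = np.stack([rc * np.cos(angles), rc * np.sin(angles)], axis=1)
    zs = np.arange(-height / 2, height / 2 + spacing / 2, spacing)
    return _wall_structure([(float(z), ring) for z in zs], atom_radius)


def make_elliptic_cavity(
    semi_major: float,
    semi_minor: float,
    height: float = 20.0,
    atom_radius: float = 1.7,
    spacing: float = 0.8,
) -> Structure:
    """Elliptic-cylinder cavity: open cross-section has the given semi-axes.

    Wall centres are offset outward along the local ellipse normal by
    ``atom_radius``.
    """
    # parametrise densely enough that arc spacing <= spacing
    n_az = max(16, int(math.ceil(2 * math.pi * (semi_major + atom_radius) / (0.5 * spacing))))
    t = 2 * math.pi * np.arange(n_az) / n_az
    x = semi_major * np.cos(t)
    y = semi_minor * np.sin(t)
    # outward normal of the ellipse at parameter t
    nx = semi_minor * np.cos(t)
    ny = semi_major * np.sin(t)
    norm = np.hypot(nx, ny)
    ring = np.stack([x + atom_radius * nx / norm, y + atom_radius * ny / norm], axis=1)
    zs = np.arange(-height / 2, height / 2 + spacing / 2, spacing)
    return _wall_structure([(float(z), ring) for z in zs], atom_radius)


def make_hourglass_cavity(
    waist_radius: float,
    curvature: float = 0.05,
    height: float = 20.0,
    atom_radius: float = 1.7,
    spacing: float = 0.8,
) -> Structure:
    """Hourglass of revolution: open radius r(z) = waist_radius + curvature z²."""
    rings = []
    for z in np.arange(-height / 2, height / 2 + spacing / 2, spacing):
        r = waist_radius + curvature * z * z
        rc = r + atom_radius
        n_az = max(8, int(math.ceil(2 * math.pi * rc / spacing)))
        angles = 2 * math.pi * np.arange(n_az) / n_az
        ring = np.stack([rc * np.cos(angles), rc * np.sin(angles)], axis=1)
        rings.append((float(z), ring))
    return _wall_structure(rings, atom_radius)


# ---------------------------------------------------------------------------
# Water wires


def make_water_wire(n: int, spacing: float = 2.8, helicity: float = 0.0) -> WaterWire:
    """Single-file wire of ``n`` oxygens with exact consecutive spacing.

    ``helicity`` (degrees per water) winds the wire on a thin helix of
    0.75 Å radius; 0 gives a straight wire on the z axis.  The exact O-O
    spacing is preserved in either case.
    """
    if n < 2:
        raise ValueError("a wire needs at least 2 oxygens")
    if not (WIRE_SPACING_MIN <= spacing <= WIRE_SPACING_MAX):
        raise ValueError(
            f"spacing {spacing} Å outside the single-file window "
            f"[{WIRE_SPACING_MIN}, {WIRE_SPACING_MAX}] Å"
        )
    if helicity == 0.0:
        zs = (np.arange(n) - (n - 1) / 2.0) * spacing
        coords = np.stack([np.zeros(n), np.zeros(n), zs], axis=1)
        return WaterWire(coords, label=f"straight-{n}")
    r_h = 0.75
    phi = math.radians(helicity)
    chord = 2.0 * r_h * math.sin(phi / 2.0)
    if chord >= spacing:
        raise ValueError("helicity too large for the requested spacing")
    dz = math.sqrt(spacing**2 - chord**2)
    idx = np.arange(n)
    coords = np.stack(
        [r_h * np.cos(idx * phi), r_h * np.sin(idx * phi), (idx - (n - 1) / 2.0) * dz], axis=1
    )
    return WaterWire(coords, label=f"helical-{n}-{helicity:g}")


# ---------------------------------------------------------------------------
# Archetype designs


def make_archetype_design(kind: str, base: BarrelParams | None = None) -> DesignCandidate:
    """A ready-made design candidate of topology ``kind`` (OCD/UCD/CSD).

    Built from a smooth barrel wall plus pseudo long/short side chains:

    * ``OCD``: long chains crowd one angular half of the constriction ring,
      displacing the open centre by >= 2 Å,
    * ``UCD``: long chains alternate with short ones around a single slice
      plane, shrinking the eyelet concentrically,
    * ``CSD``: long chains stack along the axis with a steady azimuthal
      advance, corkscrew-twisting the open centre.

    The candidate carries its structure, profile and constriction; the
    mutation map labels long positions TRP and short ones ALA.
    """
    kind = kind.upper()
    if kind not in ("OCD", "UCD", "CSD"):
        raise ValueError("kind must be OCD, UCD or CSD")
    base = base or BarrelParams()
    wall = make_cylinder_cavity(base.barrel_radius - 1.7, height=base.height)
    residues = list(wall.residues)
    seq = max(r.seq_number for r in residues)

    mutations: dict[tuple[str, int], str] = {}
    rotamers: dict[tuple[str, int], tuple[float, ...]] = {}
    R = base.barrel_radius - 1.7  # lumen radius of the smooth wall

    def add_side_chain(theta: float, z: float, long_chain: bool) -> None:
        nonlocal seq
        seq += 1
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = np.array([R * u[0], R * u[1], z])
        atoms = [Atom("CA", "C", ca)]
        reach = (1.5, 3.0, 4.5) if long_chain else (1.5,)
        for i, t in enumerate(reach):
            a = Atom(f"CB{i if i else ''}", "C", ca - t * u)
            a.vdw_radius = 2.0
            atoms.append(a)
        atoms[0].vdw_radius = 1.7
        res = Residue("A", seq, "TRP" if long_chain else "ALA", atoms)
        residues.append(res)
        mutations[res.key] = res.aa_type
        rotamers[res.key] = ()

    n_ring = 12
    if kind == "OCD":
        for i in range(n_ring):
            theta = 2 * math.pi * i / n_ring
            long_chain = math.cos(theta) > 0  # crowd the +x half only
            add_side_chain(theta, 0.0, long_chain)
    elif kind == "UCD":
        for i in range(n_ring):
            theta = 2 * math.pi * i / n_ring
            add_side_chain(theta, 0.0, i % 2 == 0)
    else:  # CSD: alternating long/short climbing the axis with a twist
        n_steps = 8
        for j in range(n_steps):
            z = -4.2 + 1.2 * j
            theta = math.radians(25.0 * j)
            add_side_chain(theta, z, j % 2 == 0)

    structure = Structure(
        residues=residues, title=f"synthetic {kind} archetype", source_id=f"archetype-{kind}"
    )
    for res in structure.residues:
        for a in res.atoms:
            if a.vdw_radius is None:
                a.vdw_radius = 1.7

    axis = compute_pore_axis(structure)
    profile = compute_profile(structure, axis=axis)
    constriction = find_constriction(profile)
    return DesignCandidate(
        mutations=mutations,
        rotamers=rotamers,
        constriction=constriction,
        accepted=True,
        structure=structure,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Stopped-flow traces


@dataclass
class TraceParams:
    """Double-exponential decay with additive Gaussian noise."""

    k1: float = 20.0  # 1/s, fast rate
    k2: float = 2.0  # 1/s, slow rate
    A1: float = 0.6
    A2: float = 0.3
    C: float = 0.1
    duration: float = 1.0  # s
    n_points: int = 500
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k1 > self.k2 > 0):
            raise ValueError("need k1 > k2 > 0")
        if self.n_points < 20:
            raise ValueError("need at least 20 points")


def make_stopped_flow_trace(params: TraceParams):
    """Seeded synthetic light-scattering decay, ready for the fitter."""
    from .scoring_transport import StoppedFlowTrace

    t = np.linspace(0.0, params.duration, params.n_points)
    clean = params.A1 * np.exp(-params.k1 * t) + params.A2 * np.exp(-params.k2 * t) + params.C
    rng = np.random.default_rng(params.seed)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=t.shape) if params.noise_sd > 0 else clean
    return StoppedFlowTrace(time=t, intensity=noisy)
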