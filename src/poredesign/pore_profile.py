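"""Pore geometry analysis for channel proteins (the "PoreAnalyzer").

Given a structure with assigned van der Waals radii, this module computes

* the pore axis (principal axis of the CA cloud),
* a slice-wise profile of the open cross-section along that axis: each
  slice is rasterised on a grid, grid points inside any atom's vdW sphere
  are blocked, the open region connected to the axis is flood-filled, and
  an equal-area ellipse is fitted to its second moments,
* the constriction (slice of minimal elliptical minor axis); the pore
  "size"/"diameter" of a design is the minor axis of this ellipse,
* pore-lining residues near the constriction,
* inner/outer wall classification of barrel residues (side chain pointing
  into the lumen vs. out toward the lipid),
* a geometric water-protein hydrogen-bond count (3.0 Å distance and
  ≤ 20° protein-atom - water-H - water-O angle criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .structure_io import Structure

__all__ = [
    "PoreAxis",
    "PoreSlice",
    "PoreProfile",
    "ConstrictionGeometry",
    "OccludedPoreError",
    "DegenerateAxisError",
    "compute_pore_axis",
    "compute_profile",
    "find_constriction",
    "identify_pore_lining_residues",
    "classify_wall_residues",
    "count_water_protein_hbonds",
]

DEFAULT_STEP = 0.5  # Å between slices
DEFAULT_PROBE_SPACING = 0.25  # Å grid spacing within a slice
DEFAULT_BAND = 6.0  # Å axial band around the constriction for lining residues
DEFAULT_SHELL = 1.4  # Å water-probe-sized shell for "lining" contact


class OccludedPoreError(RuntimeError):
    """Signalled when the pore has no open slice to analyse."""


class DegenerateAxisError(ValueError):
    """Raised when the CA set is degenerate (e.g. coplanar)."""


@dataclass(frozen=True)
class PoreAxis:
    """A line in space: origin plus unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis direction must be a nonzero vector")
        object.__setattr__(self, "direction", d / n)

    def frame(self) -> np.ndarray:
        """Orthonormal frame (3x3, rows ex, ey, ez) with ez = direction."""
        ez = self.direction
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, ez)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        ex = seed - np.dot(seed, ez) * ez
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        return np.vstack([ex, ey, ez])

    def to_axis_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into the axis frame (axis = z through origin)."""
        return (np.atleast_2d(points) - self.origin) @ self.frame().T


@dataclass(frozen=True)
class PoreSlice:
    """Open cross-section of one slice: equal-area ellipse descriptors."""

    z: float
    center: np.ndarray  # in-slice (x, y) of the open-region centroid, Å
    major_axis: float  # full length, Å
    minor_axis: float  # full length, Å
    open_area: float  # Å²

    @property
    def is_open(self) -> bool:
        return self.open_area > 0.0


@dataclass
class PoreProfile:
    """Ordered slices at uniform axial step, in the axis frame."""

    slices: list[PoreSlice]
    step: float
    axis: PoreAxis | None = None

    def __iter__(self):
        return iter(self.slices)

    def __len__(self) -> int:
        return len(self.slices)

    def open_slices(self) -> list[PoreSlice]:
        return [s for s in self.slices if s.is_open]

    def to_table(self) -> "list[dict]":
        return [
            {
                "z": s.z,
                "major_axis": s.major_axis,
                "minor_axis": s.minor_axis,
                "open_area": s.open_area,
                "cx": float(s.center[0]),
                "cy": float(s.center[1]),
            }
            for s in self.slices
        ]


@dataclass(frozen=True)
class ConstrictionGeometry:
    """The narrowest open slice of a profile."""

    slice: PoreSlice
    diameter: float  # = slice.minor_axis, Å
    center_offset: float  # in-plane distance of the open center from the axis, Å


# ---------------------------------------------------------------------------
# Axis


def compute_pore_axis(structure: Structure) -> PoreAxis:
    """Principal axis of the CA atoms, through their centroid.

    The sign is chosen so that +z points from the first residue's projection
    toward the last residue's.  Raises :class:`DegenerateAxisError` for
    degenerate (e.g. coplanar) CA sets, for which no barrel axis exists.
    """
    cas = structure.ca_coordinates()
    if len(cas) < 3:
        raise DegenerateAxisError("need at least 3 CA atoms to define a pore axis")
    centroid = cas.mean(axis=0)
    cov = np.cov((cas - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-8:  # one vanishing variance direction: coplanar points
        raise DegenerateAxisError("CA atoms are (nearly) coplanar; no unique pore axis")
    direction = evecs[:, -1]
    span = cas[-1] - cas[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    return PoreAxis(origin=centroid, direction=direction)


# ---------------------------------------------------------------------------
# Profile


def compute_profile(
    structure: Structure,
    axis: PoreAxis | None = None,
    step: float = DEFAULT_STEP,
    probe_spacing: float = DEFAULT_PROBE_SPACING,
    z_range: tuple[float, float] | None = None,
) -> PoreProfile:
    """Slice-wise open-area ellipse profile along the pore axis.

    For each slice plane, an in-plane occupancy grid (spacing
    ``probe_spacing``) marks a point blocked iff it lies within the vdW
    sphere of any atom whose sphere intersects the plane.  The open region
    connected (4-neighbour) to the axis intersection is flood-filled; its
    second moments give an ellipse rescaled to the exact region area.
    Slices whose axis point is blocked carry ``open_area = 0`` rather than
    aborting, so partially occluded designs remain analyzable.
    """
    if step <= 0 or probe_spacing <= 0:
        raise ValueError("step and probe_spacing must be positive")
    if axis is None:
        axis = compute_pore_axis(structure)

    atoms = [a for a in structure.atoms(heavy_only=True)]
    if not atoms:
        raise ValueError("structure has no heavy atoms")
    for a in atoms:
        if a.vdw_radius is None:
            raise ValueError("assign_vdw_radii must be called before compute_profile")

    pts = axis.to_axis_frame(np.array([a.position for a in atoms]))
    radii = np.array([a.vdw_radius for a in atoms])

    if z_range is None:
        zmin, zmax = float(pts[:, 2].min()), float(pts[:, 2].max())
    else:
        zmin, zmax = z_range
    n_slices = max(1, int(math.floor((zmax - zmin) / step)) + 1)

    # lateral grid extent: bounding box of atoms plus margin
    margin = float(radii.max()) + 2 * probe_spacing
    xmin, xmax = float(pts[:, 0].min()) - margin, float(pts[:, 0].max()) + margin
    ymin, ymax = float(pts[:, 1].min()) - margin, float(pts[:, 1].max()) + margin
    nx = int(round((xmax - xmin) / probe_spacing)) + 1
    ny = int(round((ymax - ymin) / probe_spacing)) + 1
    xs = xmin + probe_spacing * np.arange(nx)
    ys = ymin + probe_spacing * np.arange(ny)
    seed_ix = int(round((0.0 - xmin) / probe_spacing))
    seed_iy = int(round((0.0 - ymin) / probe_spacing))
    seed_inside = 0 <= seed_ix < nx and 0 <= seed_iy < ny

    order = np.argsort(pts[:, 2], kind="stable")
    pts_sorted = pts[order]
    radii_sorted = radii[order]
    zs_sorted = pts_sorted[:, 2]

    slices: list[PoreSlice] = []
    half = step / 2.0
    rmax = float(radii.max())
    for i in range(n_slices):
        z = zmin + i * step
        lo = np.searchsorted(zs_sorted, z - half - rmax)
        hi = np.searchsorted(zs_sorted, z + half + rmax)
        sub = pts_sorted[lo:hi]
        rr = radii_sorted[lo:hi]
        # an atom blocks the slice band [z-half, z+half]: use the widest
        # in-plane disc the sphere presents anywhere inside the band
        dz = np.clip(np.abs(sub[:, 2] - z) - half, 0.0, None)
        keep = dz < rr
        sub, rr, dz = sub[keep], rr[keep], dz[keep]
        disc = np.sqrt(rr * rr - dz * dz)

        blocked = np.zeros((nx, ny), dtype=bool)
        for (ax, ay, _), dr in zip(sub, disc):
            i0 = max(0, int(math.ceil((ax - dr - xmin) / probe_spacing)))
            i1 = min(nx - 1, int(math.floor((ax + dr - xmin) / probe_spacing)))
            if i1 < i0:
                continue
            lx = xs[i0 : i1 + 1] - ax
            j0 = max(0, int(math.ceil((ay - dr - ymin) / probe_spacing)))
            j1 = min(ny - 1, int(math.floor((ay + dr - ymin) / probe_spacing)))
            if j1 < j0:
                continue
            ly = ys[j0 : j1 + 1] - ay
            mask = (lx[:, None] ** 2 + ly[None, :] ** 2) < dr * dr
            blocked[i0 : i1 + 1, j0 : j1 + 1] |= mask

        open_slice = _empty_slice(z)
        if seed_inside and not blocked[seed_ix, seed_iy]:
            labels, _ = ndimage.label(~blocked)
            region = labels == labels[seed_ix, seed_iy]
            open_slice = _ellipse_from_region(region, xs, ys, probe_spacing, z)
        slices.append(open_slice)

    return PoreProfile(slices=slices, step=step, axis=axis)


def _empty_slice(z: float) -> PoreSlice:
    return PoreSlice(z=z, center=np.zeros(2), major_axis=0.0, minor_axis=0.0, open_area=0.0)


def _ellipse_from_region(
    region: np.ndarray, xs: np.ndarray, ys: np.ndarray, spacing: float, z: float
) -> PoreSlice:
    ii, jj = np.nonzero(region)
    n = len(ii)
    if n == 0:
        return _empty_slice(z)
    px = xs[ii]
    py = ys[jj]
    area = n * spacing * spacing
    cx, cy = float(px.mean()), float(py.mean())
    dx, dy = px - cx, py - cy
    # second moments incl. the per-cell square contribution (s²/12)
    cell = spacing * spacing / 12.0
    mxx = float(np.mean(dx * dx)) + cell
    myy = float(np.mean(dy * dy)) + cell
    mxy = float(np.mean(dx * dy))
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 1e-12, None)
    # uniform ellipse with semi-axes a >= b has moment eigenvalues a²/4, b²/4
    b_semi, a_semi = 2.0 * np.sqrt(evals[0]), 2.0 * np.sqrt(evals[1])
    scale = math.sqrt(area / (math.pi * a_semi * b_semi))
    a_semi *= scale
    b_semi *= scale
    return PoreSlice(
        z=z,
        center=np.array([cx, cy]),
        major_axis=2.0 * a_semi,
        minor_axis=2.0 * b_semi,
        open_area=area,
    )


def find_constriction(profile: PoreProfile) -> ConstrictionGeometry:
    """The open slice of minimal minor axis.

    Ties are broken by smaller open area, then by smaller z.  A fully
    occluded profile raises :class:`OccludedPoreError`.
    """
    open_slices = profile.open_slices()
    if not open_slices:
        raise OccludedPoreError("profile has no open slice (occluded pore)")
    best = min(open_slices, key=lambda s: (s.minor_axis, s.open_area, s.z))
    return ConstrictionGeometry(
        slice=best,
        diameter=best.minor_axis,
        center_offset=float(np.linalg.norm(best.center)),
    )


# ---------------------------------------------------------------------------
# Residue-level geometry


def identify_pore_lining_residues(
    structure: Structure,
    constriction: ConstrictionGeometry,
    profile: PoreProfile,
    band: float = DEFAULT_BAND,
    shell: float = DEFAULT_SHELL,
) -> list[tuple[str, int]]:
    """Residues lining the pore near the constriction.

    A residue qualifies if at least one side-chain heavy atom lies within
    ±``band`` of the constriction z and within ``shell`` of the open
    region's boundary (measured from the atom's vdW surface to the nearest
    open grid point of its slice).  Returned sorted by (chain, seq_number).
    """
    axis = profile.axis
    if axis is None:
        raise ValueError("profile must carry its axis")
    zc = constriction.slice.z
    open_by_z = {
        s.z: s for s in profile.slices if s.is_open and abs(s.z - zc) <= band + profile.step
    }
    if not open_by_z:
        return []
    zs = np.array(sorted(open_by_z))

    hits: set[tuple[str, int]] = set()
    for res in structure.protein_residues():
        side = res.side_chain_atoms()
        if not side:
            # glycine: fall back to CA so bulgeless walls can still qualify
            side = [a for a in res.atoms if a.name == "CA"]
        for a in side:
            p = axis.to_axis_frame(a.position)[0]
            if abs(p[2] - zc) > band:
                continue
            kz = zs[np.argmin(np.abs(zs - p[2]))]
            s = open_by_z[kz]
            # distance from atom surface to the open-region center, minus the
            # region's mean radius: a cheap boundary-distance surrogate that is
            # exact for circular regions
            mean_r = math.sqrt(s.open_area / math.pi)
            d_center = float(np.hypot(p[0] - s.center[0], p[1] - s.center[1]))
            d_boundary = d_center - mean_r - (a.vdw_radius or 0.0)
            if d_boundary <= shell:
                hits.add(res.key)
                break
    return sorted(hits)


def classify_wall_residues(
    structure: Structure, axis: PoreAxis
) -> dict[tuple[str, int], str]:
    """Label every protein residue ``"inner"`` or ``"outer"``.

    A residue is *inner* iff the radial distance (from the axis) of its
    side-chain heavy-atom centroid is not larger than that of its CA, i.e.
    its side chain protrudes into the barrel lumen.  Glycine, which has no
    side chain, is classified by the direction opposite the N/C bisector
    (the direction a CB would take).  Ties classify as inner.
    """
    labels: dict[tuple[str, int], str] = {}
    for res in structure.protein_residues():
        if not res.has_atom("CA"):
            continue
        ca = axis.to_axis_frame(res.atom("CA").position)[0]
        side = res.side_chain_atoms()
        if side:
            cen = axis.to_axis_frame(np.mean([a.position for a in side], axis=0))[0]
        else:
            try:
                n = res.atom("N").position
                c = res.atom("C").position
            except KeyError:
                labels[res.key] = "inner"
                continue
            pseudo = res.atom("CA").position + (res.atom("CA").position - 0.5 * (n + c))
            cen = axis.to_axis_frame(pseudo)[0]
        r_side = float(np.hypot(cen[0], cen[1]))
        r_ca = float(np.hypot(ca[0], ca[1]))
        labels[res.key] = "inner" if r_side <= r_ca else "outer"
    return labels


# ---------------------------------------------------------------------------
# Hydrogen bonds

#: protein atoms accepted as H-bond donors/acceptors: backbone N/O and
#: polar side-chain nitrogens/oxygens (plus S of Cys/Met as weak acceptors)
_POLAR_ELEMENTS = {"N", "O", "S"}

HBOND_DISTANCE = 3.0  # Å, water O to protein donor/acceptor
HBOND_ANGLE = 20.0  # degrees, protein-atom - water-H - water-O


def count_water_protein_hbonds(
    structure: Structure,
    water_frames: Sequence[Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]],
    region: tuple[float, float],
    axis: PoreAxis | None = None,
) -> float:
    """Average geometric water-protein hydrogen-bond count per frame.

    Each frame is a sequence of waters given as (O, H1, H2) coordinate
    triples.  A bond is counted iff the water oxygen lies within 3.0 Å of a
    polar protein atom (N, O or S) and the protein-atom - water-H - water-O
    angle is 20° or less for either hydrogen.  Only waters whose oxygen
    falls in the axial ``region`` (Å, in the axis frame) are considered.
    """
    if axis is None:
        axis = compute_pore_axis(structure)
    polar = [
        a.position
        for res in structure.protein_residues()
        for a in res.atoms
        if a.element in _POLAR_ELEMENTS
    ]
    if not polar:
        return 0.0
    polar_arr = np.array(polar)
    zlo, zhi = min(region), max(region)

    total = 0
    n_frames = 0
    for frame in water_frames:
        n_frames += 1
        for water in frame:
            if len(water) < 3:
                raise ValueError(
                    "waters must carry hydrogens: provide (O, H1, H2) coordinates"
                )
            o = np.asarray(water[0], float)
            z = float(axis.to_axis_frame(o)[0][2])
            if not (zlo <= z <= zhi):
                continue
            d = np.linalg.norm(polar_arr - o, axis=1)
            close = polar_arr[d <= HBOND_DISTANCE]
            if len(close) == 0:
                continue
            bonded = False
            for h in water[1:]:
                h = np.asarray(h, float)
                # deviation of the H from the O...acceptor line: the angle
                # between O->H and H->acceptor is 0° for a linear H-bond
                oh = h - o
                oh /= np.linalg.norm(oh)
                hp = close - h
                hp /= np.linalg.norm(hp, axis=1)[:, None]
                cosang = hp @ oh
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if np.any(ang <= HBOND_ANGLE):
                    bonded = True
                    break
            if bonded:
                total += 1
    if n_frames == 0:
        return 0.0
    return total / n_frames
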