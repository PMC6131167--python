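"""Classify redesigned pores into the three closure topologies.

Narrowed pores fall into three geometric families:

* **OCD** (off-center closure): the open lumen survives but its centre is
  displaced toward the barrel perimeter - bulky residues crowd one side.
* **UCD** (uniform closure): a smaller, nearly concentric eyelet with the
  bulky side chains arranged in a single slice plane.
* **CSD** (cork-screw): alternating long/short side chains stack along the
  axis so the open centre corkscrews - a lateral twist of the slice
  centres as one proceeds along the pore.

The verbal topology descriptions are operationalised here as four metrics
(centre offset, bulky-group axial spread, azimuthal twist span,
long/short alternation) with tunable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design_engine import DesignCandidate, LONG_AAS
from .pore_profile import PoreProfile

__all__ = [
    "ClassificationMetrics",
    "ClassifierThresholds",
    "UnclassifiableDesignError",
    "compute_metrics",
    "classify_design",
]

#: slices with centre offset below this are azimuthally meaningless
_MIN_OFFSET_FOR_AZIMUTH = 0.2  # Å


class UnclassifiableDesignError(RuntimeError):
    """The candidate's pore is occluded; topology metrics are undefined."""


@dataclass(frozen=True)
class ClassificationMetrics:
    """Geometric signature of a design relative to the WT pore."""

    center_offset: float  # Å, constriction centre displacement from WT centre
    bulky_z_spread: float  # Å, std of axial coords of long-residue side-chain centroids
    twist_span: float  # degrees of monotone azimuthal progression across the band
    alternation_score: float  # in [0, 1]: adjacent long/short alternation along z

    def __post_init__(self) -> None:
        for name in ("center_offset", "bulky_z_spread", "twist_span", "alternation_score"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.alternation_score > 1.0:
            raise ValueError("alternation_score must be <= 1")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds; defaults are this package's, exposed as tunable."""

    t_off: float = 1.5  # Å
    t_twist: float = 45.0  # degrees
    t_alt: float = 0.5


def compute_metrics(
    candidate: DesignCandidate,
    wt_profile: PoreProfile,
    band: float = 6.0,
) -> ClassificationMetrics:
    """Compute the four topology metrics for a re-profiled candidate.

    ``band`` is the axial window (Å, centred on the candidate constriction)
    over which the twist of the slice centres is evaluated.
    """
    if candidate.profile is None or candidate.constriction is None:
        raise UnclassifiableDesignError("candidate must be re-profiled before classification")
    profile = candidate.profile
    if not profile.open_slices():
        raise UnclassifiableDesignError("occluded pore: no open slice to classify")
    axis = profile.axis
    if axis is None:
        raise ValueError("candidate profile must carry its axis")

    # centre offset vs the WT constriction centre, in-plane
    from .pore_profile import find_constriction

    wt_con = find_constriction(wt_profile)
    c_cand = candidate.constriction.slice.center
    c_wt = wt_con.slice.center
    center_offset = float(np.hypot(c_cand[0] - c_wt[0], c_cand[1] - c_wt[1]))

    # axial spread of bulky (long side-chain) groups
    long_z: list[float] = []
    pos_z: list[tuple[float, bool]] = []  # (z, is_long) per design position
    if candidate.structure is not None and candidate.mutations:
        for key, aa in candidate.mutations.items():
            res = candidate.structure.residue(*key)
            side = res.side_chain_atoms()
            ref = side if side else [a for a in res.atoms if a.name == "CA"]
            centroid = np.mean([a.position for a in ref], axis=0)
            z = float(axis.to_axis_frame(centroid)[0][2])
            is_long = aa in LONG_AAS
            pos_z.append((z, is_long))
            if is_long:
                long_z.append(z)
    bulky_z_spread = float(np.std(long_z)) if long_z else 0.0

    # azimuthal twist of slice centres across the constriction band
    zc = candidate.constriction.slice.z
    zs, angles = [], []
    for s in profile.open_slices():
        if abs(s.z - zc) > band / 2:
            continue
        off = float(np.hypot(*s.center))
        if off < _MIN_OFFSET_FOR_AZIMUTH:
            continue
        zs.append(s.z)
        angles.append(math.atan2(s.center[1], s.center[0]))
    if len(zs) >= 3:
        unwrapped = np.unwrap(np.array(angles))
        zs_arr = np.array(zs)
        slope = np.polyfit(zs_arr, unwrapped, 1)[0]
        twist_span = abs(math.degrees(slope * (zs_arr.max() - zs_arr.min())))
    else:
        twist_span = 0.0

    # long/short alternation along the axis
    if len(pos_z) >= 2:
        ordered = [is_long for _, is_long in sorted(pos_z, key=lambda t: t[0])]
        pairs = list(zip(ordered, ordered[1:]))
        alternation = sum(1 for a, b in pairs if a != b) / len(pairs)
    else:
        alternation = 0.0

    return ClassificationMetrics(
        center_offset=center_offset,
        bulky_z_spread=bulky_z_spread,
        twist_span=twist_span,
        alternation_score=alternation,
    )


def classify_design(
    metrics: ClassificationMetrics,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> str:
    """Assign exactly one of ``"OCD"``, ``"UCD"``, ``"CSD"``.

    Priority: a displaced centre is the most salient signature, so OCD is
    tested first; then the cork-screw (twist + alternation); UCD is the
    default concentric closure.
    """
    if metrics.center_offset > thresholds.t_off:
        return "OCD"
    if metrics.twist_span > thresholds.t_twist and metrics.alternation_score > thresholds.t_alt:
        return "CSD"
    return "UCD"
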