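"""Pore-wall hydrophobicity scoring and osmotic permeability analysis.

Hydrophobicity: the inner and outer pore-wall scores are sums of
side-chain water->ethanol transfer free energies (kcal/mol; more negative
= more hydrophobic) over the residues classified as inner- or outer-wall.
A Kyte-Doolittle table ships as an alternative scale.

Permeability: stopped-flow light-scattering shrinkage curves are fitted to
a double exponential I(t) = A1 exp(-k1 t) + A2 exp(-k2 t) + C; the larger
rate constant k converts to the vesicle osmotic water permeability

    P_f = k / ((S/V_o) * delta_pi * V_w)

with S/V_o the vesicle surface-to-volume ratio (3/r for spheres), delta_pi
the osmotic gradient (osmol/cm^3) and V_w = 18 cm^3/mol the molar volume
of water.  Dividing the whole-vesicle water flow P_f*S by the average
number of channels per vesicle (N_pro/N_ves, an input from FCS) gives the
single-channel permeability p_f (cm^3/s), convertible to water molecules
per second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .structure_io import Structure

__all__ = [
    "HydrophobicityScale",
    "HydrophobicityReport",
    "StoppedFlowTrace",
    "DoubleExpFit",
    "PermeabilityResult",
    "FitFailureError",
    "UnclassifiableSignalError",
    "load_scale",
    "hydrophobicity_report",
    "fit_double_exponential",
    "osmotic_permeability",
    "single_channel_permeability",
    "water_flux_molecules_per_s",
    "permeability_ratio",
    "classify_solute_response",
    "V_W",
    "AVOGADRO",
]

V_W = 18.0  # cm^3/mol, molar volume of water
AVOGADRO = 6.02214e23

_HYDROPHOBIC = ("TRP", "PHE", "TYR", "MET", "LEU", "ILE", "VAL", "ALA")
_CHARGED = ("ASP", "GLU", "LYS", "ARG")
_ALL_AAS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


class FitFailureError(RuntimeError):
    """Double-exponential fit did not converge from any start."""


class UnclassifiableSignalError(RuntimeError):
    """Stopped-flow trace has no identifiable two-stage shape."""


# ---------------------------------------------------------------------------
# Hydrophobicity


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue hydrophobicity values with an explicit sign convention."""

    values: Mapping[str, float]
    name: str = "water_ethanol_transfer"
    convention: str = "negative_hydrophobic"
    units: str = "kcal/mol"

    def __post_init__(self) -> None:
        missing = [aa for aa in _ALL_AAS if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name} missing residues: {missing}")
        hydro = [self.values[a] for a in _HYDROPHOBIC]
        charged = [self.values[a] for a in _CHARGED]
        if self.convention == "negative_hydrophobic":
            if max(hydro) >= min(charged):
                raise ValueError(
                    "negative_hydrophobic scale must rank hydrophobic residues "
                    "below charged ones"
                )
        elif self.convention == "positive_hydrophobic":
            if min(hydro) <= max(charged):
                raise ValueError(
                    "positive_hydrophobic scale must rank hydrophobic residues "
                    "above charged ones"
                )
        else:
            raise ValueError(f"unknown convention {self.convention!r}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa.upper()]


def load_scale(name: str = "water_ethanol_transfer") -> HydrophobicityScale:
    """Load a shipped scale (``water_ethanol_transfer`` or ``kyte_doolittle``)."""
    raw = json.loads(
        resources.files("poredesign.data").joinpath("hydrophobicity_scales.json").read_text()
    )
    if name not in raw:
        raise KeyError(f"unknown scale {name!r}; shipped: {sorted(raw)}")
    entry = raw[name]
    return HydrophobicityScale(
        values=entry["values"], name=name, convention=entry["convention"], units=entry["units"]
    )


@dataclass(frozen=True)
class HydrophobicityReport:
    """Inner-wall, outer-wall and overall summed scores."""

    inner: float
    outer: float

    @property
    def overall(self) -> float:
        return self.inner + self.outer


def hydrophobicity_report(
    structure: Structure,
    wall_labels: Mapping[tuple[str, int], str],
    scale: HydrophobicityScale | None = None,
) -> HydrophobicityReport:
    """Sum the transfer free energy of inner- and outer-wall residues.

    ``wall_labels`` maps residue keys to ``"inner"``/``"outer"`` (residues
    absent from the mapping are skipped).  A residue type missing from the
    scale raises ``KeyError`` naming it.
    """
    scale = scale or load_scale()
    inner = outer = 0.0
    for res in structure.protein_residues():
        side = wall_labels.get(res.key)
        if side is None:
            continue
        try:
            v = scale[res.aa_type]
        except KeyError:
            raise KeyError(
                f"scale {scale.name} has no entry for residue type {res.aa_type!r} "
                f"({res.chain_id}{res.seq_number})"
            ) from None
        if side == "inner":
            inner += v
        else:
            outer += v
    return HydrophobicityReport(inner=inner, outer=outer)


# ---------------------------------------------------------------------------
# Stopped-flow traces


@dataclass
class StoppedFlowTrace:
    """Normalised light-scattering record: time (s) vs intensity."""

    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if len(self.time) < 20:
            raise ValueError("need at least 20 samples")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in trace")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "StoppedFlowTrace":
        """Read a 2-column (time_s, intensity) TSV/CSV file."""
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (time, intensity)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class DoubleExpFit:
    """Result of the two-exponential decay fit (k_fast >= k_slow)."""

    k_fast: float
    k_slow: float
    amplitude_fast: float
    amplitude_slow: float
    baseline: float
    converged: bool
    residual_rms: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amplitude_fast * np.exp(-self.k_fast * t)
            + self.amplitude_slow * np.exp(-self.k_slow * t)
            + self.baseline
        )


def _double_exp(t, a1, k1, a2, k2, c):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) + c


def fit_double_exponential(
    trace: StoppedFlowTrace, normalize: bool = True
) -> DoubleExpFit:
    """Least-squares fit of I(t) = A1 e^(-k1 t) + A2 e^(-k2 t) + C.

    The record is rescaled to [0, 1] before fitting (rates are invariant
    under affine intensity scaling).  Initialisation is multi-start: rate
    pairs from a log-spaced grid spanning the record's time scales; the
    lowest-residual converged fit wins.  Degenerate (constant) traces and
    non-convergence from every start raise :class:`FitFailureError`.
    """
    t = trace.time - trace.time[0]
    y = trace.intensity.astype(float)
    span = float(np.ptp(y))
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise FitFailureError("constant trace: no decay to fit")
    if normalize:
        y = (y - y.min()) / span

    t_end = float(t[-1])
    dt = float(np.median(np.diff(t)))
    k_grid = np.geomspace(0.5 / t_end, 0.5 / dt, 4)
    a0 = float(y[0] - y[-1])
    c0 = float(y[-1])

    best: tuple[float, np.ndarray] | None = None
    diagnostics = []
    for i, k1 in enumerate(k_grid):
        for k2 in k_grid[: i + 1]:
            p0 = [0.7 * a0, k1, 0.3 * a0, k2, c0]
            try:
                popt, _ = optimize.curve_fit(
                    _double_exp,
                    t,
                    y,
                    p0=p0,
                    bounds=([-np.inf, 1e-9, -np.inf, 1e-9, -np.inf], np.inf),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(str(exc))
                continue
            ssr = float(np.sum((y - _double_exp(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
    if best is None:
        raise FitFailureError(
            f"double-exponential fit failed from all {len(k_grid) * (len(k_grid) + 1) // 2} "
            f"starts; last diagnostics: {diagnostics[-3:]}"
        )
    ssr, popt = best
    a1, k1, a2, k2, c = popt
    if k1 < k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
    return DoubleExpFit(
        k_fast=float(k1),
        k_slow=float(k2),
        amplitude_fast=float(a1),
        amplitude_slow=float(a2),
        baseline=float(c),
        converged=True,
        residual_rms=math.sqrt(ssr / len(t)),
    )


# ---------------------------------------------------------------------------
# Permeability


@dataclass(frozen=True)
class PermeabilityResult:
    """Osmotic permeability bundle with every symbol of the rate equation."""

    k: float  # 1/s, larger double-exponential rate constant
    S: float  # cm^2, initial vesicle surface area
    V_o: float  # cm^3, initial vesicle volume
    delta_pi: float  # osmol/cm^3, osmotic gradient
    V_w: float  # cm^3/mol
    P_f: float  # cm/s
    n_pro_per_ves: float | None = None
    single_channel_pf: float | None = None  # cm^3/s


def osmotic_permeability(
    k: float,
    *,
    radius_cm: float | None = None,
    S: float | None = None,
    V_o: float | None = None,
    delta_pi: float,
    V_w: float = V_W,
) -> float:
    """Vesicle osmotic water permeability P_f = k / ((S/V_o) delta_pi V_w).

    Geometry may be given either as a spherical vesicle ``radius_cm``
    (S/V_o = 3/r) or as explicit ``S`` and ``V_o``.  ``delta_pi`` is in
    osmol/cm^3 (divide osmol/L by 1000).
    """
    if k < 0:
        raise ValueError("rate constant k must be >= 0")
    if delta_pi <= 0 or V_w <= 0:
        raise ValueError("delta_pi and V_w must be positive")
    if radius_cm is not None:
        if radius_cm <= 0:
            raise ValueError("radius must be positive")
        s_over_v = 3.0 / radius_cm
    elif S is not None and V_o is not None:
        if S <= 0 or V_o <= 0:
            raise ValueError("S and V_o must be positive")
        s_over_v = S / V_o
    else:
        raise ValueError("provide either radius_cm or both S and V_o")
    return k / (s_over_v * delta_pi * V_w)


def single_channel_permeability(P_f: float, S: float, n_pro_per_ves: float) -> float:
    """Per-channel volumetric permeability p_f = P_f * S / (N_pro/N_ves), cm^3/s."""
    if n_pro_per_ves <= 0:
        raise ValueError("channels per vesicle must be positive")
    if P_f < 0 or S <= 0:
        raise ValueError("P_f must be >= 0 and S positive")
    return P_f * S / n_pro_per_ves


def water_flux_molecules_per_s(pf: float) -> float:
    """Convert a single-channel permeability (cm^3/s) to water molecules/s."""
    if pf < 0:
        raise ValueError("pf must be >= 0")
    return pf / V_W * AVOGADRO


def permeability_ratio(pf_a: float, pf_b: float) -> float:
    """Fold difference pf_a / pf_b between two single-channel permeabilities."""
    if pf_b == 0:
        raise ValueError("reference permeability must be nonzero")
    return pf_a / pf_b


# ---------------------------------------------------------------------------
# Solute rejection classification


def classify_solute_response(
    trace: StoppedFlowTrace,
    alpha: float = 0.01,
    min_relative_drop: float = 0.02,
) -> str:
    """Label a two-stage osmotic-shock trace ``"excluded"`` or ``"permeable"``.

    Stage one (vesicle shrinkage) raises the scattering intensity to a
    peak; stage two levels off if the solute is excluded or decays if the
    solute (and water) re-enters.  After locating the smoothed intensity
    maximum, the final third of the record is tested for a negative linear
    trend (one-sided t-test at ``alpha``); the fitted drop must also exceed
    ``min_relative_drop`` of the signal range to count as permeation.
    Traces without an identifiable rise-to-peak raise
    :class:`UnclassifiableSignalError`.
    """
    y = trace.intensity.astype(float)
    n = len(y)
    span0 = float(np.ptp(y))
    if span0 <= 0:
        raise UnclassifiableSignalError("flat trace")
    # "the" peak of a shrinking-vesicle trace: first approach to the maximum
    # (an asymptotic plateau counts as peaked once it reaches 98% of range)
    thresh = y.min() + 0.98 * span0
    i_peak = int(np.argmax(y >= thresh))
    if i_peak <= max(2, int(0.02 * n)):
        raise UnclassifiableSignalError("no rise stage: intensity maximum at record start")

    i0 = max(i_peak + 1, int(2 * n / 3))
    if n - i0 < 10:
        raise UnclassifiableSignalError("peak too close to record end: no second stage to test")
    t_tail = trace.time[i0:]
    y_tail = y[i0:]
    res = stats.linregress(t_tail, y_tail)
    drop = -res.slope * (t_tail[-1] - t_tail[0])
    span = float(np.ptp(y))
    if span <= 0:
        raise UnclassifiableSignalError("flat trace")
    one_sided_p = res.pvalue / 2 if res.slope < 0 else 1.0
    if res.slope < 0 and one_sided_p < alpha and drop > min_relative_drop * span:
        return "permeable"
    return "excluded"
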