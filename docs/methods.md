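# Methods

`poredesign` redesigns the constriction of a β-barrel channel protein so
that its pore matches a target sub-nanometer size while leaving a
single-file water wire energetically undisturbed. This note documents the
models, the numerical choices, and what the synthetic test battery does
and does not demonstrate.

## Pore profiling

The pore axis is the principal eigenvector of the CA-atom covariance,
through the CA centroid, signed so +z runs from the first toward the last
residue. This is robust for barrels and needs no external channel-finding
tool; it fails loudly (a `DegenerateAxisError`) when the CA cloud is
coplanar and no unique axis exists. Structures whose longest dimension is
not the pore axis (e.g. very flat slabs) would need an explicit axis.

The profile slices the structure every `step` = 0.5 Å along the axis. In
each slice plane an occupancy grid (spacing `probe_spacing` = 0.25 Å)
marks a point blocked iff it lies inside the vdW sphere of any atom whose
sphere intersects the slice band — an atom at axial offset dz from the
plane blocks a disc of radius sqrt(r² − dz²), the widest it presents
anywhere in the band. The open region 4-connected to the axis
intersection is flood-filled; its second moments (including the s²/12
per-cell term) give an ellipse that is rescaled so its area equals the
region area exactly. This moment-based ellipse is stable on non-convex
regions, where a direct inscribed-ellipse fit is not. "Pore size" or
"diameter" always means the *minor axis* of the constriction ellipse, the
narrowest open slice (ties: smaller area, then smaller z). Occluded
slices carry zero area rather than aborting, so partially blocked designs
remain analyzable; a fully occluded profile raises `OccludedPoreError`.

Against analytic cavities (cylinder, elliptic cylinder, hourglass of
revolution) the recovered axes agree with the closed forms to within
2 × `probe_spacing` = 0.5 Å, which is therefore the geometric resolution
quoted for all profile numbers.

Van der Waals radii are the Bondi set (C 1.70, N 1.55, O 1.52, S 1.80 Å);
hydrogens carry 1.10 Å but are excluded from clash and profile geometry
(the radii are heavy-atom calibrated). Water hydrogens matter only for
the hydrogen-bond counter.

Wall classification: a residue is *inner* iff its side-chain heavy-atom
centroid is radially closer to the axis than its CA (ties inner); glycine
uses the direction a CB would take (opposite the N/C bisector). Pore
lining is defined near the constriction: a residue qualifies if a
side-chain heavy atom sits within ±6 Å (`band`) of the constriction z and
within 1.4 Å (`shell`, one water radius) of the open-region boundary,
where the boundary distance uses the slice's equivalent-area circle —
exact for circular lumens, approximate otherwise.

The water–protein hydrogen-bond counter is geometric: a bond is counted
when the water oxygen is within 3.0 Å of a polar protein atom (N, O, S)
and the O–H···acceptor deviation angle is ≤ 20°, i.e. the angle between
the O→H bond vector and the H→acceptor vector (0° for a perfectly linear
bond). Counts are restricted to an axial region and averaged over frames.

## Water wires

A wire is an ordered list of water-oxygen coordinates. Loading checks the
single-file spacing window [2.4, 3.5] Å and warns (but proceeds) outside
it. Placement is strictly rigid: the wire's principal axis is rotated
onto the pore axis, its centroid translated to the constriction centre,
and of the two axial orientations the one with smaller summed vdW overlap
against the protein is kept. Pairwise oxygen distances are preserved to
machine precision (tested at 1e-6 Å). Oxygens are reordered by ascending
axial coordinate after placement.

## Side-chain rebuilding

Rotamers are built from ideal internal coordinates: CB is placed from
N/CA/C with the L-configuration improper (C–N–CA–CB = +122.6°, N–CA–CB =
110.4°, 1.53 Å), and the remaining atoms follow per-residue templates
(bond, angle, torsion) via the standard NeRF construction. Ring
geometries of Phe/Tyr/Trp are idealized planar templates; ring closure is
accurate to ~0.02 Å, ample for sterics. The default rotamer library is a
coarse backbone-independent grid (chi ∈ {−60, 60, 180}°; ring chi2 ∈
{−90, 90}°); `dense_rotamer_library()` refines aromatic chi1 to 30° steps
and ring chi2 to 30° steps, which tightly packed walls need to admit
bulky residues at all. Richer libraries can be supplied as data.

## Design model

The design alphabet is hydrophobic by construction: {W, F, Y, M, L, I, V,
A}, with {W, F, Y, M} designated *long*. At least 50% of design positions
must carry long side chains (`min_long_fraction`), the safeguard against
trivial all-alanine packings. Hard constraints per candidate rotamer:

* wire exclusion — every heavy atom farther from every wire oxygen than
  the sum of their vdW radii (the wire cannot be sterically displaced, so
  the pore cannot occlude);
* no clash with the fixed environment and, pairwise, with other selected
  rotamers. Clash means distance < 0.85 × (r_i + r_j) between heavy
  atoms, the standard soft-overlap factor; bonded neighbours (±1 in
  sequence) are exempt from the environment check.

The objective scores each rotamer against the wire with a 12-6
Lennard-Jones sum (per-element ε/r_min: C 0.11/4.00, N 0.20/3.66, O
0.12/3.50, S 0.45/4.00 kcal/mol/Å; geometric-mean ε, arithmetic-mean
r_min; 10 Å cutoff). Only the relative ordering of these scores matters.
"Maximise the interaction energy" therefore selects the *least-binding*
feasible packing: all pair terms are ≤ 0 near contact, and the optimum
keeps the wall as indifferent to the wire as the constraints allow —
the design hypothesis being that removing water–wall attraction raises
permeability.

Selection is an exact MILP (HiGHS via `scipy.optimize.milp`): one binary
per (position, rotamer), exactly-one per position, x_a + x_b ≤ 1 per
clashing pair, a long-count row, optional per-amino-acid minimum-count
rows, and no-good cuts banning previously found amino-acid assignments.
On every random instance up to 6 positions × 5 candidates the MILP
objective equals exhaustive enumeration exactly (tested on 100 seeded
instances). Ties between equal-objective optima are resolved by the
solver's deterministic branching rather than an explicit lexicographic
second stage; rerunning with the same seed reproduces the output
bit-for-bit, which is the property the pipeline relies on.

The iterative driver replaces backbone-perturbation machinery with a
deterministic restart scheme: each restart solves the MILP under no-good
cuts and (after the first restart) seeded candidate subsampling
(`subsample` = 0.75 of candidates per position), rebuilds the full-atom
mutant, re-profiles it, and applies the design assessment: retained iff
the constriction falls inside [d_min, d_max] *or* the design binds the
wire less than the wild-type side chains do. A bulk ratchet adapts
proposals toward the window — while solutions re-profile too wide, the
minimum count of the bulkiest allowed residue rises (≈1 per 0.6 Å of
excess, the closure rate observed on barrel scaffolds); infeasible levels
bisect back toward the last feasible one; undershooting d_min steps down.
This reproduces the qualitative law that smaller target pores require
more (and bulkier) mutations, which the test suite asserts as a
monotonicity property.

## Closure-topology classification

The three closure families are detected from geometry alone:

| metric | definition | OCD | UCD | CSD |
|---|---|---|---|---|
| `center_offset` | constriction-centre displacement vs WT (Å) | > 1.5 | small | small |
| `twist_span` | azimuthal drift of slice centres across a 6 Å band (°), from a linear fit of unwrapped azimuths (slices with offset < 0.2 Å are skipped as angularly meaningless) | — | small | > 45 |
| `alternation_score` | fraction of axially adjacent design-position pairs alternating long/short | — | — | > 0.5 |
| `bulky_z_spread` | std of long-residue side-chain centroid z (Å) | — | < 1 (descriptive) | large |

Decision order: OCD first (the most salient signature), then CSD (twist
*and* alternation), else UCD. The thresholds (1.5 Å, 45°, 0.5) are this
package's own operationalization of verbally described families; they are
exposed in `ClassifierThresholds` and validated against constructed
archetypes, not against any external labelled set.

## Hydrophobicity scores

Pore-wall hydrophobicity is the sum of side-chain water→ethanol transfer
free energies over inner-wall and outer-wall residues separately
(overall = inner + outer, an exact bookkeeping invariant). The shipped
table is the classic Nozaki–Tanford-lineage set (Trp −3.40 … Ala −0.73
kcal/mol), with charged side chains assigned positive values so
hydrophobics always rank below charged residues; it is a data file and
deliberately editable, since published wall scores depend on the exact
per-residue table and wall-residue set used. A Kyte–Doolittle table
ships as the alternative scale (opposite sign convention, declared in the
file).

## Permeability

Stopped-flow light-scattering records are normalised to [0, 1] and fitted
to I(t) = A₁e^(−k₁t) + A₂e^(−k₂t) + C by bounded least squares with
multi-start initialisation (rate pairs from a 4-point log-spaced grid
between 0.5/T and 0.5/dt); the lowest-residual start wins and the larger
rate is k. Over 100 seeded traces at 2% noise and k_fast/k_slow = 10 the
median k_fast error is ~3%. Constant traces and universal non-convergence
raise `FitFailureError` with diagnostics.

The vesicle osmotic permeability is P_f = k / ((S/V_o) · Δπ · V_w) with
V_w = 18 cm³/mol and S/V_o = 3/r for spheres; Δπ is accepted in osmol/L
at the CLI and converted to osmol/cm³. Single-channel permeability is
p_f = P_f · S / (N_pro/N_ves), where the channels-per-vesicle count is an
external (FCS-derived) input; molecular flux is p_f/V_w × N_A.

Solute-rejection traces are classified by their second stage: after the
first approach to 98% of the signal range (the shrinkage peak), the final
third of the record is tested for a negative linear trend (one-sided
t-test, α = 0.01) with a practical-significance floor of 2% of the signal
range — "permeable" if the tail decays, "excluded" if it levels off.
Records whose maximum sits at the start (no rise stage) are
unclassifiable.

## Synthetic fixtures: what they do and do not show

The generators produce: idealized antiparallel barrels (CA cylinders with
template-oriented backbones, inward/outward pseudo-CB side chains,
optional inward bulge creating a constriction, and non-protein seam atoms
sealing the inter-strand gaps a real sheet's hydrogen bonding would
close); analytic cavities with closed-form cross-sections; exact-spacing
straight/helical wires; archetype structures for the three closure
families; and seeded double-exponential traces.

Default study conditions: barrels with 14 strands at 12 Å CA radius
(≈4.5 Å inter-strand spacing, as in real porins), 30 Å height, 2 Å
constriction bulge over a 6 Å band, giving a 15.8 Å toy constriction;
design runs repack the 14-residue constriction ring with 6–10 restarts;
traces use k = (20, 2)/s, amplitudes (0.6, 0.3), baseline 0.1, 500 points
over 1 s, 1–2% Gaussian noise. On this scaffold full-atom repacking
closes the pore to ≈6.7 Å (wire exclusion forbids anything tighter than
the wire's 3.2 Å vdW corridor plus contact radii); the sub-4 Å regime of
a real 7 × 11 Å porin constriction, where 25 design positions line a much
tighter lumen, is correspondingly represented by scaled-up windows
(e.g. (0, 7) Å) in tests.

Passing these tests demonstrates: geometric correctness of the profiler
at known cavities; exactness of the MILP against enumeration; soundness
of every returned design under the hard constraints; rigidity of wire
placement; seeded reproducibility; correct classification of
constructed topologies; and correct rate/permeability arithmetic.

It does not demonstrate: accuracy on crystallographic side-chain
conformations (ideal-geometry rotamers only), transferability of the
closure rate (0.6 Å/residue) to other scaffolds, realism of the LJ score
as an energy function, or agreement with measured permeabilities of real
designed proteins — those require real structures and wet-lab data. The
two reference-structure acceptance tests (OmpF 7 × 11 Å; AQP1 ~2.7 Å) run
the real pipeline but need the crystallographic files placed under
`data/external/`, which are not distributed with the package.

## Degenerate inputs and tie-breaks

Coplanar CA sets: error. Occluded profiles: zero-area slices, signalled
at constriction lookup. Equal-minor slices: smaller area, then smaller z.
Wall-classification radius ties: inner. Wire of one oxygen: placement
degenerates to a translation. Empty wire: vacuously exclusion-safe,
zero energy. All-alanine proposals: excluded by the long-fraction row
(infeasible when the alphabet cannot satisfy it). Subsampling never
removes a position's last candidate.
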