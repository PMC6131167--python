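"""Water-wire placement, rotamer building, clash/exclusion checks and the
rotamer-selection MILP (checked against exhaustive enumeration)."""

import itertools
import math

import numpy as np
import pytest

import poredesign as pdsg
from poredesign.design_engine import (
    DesignCandidate,
    DesignSpec,
    InfeasibleDesignError,
    LJ_PARAMS,
    WaterWire,
    WireGeometryWarning,
    accept_design,
    build_rotamer,
    detect_clash,
    interaction_energy,
    load_water_wire,
    long_chain_fraction,
    measure_dihedral,
    place_water_wire,
    select_rotamers_milp,
    wire_exclusion_ok,
)
from poredesign.pore_profile import ConstrictionGeometry, PoreSlice
from poredesign.structure_io import Atom, Residue
from poredesign.synthetic_fixtures import make_water_wire


def _backbone(chain="A", seq=1):
    return Residue(
        chain,
        seq,
        "GLY",
        [
            Atom("N", "N", [1.458, 0.0, 0.0]),
            Atom("CA", "C", [0.0, 0.0, 0.0]),
            Atom("C", "C", [-0.551, 1.420, 0.0]),
            Atom("O", "O", [-1.5, 1.6, 0.2]),
        ],
    )


class TestWireLoading:
    def test_nine_waters_at_2p8_end_to_end(self):
        wire = make_water_wire(9, 2.8)
        assert wire.end_to_end() == pytest.approx(22.4, abs=1e-9)

    def test_xyz_and_pdb_inputs(self, tmp_path):
        xyz = tmp_path / "wire.xyz"
        xyz.write_text("3\nwire\n" + "\n".join(f"O 0 0 {2.8 * i:.1f}" for i in range(3)))
        wire = load_water_wire(xyz)
        assert len(wire) == 3 and wire.spacing_ok

        pdb = tmp_path / "wire.pdb"
        lines = [
            f"HETATM{i + 1:5d}  O   HOH W{i + 1:4d}    {0.0:8.3f}{0.0:8.3f}{2.8 * i:8.3f}"
            f"  1.00  0.00           O"
            for i in range(3)
        ]
        pdb.write_text("\n".join(lines) + "\nEND\n")
        wire2 = load_water_wire(pdb)
        np.testing.assert_allclose(wire2.oxygens, wire.oxygens, atol=1e-3)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "none.xyz"
        p.write_text("0\nempty\n")
        with pytest.raises(ValueError):
            load_water_wire(p)

    def test_bad_spacing_warns_but_loads(self, tmp_path):
        p = tmp_path / "wide.xyz"
        p.write_text("2\nwide\nO 0 0 0\nO 0 0 5.0")
        with pytest.warns(WireGeometryWarning):
            wire = load_water_wire(p)
        assert not wire.spacing_ok


class TestWirePlacement:
    def test_identity_when_already_placed(self, barrel, barrel_axis, barrel_constriction):
        wire = make_water_wire(9, 2.8)
        placed = place_water_wire(wire, barrel, barrel_axis, barrel_constriction)
        again = place_water_wire(placed, barrel, barrel_axis, barrel_constriction)
        np.testing.assert_allclose(again.oxygens, placed.oxygens, atol=1e-9)

    def test_rigidity_of_pairwise_distances(self, barrel, barrel_axis, barrel_constriction):
        wire = make_water_wire(9, 2.8, helicity=15.0)
        placed = place_water_wire(wire, barrel, barrel_axis, barrel_constriction)
        drift = np.abs(placed.pairwise_distances() - wire.pairwise_distances()).max()
        assert drift < 1e-6

    def test_off_axis_wire_aligns_to_pore_axis(self, barrel, barrel_axis, barrel_constriction):
        wire = make_water_wire(9, 2.8)
        tipped = WaterWire(wire.oxygens @ np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]]).T)
        placed = place_water_wire(tipped, barrel, barrel_axis, barrel_constriction)
        angle = math.degrees(
            math.acos(abs(float(np.dot(placed.principal_axis(), barrel_axis.direction))))
        )
        assert angle < 1.0

    def test_shuffled_input_same_wire_after_placement(
        self, barrel, barrel_axis, barrel_constriction
    ):
        wire = make_water_wire(7, 2.8)
        rng = np.random.default_rng(0)
        shuffled = WaterWire(wire.oxygens[rng.permutation(7)])
        a = place_water_wire(wire, barrel, barrel_axis, barrel_constriction)
        b = place_water_wire(shuffled, barrel, barrel_axis, barrel_constriction)
        np.testing.assert_allclose(a.oxygens, b.oxygens, atol=1e-9)


class TestRotamerBuilding:
    def test_alanine_has_cb_only(self):
        rot = build_rotamer(_backbone(), "ALA", ())
        side = [a.name for a in rot.atoms if not a.is_backbone]
        assert side == ["CB"]

    def test_leucine_chis_reproduced(self):
        rot = build_rotamer(_backbone(), "LEU", (-60.0, 180.0))
        pos = {a.name: a.position for a in rot.atoms}
        chi1 = measure_dihedral(pos["N"], pos["CA"], pos["CB"], pos["CG"])
        chi2 = measure_dihedral(pos["CA"], pos["CB"], pos["CG"], pos["CD1"])
        assert chi1 == pytest.approx(-60.0, abs=0.5)
        assert chi2 == pytest.approx(180.0, abs=0.5)

    def test_tryptophan_build_is_deterministic(self):
        a = build_rotamer(_backbone(), "TRP", (60.0, -90.0))
        b = build_rotamer(_backbone(), "TRP", (60.0, -90.0))
        np.testing.assert_array_equal(
            np.array([x.position for x in a.atoms]), np.array([x.position for x in b.atoms])
        )

    def test_chi_count_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="chi"):
            build_rotamer(_backbone(), "VAL", (60.0, 180.0))

    def test_l_configuration(self):
        # the C-N-CA-CB improper of an L-amino acid is near +122.6°
        rot = build_rotamer(_backbone(), "VAL", (180.0,))
        pos = {a.name: a.position for a in rot.atoms}
        improper = measure_dihedral(pos["C"], pos["N"], pos["CA"], pos["CB"])
        assert improper == pytest.approx(122.6, abs=1.0)


class TestClashDetection:
    @staticmethod
    def _atom_group(positions):
        atoms = []
        for i, p in enumerate(positions):
            a = Atom(f"C{i}", "C", p)
            a.vdw_radius = 1.7
            atoms.append(a)
        return atoms

    def test_threshold_arithmetic(self):
        a = self._atom_group([[0.0, 0.0, 0.0]])
        b = self._atom_group([[2.0, 0.0, 0.0]])
        assert detect_clash(a, b, overlap=0.85)  # threshold 2.89 Å
        b2 = self._atom_group([[3.0, 0.0, 0.0]])
        assert not detect_clash(a, b2, overlap=0.85)

    def test_matches_brute_force_on_random_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            pa = rng.uniform(-4, 4, size=(10, 3))
            pb = rng.uniform(-4, 4, size=(10, 3))
            ga, gb = self._atom_group(pa), self._atom_group(pb)
            brute = any(
                np.linalg.norm(x - y) < 0.85 * 3.4 for x in pa for y in pb
            )
            assert detect_clash(ga, gb, overlap=0.85) == brute


class TestWireExclusionAndEnergy:
    def test_exclusion_uses_vdw_radius_sum(self):
        wire = WaterWire(np.array([[0.0, 0.0, 0.0]]))
        near = Residue("A", 1, "ALA", [Atom("CB", "C", [2.5, 0, 0])])
        near.atoms[0].vdw_radius = 1.7
        assert not wire_exclusion_ok(near, wire)  # 2.5 < 1.70 + 1.52
        far = Residue("A", 1, "ALA", [Atom("CB", "C", [4.0, 0, 0])])
        far.atoms[0].vdw_radius = 1.7
        assert wire_exclusion_ok(far, wire)

    def test_empty_wire_is_vacuously_ok(self):
        res = Residue("A", 1, "ALA", [Atom("CB", "C", [0, 0, 0])])
        assert wire_exclusion_ok(res, WaterWire(np.zeros((0, 3))))

    def test_energy_vanishes_beyond_cutoff(self):
        wire = WaterWire(np.array([[0.0, 0.0, 0.0]]))
        res = Residue("A", 1, "ALA", [Atom("CB", "C", [20.0, 0, 0])])
        assert abs(interaction_energy(res, wire)) < 1e-3

    def test_lj_minimum_value(self):
        eps_c, rmin_c = LJ_PARAMS["C"]
        eps_o, rmin_o = LJ_PARAMS["O"]
        eps = math.sqrt(eps_c * eps_o)
        rmin = 0.5 * (rmin_c + rmin_o)
        wire = WaterWire(np.array([[0.0, 0.0, 0.0]]))
        res = Residue("A", 1, "ALA", [Atom("CB", "C", [rmin, 0, 0])])
        assert interaction_energy(res, wire) == pytest.approx(-eps, rel=1e-9)

    def test_matches_hand_summed_pairs(self):
        rng = np.random.default_rng(1)
        wire = WaterWire(rng.uniform(-3, 3, size=(3, 3)))
        atoms = [Atom(f"C{i}", "C", rng.uniform(2, 6, size=3)) for i in range(5)]
        res = Residue("A", 1, "ALA", atoms)
        eps = math.sqrt(LJ_PARAMS["C"][0] * LJ_PARAMS["O"][0])
        rmin = 0.5 * (LJ_PARAMS["C"][1] + LJ_PARAMS["O"][1])
        expected = 0.0
        for a in atoms:
            for o in wire.oxygens:
                r = np.linalg.norm(a.position - o)
                if r <= 10.0:
                    expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert interaction_energy(res, wire) == pytest.approx(expected, rel=1e-9)


def _random_instance(rng, n_pos, n_cand):
    """Single-atom candidates with random geometry, labels and energies."""
    candidates = {}
    for p in range(n_pos):
        key = ("A", p + 1)
        lst = []
        for r in range(n_cand):
            pos = np.array([3.0 * p, 0.0, 0.0]) + rng.uniform(-1.2, 1.2, size=3)
            atom = Atom("CB", "C", pos)
            atom.vdw_radius = 1.7
            res = Residue("A", p + 1, "X", [atom])
            aa = rng.choice(["TRP", "PHE", "LEU", "ALA"])
            lst.append((aa, (float(r),), res, float(rng.uniform(-5, 0))))
        candidates[key] = lst
    return candidates


def _brute_force_optimum(candidates, spec):
    keys = list(spec.positions)
    best = None
    for combo in itertools.product(*(range(len(candidates[k])) for k in keys)):
        chosen = [candidates[k][r] for k, r in zip(keys, combo)]
        n_long = sum(1 for aa, _, _, _ in chosen if aa in spec.long_aas)
        if n_long < spec.min_long_fraction * len(keys) - 1e-9:
            continue
        if any(
            detect_clash(a[2], b[2], spec.clash_overlap)
            for i, a in enumerate(chosen)
            for b in chosen[i + 1 :]
        ):
            continue
        energy = sum(e for _, _, _, e in chosen)
        if best is None or energy > best:
            best = energy
    return best


class TestMilpSelection:
    def test_matches_exhaustive_search_on_seeded_instances(self, barrel, placed_wire):
        rng = np.random.default_rng(2024)
        n_compared = 0
        for _ in range(60):
            n_pos = int(rng.integers(2, 5))
            n_cand = int(rng.integers(2, 5))
            candidates = _random_instance(rng, n_pos, n_cand)
            spec = DesignSpec(
                positions=list(candidates), min_long_fraction=0.5, restarts=1, seed=0
            )
            brute = _brute_force_optimum(candidates, spec)
            if brute is None:
                with pytest.raises(InfeasibleDesignError):
                    select_rotamers_milp(barrel, spec, candidates, placed_wire)
                continue
            cand = select_rotamers_milp(barrel, spec, candidates, placed_wire)
            assert cand.wire_interaction_energy == pytest.approx(brute, abs=1e-6)
            n_compared += 1
        assert n_compared >= 20  # most random instances must be feasible

    def test_single_feasible_combination_is_forced(self, barrel, placed_wire):
        # two positions, two candidates each; all cross-pairs clash except one
        def res_at(p, x):
            a = Atom("CB", "C", [x, 0.0, 0.0])
            a.vdw_radius = 1.7
            return Residue("A", p, "X", [a])

        candidates = {
            ("A", 1): [("TRP", (0.0,), res_at(1, 0.0), -1.0), ("TRP", (1.0,), res_at(1, 1.0), -5.0)],
            ("A", 2): [("ALA", (0.0,), res_at(2, 2.0), -1.0), ("ALA", (1.0,), res_at(2, 4.0), -0.5)],
        }
        # pairs (0.0 vs 2.0): 2.0 Å apart -> clash; (1.0 vs 2.0): 1.0 -> clash;
        # (1.0 vs 4.0): 3.0 -> clash-free; (0.0 vs 4.0): 4.0 -> clash-free.
        # energies make (0.0, 4.0) = -1.5 optimal over (1.0, 4.0) = -5.5
        spec = DesignSpec(positions=list(candidates), min_long_fraction=0.5, restarts=1)
        cand = select_rotamers_milp(barrel, spec, candidates, placed_wire)
        assert cand.rotamers[("A", 1)] == (0.0,)
        assert cand.rotamers[("A", 2)] == (1.0,)

    def test_insufficient_long_candidates_infeasible(self, barrel, placed_wire):
        def res_at(p, x):
            a = Atom("CB", "C", [x, 0.0, 0.0])
            a.vdw_radius = 1.7
            return Residue("A", p, "X", [a])

        candidates = {
            ("A", p): [("ALA", (0.0,), res_at(p, 5.0 * p), -1.0)] for p in range(1, 5)
        }
        candidates[("A", 1)] = [("TRP", (0.0,), res_at(1, 5.0), -1.0)]
        spec = DesignSpec(positions=list(candidates), min_long_fraction=0.5, restarts=1)
        with pytest.raises(InfeasibleDesignError):
            select_rotamers_milp(barrel, spec, candidates, placed_wire)

    def test_empty_candidate_list_names_position(self, barrel, placed_wire):
        spec = DesignSpec(positions=[("A", 7)], restarts=1)
        with pytest.raises(InfeasibleDesignError, match="7"):
            select_rotamers_milp(barrel, spec, {("A", 7): []}, placed_wire)


class TestDesignGeneration:
    def test_seeded_run_is_reproducible(self, barrel, barrel_axis, placed_wire, dense_library):
        spec = dict(
            positions=[("A", 5 + 10 * i) for i in range(14)],
            allowed_aas=("TRP", "PHE", "ALA"),
            long_aas=("TRP", "PHE"),
            restarts=3,
            seed=11,
            d_max=8.0,
            subsample=0.6,
        )
        runs = []
        for _ in range(2):
            designs = pdsg.generate_designs(
                barrel, DesignSpec(**spec), library=dense_library, wire=placed_wire, axis=barrel_axis
            )
            runs.append([sorted(d.mutations.items()) for d in designs])
        assert runs[0] == runs[1]

    def test_accepted_designs_respect_the_window(self, design_run):
        spec, designs = design_run
        assert len(designs) >= 1
        for d in designs:
            if d.accepted:
                assert spec.d_min <= d.diameter <= spec.d_max

    def test_no_retained_design_violates_hard_constraints(self, design_run, placed_wire):
        """Post-hoc re-verification of clash and wire-exclusion soundness."""
        spec, designs = design_run
        for d in designs:
            rotamer_residues = [d.structure.residue(*k) for k in d.mutations]
            for res in rotamer_residues:
                assert wire_exclusion_ok(res, placed_wire)
            for i, a in enumerate(rotamer_residues):
                for b in rotamer_residues[i + 1 :]:
                    assert not detect_clash(a, b, spec.clash_overlap)

    def test_retained_designs_meet_long_fraction(self, design_run):
        spec, designs = design_run
        for d in designs:
            assert long_chain_fraction(d, spec) >= spec.min_long_fraction - 1e-9

    def test_output_sorted_by_diameter(self, design_run):
        _, designs = design_run
        diameters = [d.diameter for d in designs]
        assert diameters == sorted(diameters)

    def test_smaller_pores_need_more_mutations(
        self, barrel, barrel_axis, placed_wire, dense_library
    ):
        """Tighter target windows force bulkier (more mutated) designs."""

        def mean_mutations(d_min, d_max):
            spec = DesignSpec(
                positions=[("A", 5 + 10 * i) for i in range(14)],
                allowed_aas=("TRP", "PHE", "TYR", "ALA", "VAL", "LEU"),
                long_aas=("TRP", "PHE", "TYR"),
                restarts=8,
                seed=3,
                d_min=d_min,
                d_max=d_max,
                subsample=0.7,
            )
            designs = pdsg.generate_designs(
                barrel, spec, library=dense_library, wire=placed_wire, axis=barrel_axis
            )
            counts = [
                sum(1 for aa in d.mutations.values() if aa != "ALA")
                for d in designs
                if d.accepted
            ]
            return float(np.mean(counts)) if counts else None

        tight = mean_mutations(0.0, 7.0)
        loose = mean_mutations(9.0, 12.0)
        assert tight is not None and loose is not None
        assert tight >= loose


class TestAcceptanceRules:
    @staticmethod
    def _candidate(diameter):
        slice_ = PoreSlice(
            z=0.0,
            center=np.zeros(2),
            major_axis=diameter + 1,
            minor_axis=diameter,
            open_area=3.0,
        )
        con = ConstrictionGeometry(slice=slice_, diameter=diameter, center_offset=0.0)
        return DesignCandidate(
            mutations={("A", 1): "TRP"}, rotamers={("A", 1): ()}, constriction=con
        )

    @pytest.mark.parametrize(
        "diameter,window,expected",
        [
            (3.9, (0.0, 4.0), True),
            (4.1, (0.0, 4.0), False),
            (5.5, (5.0, 6.0), True),
            (4.9, (5.0, 6.0), False),
        ],
    )
    def test_window_rule(self, diameter, window, expected):
        spec = DesignSpec(positions=[("A", 1)], d_min=window[0], d_max=window[1], restarts=1)
        assert accept_design(self._candidate(diameter), spec) is expected

    def test_long_chain_fraction_arithmetic(self):
        spec = DesignSpec(positions=[("A", i) for i in range(1, 26)], restarts=1)
        muts = {("A", i): ("TRP" if i <= 13 else "ALA") for i in range(1, 26)}
        cand = DesignCandidate(mutations=muts, rotamers={k: () for k in muts})
        assert long_chain_fraction(cand, spec) == pytest.approx(13 / 25)
        muts12 = {("A", i): ("TRP" if i <= 12 else "ALA") for i in range(1, 26)}
        cand12 = DesignCandidate(mutations=muts12, rotamers={k: () for k in muts12})
        assert long_chain_fraction(cand12, spec) < 0.5

    def test_all_alanine_design_scores_zero(self):
        spec = DesignSpec(positions=[("A", i) for i in range(1, 5)], restarts=1)
        muts = {("A", i): "ALA" for i in range(1, 5)}
        cand = DesignCandidate(mutations=muts, rotamers={k: () for k in muts})
        assert long_chain_fraction(cand, spec) == 0.0
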