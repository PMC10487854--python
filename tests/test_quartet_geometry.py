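import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import g4kit.quartet_geometry as qg
from g4kit.structure_io import Selection, select
from g4kit.synthetic import BuilderSpec, build_quadruplex
from .conftest import random_rotation, transform_ensemble


@pytest.fixture(scope="module")
def quartets(default_structure):
    return qg.detect_quartets(default_structure, 0)


# ---------------------------------------------------------------------------
# glycosidic torsion
# ---------------------------------------------------------------------------

class TestChi:
    @pytest.mark.parametrize(
        "glyc, expected_chi, expected_conf",
        [("syn", 60.0, "syn"), ("anti", 240.0, "anti")],
    )
    def test_constructed_chi_recovered(self, glyc, expected_chi, expected_conf):
        ens = build_quadruplex(
            BuilderSpec(include_c_quartet=False, glycosidic=[glyc] * 4, ions=())
        )
        for chain in "ABCD":
            g = qg.compute_chi(ens, 0, (chain, 2))
            assert g.chi == pytest.approx(expected_chi, abs=1e-6)
            assert g.conformation == expected_conf

    def test_default_topology_is_syn_then_anti(self, default_structure):
        confs = [qg.compute_chi(default_structure, 0, ("A", s)).conformation for s in range(1, 6)]
        assert confs == ["syn", "anti", "anti", "anti", "anti"]

    def test_missing_atom_named_in_error(self, default_structure):
        stripped = select(default_structure, Selection(atom_names=tuple(qg.G_BASE_ATOMS)))
        with pytest.raises(qg.GeometryError, match="O4'"):
            qg.compute_chi(stripped, 0, ("A", 1))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

class TestHbonds:
    def test_g_quartet_has_eight_hoogsteen_bonds(self, default_structure):
        g1 = select(default_structure, "resi 1")
        bonds = qg.detect_hbonds(g1, 0)
        by_type = {}
        for b in bonds:
            by_type.setdefault(b.type, []).append(b)
        assert len(by_type["G-Hoogsteen-N1H...O6"]) == 4
        assert len(by_type["G-Hoogsteen-N2H...N7"]) == 4
        assert len(bonds) == 8

    def test_c_quartet_has_four_amino_o2_bonds(self, default_structure):
        c5 = select(default_structure, "resi 5")
        bonds = qg.detect_hbonds(c5, 0)
        assert len(bonds) == 4
        assert all(b.type == "C-amino-N4H...O2" for b in bonds)

    def test_distant_guanines_unbonded(self, default_structure):
        # opposite corners of the quartet are far beyond the cutoff
        far = select(default_structure, "chain A,C and resi 1")
        assert qg.detect_hbonds(far, 0) == []

    def test_bond_distances_within_cutoff(self, default_structure):
        for b in qg.detect_hbonds(default_structure, 0):
            assert 0 < b.distance <= 3.5


# ---------------------------------------------------------------------------
# quartet detection
# ---------------------------------------------------------------------------

class TestDetectQuartets:
    def test_topology_and_stack_order(self, quartets):
        assert [q.base_type for q in quartets] == ["G", "G", "G", "G", "C"]
        assert [q.residues[0].res_seq for q in quartets] == [1, 2, 3, 4, 5]

    def test_single_strand_has_no_quartets(self, default_structure):
        strand = select(default_structure, "chain A")
        assert qg.detect_quartets(strand, 0) == []

    def test_cycle_starts_at_lowest_chain(self, quartets):
        for q in quartets:
            assert q.residues[0].chain_id == "A"

    def test_matches_brute_force_cycle_enumeration(self):
        """Independent oracle: enumerate every 4-subset and cyclic order of
        residues, accept those forming a closed donor->acceptor cycle of
        primary pairing bonds, and compare with the graph algorithm."""
        ens = build_quadruplex(BuilderSpec(n_g_quartets=2, include_c_quartet=False, ions=()))
        bonds = qg.detect_hbonds(ens, 0)
        primary = {
            (b.donor_res, b.acceptor_res)
            for b in bonds
            if b.type in ("G-Hoogsteen-N1H...O6", "C-amino-N4H...O2")
        }
        residues = sorted({r for e in primary for r in e})
        assert len(residues) == 8
        expected = set()
        for combo in itertools.combinations(residues, 4):
            for perm in itertools.permutations(combo):
                if all((perm[i], perm[(i + 1) % 4]) in primary for i in range(4)):
                    expected.add(frozenset(perm))
        found = {frozenset(q.residues) for q in qg.detect_quartets(ens, 0)}
        assert found == expected
        assert len(found) == 2


# ---------------------------------------------------------------------------
# plane, polarity
# ---------------------------------------------------------------------------

class TestPlaneAndPolarity:
    def test_builder_quartets_are_flat(self, quartets):
        for q in quartets:
            assert q.planarity_rmsd == pytest.approx(0.0, abs=1e-6)
            assert abs(np.linalg.norm(q.normal) - 1.0) < 1e-9

    def test_rigid_motion_moves_center_and_keeps_planarity(self, default_structure):
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = transform_ensemble(default_structure, R, t)
        q0 = qg.detect_quartets(default_structure, 0)
        q1 = qg.detect_quartets(moved, 0)
        for a, b in zip(q0, q1):
            assert np.allclose(R @ a.center + t, b.center, atol=1e-6)
            assert b.planarity_rmsd == pytest.approx(a.planarity_rmsd, abs=1e-9)

    def test_collinear_atoms_rejected(self):
        pts = {c: {"O6": np.array([float(i), 0.0, 0.0])} for i, c in enumerate("ABCD")}
        with pytest.raises(qg.GeometryError, match="collinear|degenerate"):
            qg.quartet_plane(pts, "G")

    def test_mirror_image_flips_polarity(self, default_structure):
        mirror = np.diag([-1.0, 1.0, 1.0])  # reflection in a plane containing the axis
        mirrored = transform_ensemble(default_structure, mirror, np.zeros(3))
        for a, b in zip(
            qg.detect_quartets(default_structure, 0), qg.detect_quartets(mirrored, 0)
        ):
            assert {a.polarity, b.polarity} == {"clockwise", "anticlockwise"}

    def test_reversed_view_flips_polarity(self, quartets):
        q = quartets[0]
        assert qg.polarity(q, q.normal) != qg.polarity(q, -q.normal)

    def test_open_cycle_rejected(self, quartets):
        import dataclasses
        q = quartets[0]
        broken = dataclasses.replace(q, hbonds=())
        with pytest.raises(qg.GeometryError, match="cycle"):
            qg.polarity(broken)


# ---------------------------------------------------------------------------
# step geometry
# ---------------------------------------------------------------------------

class TestStepGeometry:
    def test_paper_geometry_offsets_recovered(self, quartets):
        steps = [qg.step_geometry(a, b) for a, b in zip(quartets, quartets[1:])]
        assert [s.d for s in steps[:3]] == pytest.approx([0.4, 0.5, 0.6], abs=1e-6)
        for s in steps:
            assert s.rise == pytest.approx(3.3, abs=1e-6)
            assert s.twist == pytest.approx(21.6, abs=1e-6)

    def test_zero_offset_gives_zero_d(self):
        ens = build_quadruplex(BuilderSpec(offset=0.0, ions=()))
        qs = qg.detect_quartets(ens, 0)
        for a, b in zip(qs, qs[1:]):
            assert qg.step_geometry(a, b).d == pytest.approx(0.0, abs=1e-9)

    def test_d_rise_pythagoras(self, quartets):
        for a, b in zip(quartets, quartets[1:]):
            s = qg.step_geometry(a, b)
            assert s.d**2 + s.rise**2 == pytest.approx(
                float(np.sum((b.center - a.center) ** 2)), abs=1e-9
            )

    def test_descriptors_invariant_under_rigid_motion(self, default_structure):
        rng = np.random.default_rng(11)
        moved = transform_ensemble(default_structure, random_rotation(rng), rng.normal(size=3) * 5)
        s0 = [qg.step_geometry(a, b) for a, b in itertools.pairwise(qg.detect_quartets(default_structure, 0))]
        s1 = [qg.step_geometry(a, b) for a, b in itertools.pairwise(qg.detect_quartets(moved, 0))]
        for x, y in zip(s0, s1):
            assert y.d == pytest.approx(x.d, abs=1e-6)
            assert y.rise == pytest.approx(x.rise, abs=1e-6)
            assert y.twist == pytest.approx(x.twist, abs=1e-6)

    def test_shared_residues_rejected(self, quartets):
        with pytest.raises(qg.GeometryError, match="share"):
            qg.step_geometry(quartets[0], quartets[0])

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        rise=st.floats(2.5, 4.5),
        twist=st.floats(0.0, 40.0),
        offset=st.floats(0.0, 1.5),
    )
    def test_round_trip_over_parameter_ranges(self, rise, twist, offset):
        """Detection + step analysis recovers any constructed geometry."""
        ens = build_quadruplex(
            BuilderSpec(include_c_quartet=False, rise=rise, twist=twist, offset=offset, ions=())
        )
        qs = qg.detect_quartets(ens, 0)
        assert len(qs) == 4
        for a, b in zip(qs, qs[1:]):
            s = qg.step_geometry(a, b)
            assert s.rise == pytest.approx(rise, abs=1e-6)
            assert s.twist == pytest.approx(twist, abs=1e-6)
            assert s.d == pytest.approx(offset, abs=1e-6)


# ---------------------------------------------------------------------------
# stacking modes
# ---------------------------------------------------------------------------

class TestStacking:
    def test_aligned_stack_is_six_six(self):
        ens = build_quadruplex(BuilderSpec(include_c_quartet=False, twist=0.0, offset=0.0, ions=()))
        qs = qg.detect_quartets(ens, 0)
        assert qg.stacking_mode(qs[0], qs[1]) == "six_six"

    def test_default_twist_gives_mixed_ring_overlap(self, quartets):
        assert qg.stacking_mode(quartets[0], quartets[1]) == "five_six"

    def test_labels_are_valid(self, quartets):
        valid = {"five_five", "five_six", "six_six", "partial_six", "none"}
        for a, b in zip(quartets, quartets[1:]):
            assert qg.stacking_mode(a, b) in valid


# ---------------------------------------------------------------------------
# grooves
# ---------------------------------------------------------------------------

class TestGrooves:
    def test_c4_symmetry_gives_equal_widths(self, default_structure, quartets):
        core = [q for q in quartets if q.base_type == "G"]
        recs = qg.classify_grooves(default_structure, 0, core)
        widths = [r.width for r in recs]
        assert len(recs) == 4
        assert max(widths) - min(widths) < 1.2  # helical offset wobble only
        assert all(r.groove_class == "medium" for r in recs)

    def test_degenerate_thresholds_make_all_medium(self, default_structure, quartets):
        core = [q for q in quartets if q.base_type == "G"]
        recs = qg.classify_grooves(default_structure, 0, core, thresholds=(0.0, math.inf))
        assert all(r.groove_class == "medium" for r in recs)

    def test_missing_phosphorus_lists_residues(self, default_structure, quartets):
        no_p = select(default_structure, Selection(atom_names=tuple(qg.G_BASE_ATOMS) + ("C1'", "O4'")))
        core = [q for q in quartets if q.base_type == "G"]
        with pytest.raises(qg.GeometryError, match="A:DG1"):
            qg.classify_grooves(no_p, 0, core)


# ---------------------------------------------------------------------------
# ion assignment
# ---------------------------------------------------------------------------

class TestIons:
    def test_default_ions_sit_in_their_sites(self, default_structure, quartets):
        sites = [a.site for a in qg.assign_ions(default_structure, 0, quartets)]
        assert sites == ["O5", "I", "O3"]

    def test_far_ion_is_bulk(self, quartets):
        ens = build_quadruplex(BuilderSpec(ions=(("O5", "K"),)))
        qs = qg.detect_quartets(ens, 0)
        # displace the ion 20 A off axis
        import dataclasses
        atoms = list(ens.models[0])
        for i, a in enumerate(atoms):
            if a.is_ion:
                atoms[i] = dataclasses.replace(a, xyz=(a.xyz[0] + 20.0, a.xyz[1], a.xyz[2]))
        from g4kit.structure_io import StructureEnsemble
        moved = StructureEnsemble(models=[atoms], metadata="x")
        assignments = qg.assign_ions(moved, 0, qs)
        assert [a.site for a in assignments] == ["bulk"]
        assert assignments[0].radial_distance > 19.0

    def test_no_quartets_rejected(self, default_structure):
        with pytest.raises(qg.GeometryError):
            qg.assign_ions(default_structure, 0, [])

    def test_dimer_interface_site_and_ion_distances(self, dimer_structure):
        qs = qg.detect_quartets(dimer_structure, 0)
        assert len(qs) == 10
        assignments = qg.assign_ions(dimer_structure, 0, qs)
        sites = {a.site for a in assignments}
        assert {"O5", "I", "OGG"} <= sites
        dists = qg.ion_pair_distances(assignments)
        i_ogg = next(v for (x, y), v in dists.items()
                     if {x.split("#")[0], y.split("#")[0]} == {"I", "OGG"})
        # axial separation at default geometry: interface/2 + rise + rise/2
        expected = 3.57 / 2 + 3.3 + 3.3 / 2
        assert i_ogg == pytest.approx(expected, abs=0.15)
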