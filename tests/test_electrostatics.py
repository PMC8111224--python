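"""Coulomb engine, probe placement, structure readers and transition tables."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import costark as ck
from costark.errors import FormatError, SingularityError, ValidationError

from conftest import naive_coulomb_field


def single_charge(position, q=1.0):
    atom = ck.ChargedAtom(ck.AtomID("X", "CHG", "1", "Q"), np.asarray(position, float))
    structure = ck.ChargedStructure([atom])
    return structure, ck.ChargeState("s", {atom.atom_id: q})


class TestCoulombField:
    def test_single_charge_analytic_magnitude_and_direction(self):
        structure, state = single_charge([0.0, 0.0, 0.0], q=1.0)
        E = ck.coulomb_field(structure, state, [10.0, 0.0, 0.0], eps_r=4.0)
        assert np.linalg.norm(E) == pytest.approx(3.59991, abs=1e-9)
        assert E[0] > 0 and abs(E[1]) < 1e-15 and abs(E[2]) < 1e-15  # away from +q

    def test_charge_sign_flip_reverses_vector_exactly(self):
        structure, plus = single_charge([1.0, -2.0, 0.5], q=0.7)
        minus = ck.ChargeState("m", {k: -v for k, v in plus.charges.items()})
        point = [4.0, 1.0, 2.0]
        assert np.array_equal(ck.coulomb_field(structure, plus, point),
                              -ck.coulomb_field(structure, minus, point))

    def test_symmetric_pair_cancels_transverse_components(self):
        a1 = ck.ChargedAtom(ck.AtomID("X", "CHG", "1", "Q"), np.array([0.0, 5.0, 0.0]))
        a2 = ck.ChargedAtom(ck.AtomID("X", "CHG", "2", "Q"), np.array([0.0, -5.0, 0.0]))
        structure = ck.ChargedStructure([a1, a2])
        state = ck.ChargeState("s", {a1.atom_id: 1.0, a2.atom_id: 1.0})
        E = ck.coulomb_field(structure, state, [0.0, 0.0, 0.0])
        assert np.abs(E).max() < 1e-12

    def test_inverse_square_scaling(self):
        structure, state = single_charge([0.0, 0.0, 0.0])
        near = np.linalg.norm(ck.coulomb_field(structure, state, [5.0, 0.0, 0.0]))
        far = np.linalg.norm(ck.coulomb_field(structure, state, [10.0, 0.0, 0.0]))
        assert abs(near / far - 4.0) < 1e-12

    def test_eps_r_scaling(self):
        structure, state = single_charge([1.0, 1.0, 1.0])
        E1 = ck.coulomb_field(structure, state, [5.0, 2.0, 0.0], eps_r=1.0)
        E4 = ck.coulomb_field(structure, state, [5.0, 2.0, 0.0], eps_r=4.0)
        assert np.abs(E4 - E1 / 4.0).max() < 1e-15

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        positions = rng.uniform(-15, 15, size=(n, 3))
        charges = rng.uniform(-1, 1, size=n)
        atoms = [ck.ChargedAtom(ck.AtomID("X", "RND", str(i), "Q"), p)
                 for i, p in enumerate(positions)]
        structure = ck.ChargedStructure(atoms)
        state = ck.ChargeState("s", {a.atom_id: q for a, q in zip(atoms, charges)})
        point = rng.uniform(20, 25, size=3)
        E = ck.coulomb_field(structure, state, point, eps_r=4.0)
        oracle = naive_coulomb_field(positions, charges, point, 4.0)
        assert np.abs(E - oracle).max() < 1e-12 * np.linalg.norm(oracle)

    def test_superposition_over_charges(self):
        rng = np.random.default_rng(9)
        positions = rng.uniform(-10, 10, size=(8, 3))
        charges = rng.uniform(-1, 1, size=8)
        atoms = [ck.ChargedAtom(ck.AtomID("X", "RND", str(i), "Q"), p)
                 for i, p in enumerate(positions)]
        structure = ck.ChargedStructure(atoms)
        point = np.array([14.0, 0.0, 3.0])
        total = ck.coulomb_field(
            structure, ck.ChargeState("all", {a.atom_id: q for a, q in zip(atoms, charges)}),
            point)
        parts = sum(ck.coulomb_field(structure, ck.ChargeState("one", {a.atom_id: q}), point)
                    for a, q in zip(atoms, charges))
        assert np.abs(total - parts).max() < 1e-12 * np.linalg.norm(total)

    def test_coincident_point_raises_naming_atom(self):
        structure, state = single_charge([2.0, 0.0, 0.0])
        with pytest.raises(SingularityError, match="X/CHG/1/Q"):
            ck.coulomb_field(structure, state, [2.0, 0.0, 0.0])


class TestProjection:
    def test_parallel_orthogonal_and_random(self, linear_probe):
        p = linear_probe.p
        assert ck.project_field(3.0 * p, linear_probe) == pytest.approx(3.0)
        assert abs(ck.project_field([1.0, 0.0, 0.0], linear_probe)) < 1e-12
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.standard_normal(3)
            assert ck.project_field(v, linear_probe) == pytest.approx(float(p @ v), abs=1e-12)

    def test_projection_bounded_by_magnitude(self, bent_probe):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.standard_normal(3)
            assert abs(ck.project_field(v, bent_probe)) <= np.linalg.norm(v) + 1e-12


class TestFieldChange:
    def test_unit_charge_behind_probe(self, linear_probe):
        spec = ck.ToyStructureSpec(
            [(linear_probe.midpoint - 5.0 * linear_probe.p, 0.0, 1.0)], probe=linear_probe)
        structure, sa, sb = ck.generate_toy_structure(spec)
        res = ck.field_change(structure, sb, sa, linear_probe, eps_r=4.0)
        assert res.projection == pytest.approx(14.39964, abs=1e-9)
        assert res.delta_total_charge == pytest.approx(1.0)

    def test_identical_states_give_zero(self, linear_probe):
        spec = ck.ToyStructureSpec([([3.0, 4.0, 0.0], 0.4, 0.4)], probe=linear_probe)
        structure, sa, sb = ck.generate_toy_structure(spec)
        res = ck.field_change(structure, sb, sa, linear_probe)
        assert np.abs(res.field_vector).max() == 0.0
        assert res.projection == 0.0

    def test_frame_invariance_under_rigid_motion(self, bent_probe):
        rng = np.random.default_rng(12)
        positions = rng.uniform(-8, 8, size=(6, 3)) + np.array([0, 0, 10.0])
        q_a = rng.uniform(-0.5, 0.5, size=6)
        q_b = q_a + rng.uniform(-0.5, 0.5, size=6)
        spec = ck.ToyStructureSpec(list(zip(positions, q_a, q_b)), probe=bent_probe)
        structure, sa, sb = ck.generate_toy_structure(spec)
        ref = ck.field_change(structure, sb, sa, bent_probe).projection

        R = Rotation.random(random_state=42).as_matrix()
        t = np.array([5.0, -7.0, 11.0])
        moved = ck.ToyStructureSpec(
            [(R @ p + t, a, b) for p, a, b in zip(positions, q_a, q_b)],
            probe=ck.ProbeGeometry(R @ bent_probe.fe_position + t,
                                   R @ bent_probe.c_position + t,
                                   R @ bent_probe.o_position + t))
        m_structure, m_sa, m_sb = ck.generate_toy_structure(moved)
        rotated = ck.field_change(m_structure, m_sb, m_sa, moved.probe).projection
        assert abs(rotated - ref) < 1e-10


class TestProbePlacement:
    def test_idealized_construction_arithmetic(self):
        probe = ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                                  "idealized_linear", d_co=1.13)
        assert np.allclose(probe.c_position, [0, 0, 1.70])
        assert np.allclose(probe.o_position, [0, 0, 2.83])
        assert np.allclose(probe.p, [0, 0, 1])
        assert np.allclose(probe.midpoint, [0, 0, 2.265])
        assert probe.fe_c_o_angle == pytest.approx(180.0, abs=1e-9)

    def test_bent_geometry_hits_requested_angle(self):
        probe = ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]), "bent",
                                  bend_plane=np.array([1.0, 0.0, 0.0]))
        assert probe.fe_c_o_angle == pytest.approx(169.0, abs=0.01)
        assert np.linalg.norm(probe.c_position) == pytest.approx(1.67)
        assert np.linalg.norm(probe.o_position - probe.c_position) == pytest.approx(1.13)

    def test_bent_at_180_reproduces_idealized(self):
        ideal = ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                                  "idealized_linear", d_fe_c=1.70)
        bent = ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]), "bent",
                                 d_fe_c=1.70, angle_deg=180.0,
                                 bend_plane=np.array([1.0, 0.0, 0.0]))
        assert np.abs(bent.o_position - ideal.o_position).max() < 1e-9

    def test_invalid_axis_or_bend_plane(self):
        with pytest.raises(ValidationError):
            ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 2.0]), "idealized_linear")
        with pytest.raises(ValidationError):
            ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]), "bent",
                              bend_plane=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValidationError):
            ck.place_co_probe(np.zeros(3), np.array([0.0, 0.0, 1.0]), "bent")


PQR_FIXTURE = """\
REMARK synthetic three-atom fixture
ATOM      1  FE  HEM A 412      0.000   0.000   0.000  2.0000 1.2000
ATOM      2  O1A PRA A 413      1.000   2.000   3.000 -0.5000 1.5000
HETATM    3  CU  CUA A 500     10.000   0.000   0.000  1.0000 1.1000
"""

PDB_ALTLOC_FIXTURE = """\
ATOM      1  CA AALA A   1      11.000  12.000  13.000  0.50 10.00           C
ATOM      2  CA BALA A   1      11.500  12.000  13.000  0.50 10.00           C
ATOM      3  CB  ALA A   1      12.000  13.000  14.000  1.00 10.00           C
END
"""


class TestStructureReaders:
    def test_pqr_atoms_and_charges(self, tmp_path):
        path = tmp_path / "toy.pqr"
        path.write_text(PQR_FIXTURE)
        structure, state = ck.read_structure(path)
        assert len(structure) == 3
        fe = structure.find("A", "412", "FE")
        assert np.allclose(fe.position, [0, 0, 0])
        assert state.charges[fe.atom_id] == pytest.approx(2.0)
        assert state.total_charge == pytest.approx(2.5, abs=1e-9)

    def test_pqr_without_chain_column(self, tmp_path):
        path = tmp_path / "nochain.pqr"
        path.write_text("ATOM      1  FE  HEM   412      0.0 0.0 0.0  2.0 1.2\n")
        structure, state = ck.read_structure(path)
        assert structure.atoms[0].atom_id.chain == ""
        assert state.total_charge == pytest.approx(2.0)

    def test_pqr_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.pqr"
        path.write_text("ATOM 1 FE HEM A 412 0.0 0.0 zz 2.0 1.2\n")
        with pytest.raises(FormatError) as err:
            ck.read_structure(path)
        assert err.value.line == 1

    def test_pdb_keeps_first_altloc(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(PDB_ALTLOC_FIXTURE)
        structure, state = ck.read_structure(path)
        assert state is None
        names = [a.atom_id.name for a in structure.atoms]
        assert names == ["CA", "CB"]
        ca = structure.find("A", "1", "CA")
        assert ca.position[0] == pytest.approx(11.0)  # first altloc kept


class TestReportTransitions:
    def _three_groups(self, probe):
        rng = np.random.default_rng(21)
        atoms, transitions = [], []
        for g in range(3):
            ids, q = [], {}
            for j in range(2):
                atom_id = ck.AtomID("X", "GRP", f"{g}", f"Q{j}")
                atoms.append(ck.ChargedAtom(atom_id, rng.uniform(4, 12, 3)))
                ids.append(atom_id)
                q[atom_id] = rng.uniform(-1, 1)
            transitions.append(ck.Transition(
                f"group{g}", ck.ChargeState(f"g{g}_i", {i: 0.0 for i in ids}),
                ck.ChargeState(f"g{g}_f", q)))
        return ck.ChargedStructure(atoms), transitions

    def test_disjoint_groups_sum_by_superposition(self, linear_probe):
        structure, transitions = self._three_groups(linear_probe)
        names = [t.name for t in transitions]
        table = ck.report_transitions(structure, transitions, {"p": linear_probe},
                                      sums={"combined": names})
        assert table.loc["combined", "p"] == pytest.approx(
            sum(table.loc[n, "p"] for n in names), abs=1e-10)
        # union transition equals the sum row
        union = ck.Transition(
            "union",
            ck.ChargeState("u_i", {k: 0.0 for t in transitions for k in t.initial.charges}),
            ck.ChargeState("u_f", {k: v for t in transitions for k, v in t.final.charges.items()}))
        t2 = ck.report_transitions(structure, [union], {"p": linear_probe})
        assert t2.loc["union", "p"] == pytest.approx(table.loc["combined", "p"], abs=1e-10)

    def test_duplicate_probes_give_identical_columns(self, linear_probe):
        structure, transitions = self._three_groups(linear_probe)
        table = ck.report_transitions(structure, transitions,
                                      {"a": linear_probe, "b": linear_probe})
        assert np.array_equal(table["a"].to_numpy(), table["b"].to_numpy())

    def test_unknown_sum_member_raises(self, linear_probe):
        structure, transitions = self._three_groups(linear_probe)
        with pytest.raises(KeyError, match="nonsense"):
            ck.report_transitions(structure, transitions, {"p": linear_probe},
                                  sums={"bad": ["nonsense"]})
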