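"""Data model, I/O and periodic-geometry primitives."""

import numpy as np
import pytest

from voroshell.core import (
    Frame,
    SimulationBox,
    StructureError,
    Trajectory,
    center_of_mass,
    minimum_image_distance,
    read_topology,
    read_trajectory,
    molecule_centers_of_mass,
    wrap_frame,
    write_topology,
    write_xyz,
)

from conftest import single_atom_topology, water_like_topology


class TestSimulationBox:
    def test_volume_is_edge_product(self):
        box = SimulationBox((2.0, 3.0, 4.0))
        assert box.volume == pytest.approx(24.0)

    @pytest.mark.parametrize("edges", [(0.0, 1, 1), (-1, 1, 1), (1, 1)])
    def test_invalid_edges_rejected(self, edges):
        with pytest.raises(StructureError):
            SimulationBox(edges)


class TestXyzRoundTrip:
    def test_coordinates_and_times_survive(self, tmp_path):
        top = single_atom_topology(["solute", "A", "A"])
        box = SimulationBox((10.0, 10.0, 10.0))
        rng = np.random.default_rng(0)
        frames = [
            Frame(time=0.5 * f, coords=rng.uniform(0, 10, (3, 3)), box=box)
            for f in range(2)
        ]
        path = tmp_path / "t.xyz"
        write_xyz(Trajectory(frames), top, path)
        back = read_trajectory(path, "xyz", top)
        assert len(back) == 2
        for orig, rt in zip(frames, back):
            np.testing.assert_allclose(rt.coords, orig.coords, atol=1e-4)
            assert rt.time == pytest.approx(orig.time)
            np.testing.assert_allclose(rt.box.edges, orig.box.edges)

    def test_atom_count_mismatch_names_frame(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("4\n10 10 10\nX 0 0 0\nX 1 0 0\nX 2 0 0\nX 3 0 0\n")
        with pytest.raises(StructureError, match="frame 0"):
            read_trajectory(path, "xyz", single_atom_topology(["solute", "A", "A"]))

    def test_missing_box_is_an_error(self, tmp_path):
        path = tmp_path / "nobox.xyz"
        path.write_text("2\ncomment without numbers\nX 0 0 0\nX 1 0 0\n")
        with pytest.raises(StructureError, match="box"):
            read_trajectory(path, "xyz", single_atom_topology(["solute", "A"]))


class TestGroPdb:
    def test_gro_box_nm_converted_to_angstrom(self, tmp_path):
        def atom_line(resid, num, x):
            return (
                f"{resid:>5d}{'SOL':<5s}{'X':>5s}{num:>5d}"
                f"{x:8.3f}{x:8.3f}{x:8.3f}\n"
            )

        gro = (
            "two atoms\n"
            "    2\n"
            + atom_line(1, 1, 1.0)
            + atom_line(2, 2, 2.0)
            + "   6.00150   6.00150   6.00150\n"
        )
        path = tmp_path / "b.gro"
        path.write_text(gro)
        traj = read_trajectory(path, "gro", single_atom_topology(["solute", "A"]))
        np.testing.assert_allclose(traj[0].box.edges, [60.015, 60.015, 60.015])
        np.testing.assert_allclose(traj[0].coords[0], [10.0, 10.0, 10.0])

    def test_pdb_cryst1_box(self, tmp_path):
        pdb = (
            "CRYST1   25.000   25.000   25.000  90.00  90.00  90.00 P 1\n"
            "ATOM      1  X   MOL A   1       1.000   2.000   3.000  1.00  0.00\n"
            "ATOM      2  X   MOL A   2       4.000   5.000   6.000  1.00  0.00\n"
            "END\n"
        )
        path = tmp_path / "b.pdb"
        path.write_text(pdb)
        traj = read_trajectory(path, "pdb", single_atom_topology(["solute", "A"]))
        np.testing.assert_allclose(traj[0].box.edges, [25.0, 25.0, 25.0])
        np.testing.assert_allclose(traj[0].coords[1], [4.0, 5.0, 6.0])


class TestWrap:
    box = SimulationBox((10.0, 10.0, 10.0))

    def test_negative_coordinate_wraps_up(self):
        f = Frame(0.0, np.array([[-1.0, 0.0, 0.0]]), self.box)
        assert wrap_frame(f).coords[0, 0] == pytest.approx(9.0)

    def test_edge_maps_to_zero_half_open(self):
        f = Frame(0.0, np.array([[10.0, 5.0, 5.0]]), self.box)
        assert wrap_frame(f).coords[0, 0] == pytest.approx(0.0)

    def test_molecule_wrapped_rigidly(self):
        # diatomic straddling the boundary keeps its bond length
        top = water_like_topology(0)
        coords = np.array([[9.7, 5, 5], [10.7, 5, 5], [9.37, 5.94, 5]])
        f = Frame(0.0, coords, self.box)
        wrapped = wrap_frame(f, top)
        d_before = np.linalg.norm(coords[1] - coords[0])
        d_after = np.linalg.norm(wrapped.coords[1] - wrapped.coords[0])
        assert d_after == pytest.approx(d_before, abs=1e-12)


class TestCenterOfMass:
    box = SimulationBox((10.0, 10.0, 10.0))

    def test_centroid_for_equal_masses(self):
        top = single_atom_topology(["solute", "A"])
        # one 2-atom molecule needs a real multi-atom topology
        from voroshell.core import AtomRecord, Topology

        atoms = [
            AtomRecord(0, "X", "X", 1.0, molecule_id=0, species="solute"),
            AtomRecord(1, "X", "X", 1.0, molecule_id=0, species="solute"),
            AtomRecord(2, "X", "X", 1.0, molecule_id=1, species="A"),
        ]
        top = Topology(atoms, solute_id=0)
        f = Frame(0.0, np.array([[0.0, 0, 0], [2.0, 0, 0], [5, 5, 5]]), self.box)
        np.testing.assert_allclose(center_of_mass(f, top, 0), [1.0, 0, 0])

    def test_weighted_mean(self):
        from voroshell.core import AtomRecord, Topology

        atoms = [
            AtomRecord(0, "X", "X", 1.0, molecule_id=0, species="solute"),
            AtomRecord(1, "X", "X", 3.0, molecule_id=0, species="solute"),
            AtomRecord(2, "X", "X", 1.0, molecule_id=1, species="A"),
        ]
        top = Topology(atoms, solute_id=0)
        f = Frame(0.0, np.array([[0.0, 0, 0], [4.0, 0, 0], [5, 5, 5]]), self.box)
        assert center_of_mass(f, top, 0)[0] == pytest.approx(3.0)

    def test_boundary_straddling_molecule(self):
        # atoms at x = 9.5 and 0.5: the physical center is at 10.0 -> 0.0
        from voroshell.core import AtomRecord, Topology

        atoms = [
            AtomRecord(0, "X", "X", 1.0, molecule_id=0, species="solute"),
            AtomRecord(1, "X", "X", 1.0, molecule_id=0, species="solute"),
            AtomRecord(2, "X", "X", 1.0, molecule_id=1, species="A"),
        ]
        top = Topology(atoms, solute_id=0)
        f = Frame(
            0.0, np.array([[9.5, 0, 0], [0.5, 0, 0], [5, 5, 5]]), self.box
        )
        com = center_of_mass(f, top, 0)
        assert com[0] == pytest.approx(0.0, abs=1e-9)

    def test_vectorized_matches_scalar(self, small_gas):
        traj, top = small_gas
        frame = traj[0]
        coms = molecule_centers_of_mass(frame, top)
        for i in (0, 17, 63):
            np.testing.assert_allclose(
                coms[i], center_of_mass(frame, top, i), atol=1e-12
            )


class TestMinimumImage:
    box = SimulationBox((10.0, 10.0, 10.0))

    def test_nearest_image(self):
        d = minimum_image_distance(
            np.array([1.0, 0, 0]), np.array([9.0, 0, 0]), self.box
        )
        assert d == pytest.approx(2.0)

    def test_identity(self):
        p = np.array([3.3, 4.4, 5.5])
        assert minimum_image_distance(p, p, self.box) == 0.0

    def test_against_27_image_brute_force(self):
        rng = np.random.default_rng(5)
        box = SimulationBox((7.0, 9.0, 11.0))
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) * box.edges
        for _ in range(50):
            a = rng.uniform(0, box.edges)
            b = rng.uniform(0, box.edges)
            brute = np.min(np.linalg.norm(a - (b + shifts), axis=1))
            assert minimum_image_distance(a, b, box) == pytest.approx(
                brute, rel=1e-12
            )

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(6)
        half_diag = 0.5 * np.linalg.norm(self.box.edges)
        for _ in range(20):
            a, b = rng.uniform(0, 10, (2, 3))
            dab = minimum_image_distance(a, b, self.box)
            assert dab == pytest.approx(
                minimum_image_distance(b, a, self.box), rel=1e-14
            )
            assert dab <= half_diag + 1e-12


class TestTopologyConfig:
    def test_yaml_round_trip(self, tmp_path):
        top = water_like_topology(3)
        path = tmp_path / "topo.yaml"
        write_topology(top, path)
        back = read_topology(path)
        assert back.n_atoms == top.n_atoms
        assert back.solute_id == top.solute_id
        assert back.species_of == top.species_of
        np.testing.assert_allclose(back.charges, top.charges)
        assert sorted(back.bonds) == sorted(top.bonds)

    def test_donor_without_bond_rejected(self):
        from voroshell.core import AtomRecord, Topology

        atoms = [
            AtomRecord(0, "H", "H", 1.0, molecule_id=0, species="s",
                       is_donor_h=True),
            AtomRecord(1, "X", "X", 1.0, molecule_id=1, species="A"),
        ]
        with pytest.raises(StructureError, match="covalent"):
            Topology(atoms, solute_id=0)

    def test_trajectory_requires_uniform_spacing(self):
        box = SimulationBox((5, 5, 5))
        frames = [
            Frame(t, np.zeros((1, 3)), box) for t in (0.0, 1.0, 2.5)
        ]
        with pytest.raises(StructureError, match="uniform"):
            Trajectory(frames)
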