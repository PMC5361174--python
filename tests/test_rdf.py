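"""RDF construction, shell decomposition, and Kirkwood-Buff integrals."""

import numpy as np
import pytest

from voroshell.core import Frame, SimulationBox, Trajectory
from voroshell.rdf import (
    RdfCurve,
    com_rdf,
    cumulative_cn,
    excess_cn,
    first_minimum,
    kb_analysis,
    kb_integral,
    nearest_atom_rdf,
    shell_decompose_rdf,
)
from voroshell.voronoi import BULK_SHELL, shell_map_for

from conftest import single_atom_topology


def synthetic_curve(g_of_r, bin_width=0.1, r_max=12.0, rho=0.02):
    edges = bin_width * np.arange(int(r_max / bin_width) + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfCurve(
        bin_edges=edges,
        values=np.asarray(g_of_r(centers), dtype=float),
        pair_counts=np.zeros(len(centers), dtype=np.int64),
        bulk_density=rho,
        metric="com_r",
        n_frames=1,
        species="A",
    )


class TestComRdf:
    def test_counts_match_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        L, n = 12.0, 25
        box = SimulationBox((L, L, L))
        top = single_atom_topology(["solute"] + ["A"] * (n - 1))
        frames = [Frame(float(t), rng.uniform(0, L, (n, 3)), box) for t in range(3)]
        traj = Trajectory(frames)
        curve = com_rdf(traj, top, "A", bin_width=0.25)

        bw = 0.25
        brute = np.zeros_like(curve.pair_counts)
        shifts = (
            np.array(
                [
                    [i, j, k]
                    for i in (-1, 0, 1)
                    for j in (-1, 0, 1)
                    for k in (-1, 0, 1)
                ]
            )
            * L
        )
        for f in frames:
            for m in range(1, n):
                d = np.min(
                    np.linalg.norm(f.coords[0] - (f.coords[m] + shifts), axis=1)
                )
                if d < curve.bin_edges[-1]:
                    brute[int(d // bw)] += 1
        np.testing.assert_array_equal(curve.pair_counts, brute)

    def test_single_fixed_molecule_occupies_one_bin(self):
        L = 20.0
        top = single_atom_topology(["solute", "A"])
        coords = np.array([[10.0, 10, 10], [10.0 + 4.33, 10, 10]])
        traj = Trajectory([Frame(0.0, coords, SimulationBox((L, L, L)))])
        curve = com_rdf(traj, top, "A", bin_width=0.1)
        nonzero = np.flatnonzero(curve.pair_counts)
        assert len(nonzero) == 1
        lo, hi = curve.bin_edges[nonzero[0]], curve.bin_edges[nonzero[0] + 1]
        assert lo <= 4.33 < hi

    def test_ideal_gas_is_flat_within_poisson_noise(self):
        from voroshell.synthetic import SyntheticSpec, gen_ideal_gas

        spec = SyntheticSpec(
            kind="ideal_gas", n_molecules=300, n_frames=60, seed=8,
            species_fractions={"A": 1.0},
        )
        traj, top, _ = gen_ideal_gas(spec)
        curve = com_rdf(traj, top, "A", bin_width=0.2, r_max=6.0)
        sel = curve.bin_centers > 1.0
        edges = curve.bin_edges
        vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = curve.bulk_density * vol * curve.n_frames
        sigma = 1.0 / np.sqrt(expected[sel])
        assert np.all(np.abs(curve.values[sel] - 1.0) < 3.0 * sigma)

    def test_r_max_beyond_half_box_rejected(self, small_gas):
        traj, top = small_gas
        with pytest.raises(ValueError, match="minimum-image"):
            com_rdf(traj, top, "A", r_max=0.51 * traj[0].box.min_edge)


class TestNearestAtomRdf:
    def test_single_atom_solute_reduces_to_com_rdf(self, small_gas):
        traj, top = small_gas
        c1 = com_rdf(traj, top, "A", bin_width=0.2)
        c2 = nearest_atom_rdf(traj, top, "A", bin_width=0.2)
        np.testing.assert_array_equal(c1.pair_counts, c2.pair_counts)

    def test_solvent_ring_at_fixed_nearest_distance(self):
        # linear triatomic solute along x, solvent ring at s0 from the middle atom
        from voroshell.core import AtomRecord, Topology

        L, s0 = 30.0, 3.0
        atoms = [
            AtomRecord(i, "C", "C", 12.0, molecule_id=0, species="solute")
            for i in range(3)
        ]
        n_ring = 12
        atoms += [
            AtomRecord(3 + i, "X", "X", 1.0, molecule_id=1 + i, species="A")
            for i in range(n_ring)
        ]
        top = Topology(atoms, solute_id=0)
        center = np.array([15.0, 15.0, 15.0])
        solute = center + np.array([[-1.5, 0, 0], [0, 0, 0], [1.5, 0, 0]])
        angles = 2 * np.pi * np.arange(n_ring) / n_ring
        ring = center + s0 * np.stack(
            [np.zeros(n_ring), np.cos(angles), np.sin(angles)], axis=1
        )
        traj = Trajectory(
            [Frame(0.0, np.vstack([solute, ring]), SimulationBox((L, L, L)))]
        )
        curve = nearest_atom_rdf(traj, top, "A", bin_width=0.1)
        nonzero = np.flatnonzero(curve.pair_counts)
        assert len(nonzero) == 1
        assert curve.pair_counts[nonzero[0]] == n_ring
        assert curve.bin_edges[nonzero[0]] <= s0 < curve.bin_edges[nonzero[0] + 1]

    def test_counts_match_min_over_atoms_brute_force(self):
        rng = np.random.default_rng(13)
        from voroshell.core import AtomRecord, Topology

        L = 10.0
        atoms = [
            AtomRecord(i, "C", "C", 12.0, molecule_id=0, species="solute")
            for i in range(4)
        ] + [
            AtomRecord(4 + i, "X", "X", 1.0, molecule_id=1 + i, species="A")
            for i in range(15)
        ]
        top = Topology(atoms, solute_id=0)
        coords = rng.uniform(0, L, (19, 3))
        traj = Trajectory([Frame(0.0, coords, SimulationBox((L, L, L)))])
        curve = nearest_atom_rdf(traj, top, "A", bin_width=0.2)

        shifts = (
            np.array(
                [
                    [i, j, k]
                    for i in (-1, 0, 1)
                    for j in (-1, 0, 1)
                    for k in (-1, 0, 1)
                ]
            )
            * L
        )
        brute = np.zeros_like(curve.pair_counts)
        for m in range(4, 19):
            best = min(
                np.min(np.linalg.norm(coords[a] - (coords[m] + shifts), axis=1))
                for a in range(4)
            )
            if best < curve.bin_edges[-1]:
                brute[int(best // 0.2)] += 1
        np.testing.assert_array_equal(curve.pair_counts, brute)


class TestShellDecomposition:
    def test_components_sum_to_total_bin_exactly(self, small_gas, small_gas_shells):
        traj, top = small_gas
        _, shell_map, _ = small_gas_shells
        curve = shell_decompose_rdf(traj, top, "A", shell_map, shells=(1, 2, 3))
        total = sum(curve.shell_pair_counts.values())
        np.testing.assert_array_equal(total, curve.pair_counts)
        recon = sum(curve.shell_components.values())
        np.testing.assert_allclose(recon, curve.values, atol=1e-12)

    def test_two_molecule_system_all_in_shell_one(self):
        L = 10.0
        top = single_atom_topology(["solute", "A"])
        coords = np.array([[2.5, 5.0, 5.0], [6.5, 5.0, 5.0]])
        traj = Trajectory([Frame(0.0, coords, SimulationBox((L, L, L)))])
        shell_map = shell_map_for(traj, top)
        curve = shell_decompose_rdf(traj, top, "A", shell_map, shells=(1,))
        assert curve.shell_pair_counts[1].sum() == 1
        assert curve.shell_pair_counts[BULK_SHELL].sum() == 0

    def test_sc_lattice_shell_masses(self):
        from voroshell.synthetic import SyntheticSpec, gen_lattice

        spec = SyntheticSpec(
            kind="sc_lattice", n_molecules=125,
            box=SimulationBox((15.0, 15.0, 15.0)),
        )
        frame, top, _ = gen_lattice(spec)
        traj = Trajectory([frame])
        shell_map = shell_map_for(traj, top)
        curve = shell_decompose_rdf(
            traj, top, "A", shell_map, shells=(1, 2), bin_width=0.1
        )
        assert curve.shell_pair_counts[1].sum() == 6
        assert curve.shell_pair_counts[2].sum() == 18

    def test_frame_mismatch_rejected(self, small_gas, small_gas_shells):
        from voroshell.voronoi import ShellMap

        traj, top = small_gas
        _, shell_map, _ = small_gas_shells
        short = ShellMap(shell_map.shells[:-1], shell_map.molecule_ids)
        with pytest.raises(Exception, match="frames"):
            shell_decompose_rdf(traj, top, "A", short)


class TestCoordinationNumber:
    def test_zero_g_gives_zero_cn(self):
        curve = synthetic_curve(lambda r: np.zeros_like(r))
        assert cumulative_cn(curve, 5.0) == 0.0

    def test_uniform_g_gives_sphere_volume_times_density(self):
        rho = 0.02
        curve = synthetic_curve(lambda r: np.ones_like(r), rho=rho)
        R = 5.0
        expected = 4 / 3 * np.pi * R**3 * rho
        assert cumulative_cn(curve, R) == pytest.approx(expected, rel=1e-3)

    def test_gaussian_bump_matches_fine_quadrature(self):
        rho = 0.02

        def g(r):
            return 1.0 + 2.0 * np.exp(-((r - 4.0) ** 2) / 0.5)

        curve = synthetic_curve(g, bin_width=0.05)
        R = 8.0
        rr = np.linspace(0, R, 200_001)
        oracle = rho * np.trapezoid(g(rr) * 4 * np.pi * rr**2, rr)
        assert cumulative_cn(curve, R) == pytest.approx(oracle, rel=1e-4)

    def test_cn_running_curve_is_non_decreasing(self):
        curve = synthetic_curve(lambda r: 1.0 + np.sin(r) ** 2)
        kb = kb_integral(curve)
        assert np.all(np.diff(kb.cn_running) >= -1e-12)


class TestFirstMinimum:
    @staticmethod
    def peaked(centers, peak=3.0, trough=5.0, peak2=7.0):
        return (
            1.0
            + 1.5 * np.exp(-((centers - peak) ** 2) / 0.3)
            - 0.5 * np.exp(-((centers - trough) ** 2) / 0.3)
            + 0.8 * np.exp(-((centers - peak2) ** 2) / 0.3)
        )

    def test_finds_trough_between_two_peaks(self):
        curve = synthetic_curve(lambda r: self.peaked(r))
        result = first_minimum(curve)
        assert result.r == pytest.approx(5.0, abs=0.2)
        assert not result.ambiguous

    def test_monotone_curve_is_an_error(self):
        curve = synthetic_curve(lambda r: 0.1 * r)
        with pytest.raises(ValueError):
            first_minimum(curve)

    def test_near_equal_double_trough_sets_ambiguity_flag(self):
        def g(r):
            return (
                1.0
                + np.exp(-((r - 2.5) ** 2) / 0.2)
                - 0.5 * np.exp(-((r - 4.0) ** 2) / 0.2)
                + 0.7 * np.exp(-((r - 5.5) ** 2) / 0.2)
                - 0.51 * np.exp(-((r - 7.0) ** 2) / 0.2)
                + 0.7 * np.exp(-((r - 8.5) ** 2) / 0.2)
            )

        curve = synthetic_curve(g)
        result = first_minimum(curve)
        assert result.ambiguous


class TestKirkwoodBuff:
    def test_uniform_g_gives_zero_integral(self):
        curve = synthetic_curve(lambda r: np.ones_like(r))
        assert kb_integral(curve).delta_g == pytest.approx(0.0, abs=1e-9)

    def test_hard_sphere_step_closed_form(self):
        sigma = 3.0
        curve = synthetic_curve(
            lambda r: (r >= sigma).astype(float), bin_width=0.01
        )
        expected = -4.0 / 3.0 * np.pi * sigma**3
        assert kb_integral(curve, r_upper=10.0).delta_g == pytest.approx(
            expected, rel=1e-3
        )

    def test_sampled_ideal_gas_consistent_with_zero(self):
        from voroshell.synthetic import SyntheticSpec, gen_ideal_gas

        spec = SyntheticSpec(
            kind="ideal_gas", n_molecules=300, n_frames=80, seed=19,
            species_fractions={"A": 1.0},
        )
        traj, top, _ = gen_ideal_gas(spec)
        curve = com_rdf(traj, top, "A", bin_width=0.2, r_max=6.0)
        kb = kb_integral(curve)
        # resampling oracle: KB noise from per-frame pair-count fluctuations
        n_boot = 200
        rng = np.random.default_rng(0)
        edges = curve.bin_edges
        vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        lam = curve.bulk_density * vol * curve.n_frames
        samples = rng.poisson(lam, size=(n_boot, len(lam)))
        g_boot = samples / lam
        r = np.concatenate([[0.0], curve.bin_centers])
        sigma_kb = np.std(
            [
                np.trapezoid(
                    (np.concatenate([[0.0], g]) - 1.0) * 4 * np.pi * r**2, r
                )
                for g in g_boot
            ]
        )
        assert abs(kb.delta_g) < 3 * sigma_kb

    def test_excess_cn_definition_and_sign(self):
        sigma = 3.0
        curve = synthetic_curve(
            lambda r: (r >= sigma).astype(float), bin_width=0.02, rho=0.02
        )
        kb = kb_analysis(curve, R=6.0)
        assert excess_cn(kb) < 0
        expected = kb.cn_at_R - 4 / 3 * np.pi * 6.0**3 * curve.bulk_density
        assert excess_cn(kb) == pytest.approx(expected, rel=1e-12)

    def test_excess_cn_equals_density_times_kb_integral(self):
        """ΔCN = rho·ΔG(R): both code paths agree (algebraic identity)."""

        def g(r):
            return 1.0 + 1.2 * np.exp(-((r - 3.5) ** 2) / 0.4)

        curve = synthetic_curve(g, bin_width=0.02)
        R = 6.0
        kb = kb_analysis(curve, R=R, r_upper=R)
        dcn = excess_cn(kb)
        # both routes share the g-quadrature; they differ only in the O(Δr²)
        # trapezoid error of the analytic (4π/3)R³ term
        assert dcn == pytest.approx(curve.bulk_density * kb.delta_g, rel=1e-3)
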