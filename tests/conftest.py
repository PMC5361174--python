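import numpy as np
import pytest

from voroshell.core import AtomRecord, Frame, SimulationBox, Topology, Trajectory


def single_atom_topology(species_seq, solute_id=0, masses=None):
    """n single-atom molecules with the given species labels."""
    atoms = [
        AtomRecord(
            atom_id=i,
            name="X",
            element="X",
            mass=1.0 if masses is None else masses[i],
            molecule_id=i,
            species=sp,
        )
        for i, sp in enumerate(species_seq)
    ]
    return Topology(atoms, solute_id=solute_id)


def water_like_topology(n_waters, solute_charge=0.0):
    """A 3-site solute (O, H, H) plus n rigid 3-site water-like molecules,
    with donor/acceptor flags and SPC/E-like parameters."""
    atoms, bonds = [], []
    for m in range(n_waters + 1):
        base = 3 * m
        sp = "solute" if m == 0 else "water"
        q_o = solute_charge - 0.8476 if m == 0 else -0.8476
        atoms += [
            AtomRecord(base, "OW", "O", 15.999, charge=q_o, lj_epsilon=0.6502,
                       lj_sigma=3.166, molecule_id=m, species=sp,
                       is_acceptor=True),
            AtomRecord(base + 1, "HW1", "H", 1.008, charge=0.4238,
                       molecule_id=m, species=sp, is_donor_h=True),
            AtomRecord(base + 2, "HW2", "H", 1.008, charge=0.4238,
                       molecule_id=m, species=sp, is_donor_h=True),
        ]
        bonds += [(base, base + 1), (base, base + 2)]
    return Topology(atoms, solute_id=0, bonds=bonds)


def place_water(center, rot=np.eye(3)):
    """Rigid water-geometry triplet (O at center), OH = 1.0 Å, 109.47°."""
    local = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-0.3333, 0.9428, 0.0]]
    )
    return center + local @ rot.T


@pytest.fixture(scope="session")
def small_gas():
    """20-frame 100-molecule uniform gas shared by identity tests."""
    from voroshell.synthetic import SyntheticSpec, gen_ideal_gas

    spec = SyntheticSpec(kind="ideal_gas", n_molecules=100, n_frames=20, seed=42)
    traj, top, info = gen_ideal_gas(spec)
    return traj, top


@pytest.fixture(scope="session")
def small_gas_shells(small_gas):
    from voroshell.voronoi import shell_census, shell_map_for, tessellate_frame

    traj, top = small_gas
    cells = [tessellate_frame(f, top) for f in traj]
    shell_map = shell_map_for(traj, top, cells)
    census = shell_census(traj, top, 3, shell_map, cells)
    return cells, shell_map, census
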