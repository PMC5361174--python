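"""Core data model: periodic boxes, topologies, frames and trajectory I/O.

All coordinate conventions of the package live here.  Internally every
length is in Angstrom, times in ps, energies in kJ/mol, temperatures in K.
Boxes are orthorhombic; triclinic input is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimulationBox",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "StructureError",
    "read_topology",
    "read_trajectory",
    "write_xyz",
    "wrap_frame",
    "center_of_mass",
    "molecule_centers_of_mass",
    "minimum_image_displacement",
    "minimum_image_distance",
]


class StructureError(ValueError):
    """Raised when a file or topology violates a structural contract."""


#: standard atomic masses (amu) for the elements that occur in the targeted
#: solute/solvent systems; unknown elements fall back to unit mass.
STANDARD_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.904,
    "X": 1.0,
}


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box with edge lengths in Angstrom."""

    edge_lengths: tuple[float, float, float]

    def __post_init__(self):
        edges = np.asarray(self.edge_lengths, dtype=float)
        if edges.shape != (3,):
            raise StructureError(
                f"box needs exactly three edge lengths, got {edges.shape}"
            )
        if not np.all(edges > 0):
            raise StructureError(f"box edges must be positive, got {edges}")
        object.__setattr__(self, "edge_lengths", tuple(float(e) for e in edges))

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))

    @property
    def min_edge(self) -> float:
        return float(np.min(self.edges))


@dataclass(frozen=True)
class AtomRecord:
    """Single atom with force-field metadata.

    ``charge`` is in elementary charges, ``lj_epsilon`` in kJ/mol,
    ``lj_sigma`` in Angstrom.  ``is_donor_h`` marks hydrogens that can act
    as hydrogen-bond donors (they must have a covalently bonded partner in
    the topology); ``is_acceptor`` marks hydrogen-bond acceptor atoms.
    """

    atom_id: int
    name: str
    element: str
    mass: float
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 0.0
    molecule_id: int = 0
    species: str = ""
    is_donor_h: bool = False
    is_acceptor: bool = False

    def __post_init__(self):
        if self.mass < 0:
            raise StructureError(f"atom {self.atom_id}: negative mass")
        if self.lj_epsilon < 0 or self.lj_sigma < 0:
            raise StructureError(f"atom {self.atom_id}: negative LJ parameter")


class Topology:
    """Static description of the system: atoms, molecules, species, bonds.

    Exactly one molecule is the solute.  Molecule ids are contiguous
    integers starting at 0 and atoms of one molecule are contiguous in the
    global atom order (the order of trajectory files).
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        solute_id: int,
        bonds: Iterable[tuple[int, int]] = (),
    ):
        self.atoms = list(atoms)
        self.n_atoms = len(self.atoms)
        if self.n_atoms == 0:
            raise StructureError("topology has no atoms")

        # group atom indices by molecule; require contiguity
        self.molecules: dict[int, np.ndarray] = {}
        self.species_of: dict[int, str] = {}
        for idx, atom in enumerate(self.atoms):
            self.molecules.setdefault(atom.molecule_id, []).append(idx)
            self.species_of[atom.molecule_id] = atom.species
        for mol_id, idxs in self.molecules.items():
            arr = np.asarray(idxs, dtype=np.intp)
            if not np.array_equal(arr, np.arange(arr[0], arr[-1] + 1)):
                raise StructureError(f"molecule {mol_id}: atoms not contiguous")
            self.molecules[mol_id] = arr
        self.molecule_ids = np.array(sorted(self.molecules), dtype=np.intp)
        self.n_molecules = len(self.molecule_ids)

        if solute_id not in self.molecules:
            raise StructureError(f"solute molecule {solute_id} not in topology")
        self.solute_id = int(solute_id)

        self.bonds: list[tuple[int, int]] = []
        for i, j in bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise StructureError(f"bond ({i}, {j}) references invalid atom ids")
            self.bonds.append((int(i), int(j)))
        self._bond_partners: dict[int, list[int]] = {}
        for i, j in self.bonds:
            self._bond_partners.setdefault(i, []).append(j)
            self._bond_partners.setdefault(j, []).append(i)

        for idx, atom in enumerate(self.atoms):
            if atom.is_donor_h:
                if atom.element != "H":
                    raise StructureError(
                        f"atom {atom.atom_id}: donor flag on non-hydrogen"
                    )
                if idx not in self._bond_partners:
                    raise StructureError(
                        f"atom {atom.atom_id}: donor hydrogen has no covalent bond"
                    )

        # cached per-atom arrays
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms], dtype=float)
        self.atom_molecule = np.array(
            [a.molecule_id for a in self.atoms], dtype=np.intp
        )
        self.species_labels = sorted(
            {s for m, s in self.species_of.items() if m != self.solute_id}
        )

    def atom_indices(self, molecule_id: int) -> np.ndarray:
        return self.molecules[molecule_id]

    def bond_partners(self, atom_index: int) -> list[int]:
        return self._bond_partners.get(atom_index, [])

    def molecules_of_species(self, species: str) -> np.ndarray:
        ids = [m for m in self.molecule_ids if self.species_of[m] == species]
        return np.asarray(ids, dtype=np.intp)

    @property
    def solvent_ids(self) -> np.ndarray:
        return self.molecule_ids[self.molecule_ids != self.solute_id]


@dataclass
class Frame:
    """One snapshot: time (ps), per-atom coordinates (Å) and the box."""

    time: float
    coords: np.ndarray
    box: SimulationBox

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"coords must be (N, 3), got {self.coords.shape}")


class Trajectory:
    """Time-ordered uniformly spaced sequence of frames."""

    TIME_TOL = 1e-6  # ps

    def __init__(self, frames: Sequence[Frame]):
        if not frames:
            raise StructureError("trajectory has no frames")
        self.frames = list(frames)
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise StructureError("frame times must be strictly increasing")
            if np.ptp(dts) > self.TIME_TOL:
                raise StructureError(
                    f"frame spacing not uniform within {self.TIME_TOL} ps"
                )
            self.frame_spacing = float(np.mean(dts))
        else:
            self.frame_spacing = 0.0

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# periodic geometry


def _wrap_coords(coords, edges) -> np.ndarray:
    """Componentwise wrap into [0, edge); guards the floating-point edge
    case where np.mod of a tiny negative value rounds up to the edge."""
    w = np.mod(coords, edges)
    return np.where(w >= edges, w - edges, w)


def minimum_image_displacement(a, b, box: SimulationBox) -> np.ndarray:
    """Nearest-image displacement vector(s) a - b for an orthorhombic box."""
    edges = box.edges
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return delta - edges * np.round(delta / edges)


def minimum_image_distance(a, b, box: SimulationBox) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points a and b (Å)."""
    delta = minimum_image_displacement(a, b, box)
    return np.linalg.norm(delta, axis=-1)


def wrap_frame(frame: Frame, topology: Topology | None = None) -> Frame:
    """Wrap coordinates into [0, edge) per axis.

    With a topology, whole molecules are wrapped rigidly: each molecule is
    first made whole by minimum-image reconstruction from its first atom,
    then translated so that the first atom lies inside the box.  Internal
    geometry is therefore preserved exactly.
    """
    edges = frame.box.edges
    coords = frame.coords.copy()
    if topology is None:
        coords = _wrap_coords(coords, edges)
    else:
        if coords.shape[0] != topology.n_atoms:
            raise StructureError(
                f"frame has {coords.shape[0]} atoms, topology {topology.n_atoms}"
            )
        for mol_id in topology.molecule_ids:
            idxs = topology.molecules[mol_id]
            mol = coords[idxs]
            ref = mol[0]
            # make whole relative to the reference atom
            mol = ref + minimum_image_displacement(mol, ref, frame.box)
            shift = _wrap_coords(ref, edges) - ref
            coords[idxs] = mol + shift
    return replace(frame, coords=coords)


def _whole_molecule(frame: Frame, topology: Topology, molecule_id: int) -> np.ndarray:
    idxs = topology.molecules[molecule_id]
    mol = frame.coords[idxs]
    ref = mol[0]
    return ref + minimum_image_displacement(mol, ref, frame.box)


def center_of_mass(frame: Frame, topology: Topology, molecule_id: int) -> np.ndarray:
    """Mass-weighted center of a molecule after minimum-image reconstruction.

    The molecule is unwrapped relative to its first atom so a molecule
    straddling the boundary gets a physically sensible center, which is
    then wrapped back into [0, edge).
    """
    idxs = topology.molecules[molecule_id]
    masses = topology.masses[idxs]
    total = masses.sum()
    if total <= 0:
        raise StructureError(f"molecule {molecule_id}: total mass is zero")
    mol = _whole_molecule(frame, topology, molecule_id)
    com = (masses[:, None] * mol).sum(axis=0) / total
    return _wrap_coords(com, frame.box.edges)


def molecule_centers_of_mass(frame: Frame, topology: Topology) -> np.ndarray:
    """Centers of mass of all molecules, row i = molecule_ids[i].

    Vectorized equivalent of :func:`center_of_mass` applied to every
    molecule: each molecule is made whole relative to its first atom by
    the minimum-image convention, mass-averaged, and wrapped into the box.
    """
    if frame.coords.shape[0] != topology.n_atoms:
        raise StructureError(
            f"frame has {frame.coords.shape[0]} atoms, topology {topology.n_atoms}"
        )
    first_atom = np.array(
        [topology.molecules[m][0] for m in topology.molecule_ids], dtype=np.intp
    )
    mol_index = np.searchsorted(topology.molecule_ids, topology.atom_molecule)
    refs = frame.coords[first_atom][mol_index]  # per-atom reference position
    whole = refs + minimum_image_displacement(frame.coords, refs, frame.box)
    masses = topology.masses
    totals = np.zeros(len(topology.molecule_ids))
    np.add.at(totals, mol_index, masses)
    if np.any(totals <= 0):
        bad = topology.molecule_ids[totals <= 0]
        raise StructureError(f"molecule {int(bad[0])}: total mass is zero")
    com = np.zeros((len(topology.molecule_ids), 3))
    np.add.at(com, mol_index, masses[:, None] * whole)
    return _wrap_coords(com / totals[:, None], frame.box.edges)


# ---------------------------------------------------------------------------
# topology config


def _species_atoms(spec: dict, species: str, start_atom: int, start_mol: int):
    atoms = []
    for local, a in enumerate(spec["atoms"]):
        element = a.get("element", "X")
        mass = a.get("mass")
        if mass is None:
            if element not in STANDARD_MASSES:
                warnings.warn(
                    f"element {element!r} has no standard mass; using 1.0 amu"
                )
            mass = STANDARD_MASSES.get(element, 1.0)
        atoms.append(
            AtomRecord(
                atom_id=start_atom + local,
                name=a.get("name", f"{element}{local}"),
                element=element,
                mass=float(mass),
                charge=float(a.get("charge", 0.0)),
                lj_epsilon=float(a.get("epsilon", 0.0)),
                lj_sigma=float(a.get("sigma", 0.0)),
                molecule_id=start_mol,
                species=species,
                is_donor_h=bool(a.get("donor", False)),
                is_acceptor=bool(a.get("acceptor", False)),
            )
        )
    bonds = [
        (start_atom + i, start_atom + j) for i, j in spec.get("bonds", [])
    ]
    return atoms, bonds


def read_topology(path: str | Path) -> Topology:
    """Read the YAML topology/parameter config.

    Layout::

        species:
          water:
            atoms:
              - {name: OW, element: O, mass: 15.999, charge: -0.8476,
                 epsilon: 0.6502, sigma: 3.166, acceptor: true}
              - {name: HW1, element: H, charge: 0.4238, donor: true}
              - {name: HW2, element: H, charge: 0.4238, donor: true}
            bonds: [[0, 1], [0, 2]]
        molecules:            # file order of the trajectory
          - {species: caffeine, count: 1}
          - {species: water, count: 500}
        solute: 0             # molecule id
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("species", "molecules"):
        if key not in cfg:
            raise StructureError(f"topology config missing {key!r} section")

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    mol_id = 0
    for block in cfg["molecules"]:
        species = block["species"]
        if species not in cfg["species"]:
            raise StructureError(f"unknown species {species!r} in molecules list")
        spec = cfg["species"][species]
        for _ in range(int(block.get("count", 1))):
            a, b = _species_atoms(spec, species, len(atoms), mol_id)
            atoms.extend(a)
            bonds.extend(b)
            mol_id += 1
    solute = int(cfg.get("solute", 0))
    return Topology(atoms, solute_id=solute, bonds=bonds)


# ---------------------------------------------------------------------------
# trajectory I/O


def _read_xyz(path: Path, topology: Topology) -> Trajectory:
    """XYZ dialect: the comment line carries the box as three floats (Å)
    and optionally a ``t=<ps>`` token."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise StructureError(
                f"frame {frame_index}: bad atom-count line {lines[pos]!r}"
            ) from exc
        if n != topology.n_atoms:
            raise StructureError(
                f"frame {frame_index}: {n} atoms, topology has {topology.n_atoms}"
            )
        comment = lines[pos + 1].split()
        time = float(frame_index)
        box_vals = []
        for tok in comment:
            if tok.startswith("t="):
                time = float(tok[2:])
            else:
                try:
                    box_vals.append(float(tok))
                except ValueError:
                    pass
        if len(box_vals) < 3:
            raise StructureError(
                f"frame {frame_index}: no box (need three floats on the comment line)"
            )
        box = SimulationBox(tuple(box_vals[:3]))
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise StructureError(f"frame {frame_index}: truncated coordinate block")
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in block], dtype=float
        )
        frames.append(Frame(time=time, coords=coords, box=box))
        pos += 2 + n
        frame_index += 1
    if not frames:
        raise StructureError(f"{path}: no frames found")
    return Trajectory(frames)


def _read_mdanalysis(path: Path, fmt: str, topology: Topology) -> Trajectory:
    """GRO / PDB reading through MDAnalysis (GRO is nm on disk; MDAnalysis
    reports Å).  Multi-model PDB files yield multi-frame trajectories."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
    if u.atoms.n_atoms != topology.n_atoms:
        raise StructureError(
            f"frame 0: {u.atoms.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    frames = []
    for i, ts in enumerate(u.trajectory):
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise StructureError(f"frame {i}: no box information in {path}")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise StructureError(
                f"frame {i}: triclinic box (angles {dims[3:6]}); only "
                "orthorhombic boxes are supported"
            )
        frames.append(
            Frame(
                time=float(i),
                coords=ts.positions.astype(float).copy(),
                box=SimulationBox(tuple(float(x) for x in dims[:3])),
            )
        )
    return Trajectory(frames)


def read_trajectory(
    path: str | Path, format: str | None = None, topology: Topology | None = None
) -> Trajectory:
    """Read a trajectory (xyz dialect, gro, or pdb) against a topology."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if topology is None:
        raise ValueError("a topology is required to validate the trajectory")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path, topology)
    if fmt in ("gro", "pdb"):
        return _read_mdanalysis(path, fmt, topology)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the YAML topology config (inverse of :func:`read_topology`).

    Molecules of the same species must be identical copies of the first
    one, which holds for every topology this package builds.
    """
    import yaml

    species_cfg: dict[str, dict] = {}
    mol_runs: list[dict] = []
    for m in topology.molecule_ids:
        sp = topology.species_of[int(m)]
        if sp not in species_cfg:
            idxs = topology.molecules[int(m)]
            atoms = []
            for i in idxs:
                a = topology.atoms[i]
                atoms.append(
                    {
                        "name": a.name,
                        "element": a.element,
                        "mass": a.mass,
                        "charge": a.charge,
                        "epsilon": a.lj_epsilon,
                        "sigma": a.lj_sigma,
                        "donor": a.is_donor_h,
                        "acceptor": a.is_acceptor,
                    }
                )
            local = {int(i): n for n, i in enumerate(idxs)}
            bonds = [
                [local[i], local[j]]
                for i, j in topology.bonds
                if i in local and j in local
            ]
            species_cfg[sp] = {"atoms": atoms, "bonds": bonds}
        if mol_runs and mol_runs[-1]["species"] == sp:
            mol_runs[-1]["count"] += 1
        else:
            mol_runs.append({"species": sp, "count": 1})
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "species": species_cfg,
                "molecules": mol_runs,
                "solute": int(topology.solute_id),
            },
            fh,
            sort_keys=False,
        )


def write_xyz(trajectory: Trajectory | Iterable[Frame], topology: Topology,
              path: str | Path) -> None:
    """Write the XYZ dialect consumed by :func:`read_trajectory`."""
    names = [a.element or a.name for a in topology.atoms]
    with open(path, "w") as fh:
        for frame in trajectory:
            e = frame.box.edges
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"{e[0]:.10g} {e[1]:.10g} {e[2]:.10g} t={frame.time:.10g}\n")
            for name, xyz in zip(names, frame.coords):
                fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
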