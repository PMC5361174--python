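"""Synthetic solute-in-solvent configurations with analytic ground truth.

Every analysis stage of this package can be exercised without any MD data:
the generators below produce trajectories whose shell structure,
concentration enrichment, or exchange kinetics are known by construction.

* ``ideal_gas`` — uniform i.i.d. single-atom molecules: a structureless
  reference whose g(r) is flat and whose species are distributed
  homogeneously.  The default number density (0.0334 Å⁻³) matches liquid
  water so cell and shell dimensions are on the physical scale.
* ``sc_lattice`` / ``fcc_lattice`` — perfect lattices with exactly known
  Voronoi geometry (simple cubic: 6 face neighbours, cubic cells a³;
  fcc: 12 face neighbours, rhombic-dodecahedral cells).
* ``enriched_shell`` — a fixed central solute with one species enriched by
  a factor f inside a spherical well; each enriched molecule falls in the
  well with probability f·V_well/V_box (uniform within its zone), which
  makes the imposed well-vs-whole-box concentration ratio *exactly* f for
  any well size.
* ``exchange_dynamics`` — independent two-state Markov chains hopping
  between an inner zone (first shell by construction) and a reservoir:
  the normalized residence correlation is p + (1-p)·exp(-k·t) with
  relaxation rate k and stationary occupancy p, analytically.
* ``planar_solute`` — a rigid flat plate with a structured contact layer
  at fixed nearest-atom distance plus a uniform background: the shell
  anisotropy fixture, where spherical and Voronoi first-shell analyses
  genuinely disagree.

Randomness is drawn from a counter-based stream keyed by (seed, frame),
so each frame is generatable independently and byte-reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AtomRecord,
    Frame,
    SimulationBox,
    Topology,
    Trajectory,
    write_topology,
    write_xyz,
)
from .voronoi import ShellMap

__all__ = [
    "SyntheticSpec",
    "gen_ideal_gas",
    "gen_lattice",
    "gen_enriched_shell",
    "gen_exchange_dynamics",
    "gen_planar_solute",
    "generate",
    "write_fixture",
]

#: liquid-water-like number density, molecules per Å^3
DEFAULT_DENSITY = 0.0334

KINDS = (
    "ideal_gas",
    "sc_lattice",
    "fcc_lattice",
    "enriched_shell",
    "exchange_dynamics",
    "planar_solute",
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic system; the seed fully determines it."""

    kind: str = "ideal_gas"
    n_molecules: int = 500  # total, including the solute
    box: SimulationBox | None = None  # default: liquid-like density
    species_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "B": 0.5}
    )
    enrichment_factor: float = 3.0
    #: enrichment/exchange inner-zone radius (Å).  The well must contain
    #: the whole first Voronoi shell for the imposed enrichment to be the
    #: first shell's ground truth; at the default liquid-like density the
    #: mean spacing is ~3.1 Å and face neighbours reach ~2x that, so the
    #: default is ~3x the mean spacing.
    well_radius: float = 9.0
    exchange_rate: float = 0.1  # ps^-1, correlation relaxation rate k
    inner_occupancy: float = 0.05  # stationary first-shell probability p
    n_frames: int = 100
    frame_spacing: float = 0.1  # ps
    seed: int = 0
    # planar-solute geometry
    plate_shape: tuple[int, int] = (4, 4)
    plate_spacing: float = 1.4  # Å
    contact_distance: float = 3.0  # Å, nearest-atom distance of the layer
    contact_width: float = 0.6  # Å, layer thickness
    background_min_s: float = 4.5  # Å, background exclusion
    n_contact: int = 40

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        total = sum(self.species_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, not 1")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment factor must be positive")
        if self.exchange_rate < 0:
            raise ValueError("exchange rate must be non-negative")
        if self.box is None:
            edge = (self.n_molecules / DEFAULT_DENSITY) ** (1.0 / 3.0)
            self.box = SimulationBox((edge, edge, edge))

    def rng(self, frame: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % 2**31, frame])


def _species_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Exact largest-remainder apportionment of n molecules."""
    labels = sorted(fractions)
    floors = {sp: int(np.floor(fractions[sp] * n)) for sp in labels}
    rest = n - sum(floors.values())
    remainders = sorted(
        labels, key=lambda sp: (fractions[sp] * n) % 1.0, reverse=True
    )
    for sp in remainders[:rest]:
        floors[sp] += 1
    return floors


def _single_atom_topology(species_seq: list[str], solute_id: int = 0) -> Topology:
    atoms = [
        AtomRecord(
            atom_id=i, name="X", element="X", mass=1.0, molecule_id=i, species=sp
        )
        for i, sp in enumerate(species_seq)
    ]
    return Topology(atoms, solute_id=solute_id)


def gen_ideal_gas(spec: SyntheticSpec) -> tuple[Trajectory, Topology, dict]:
    """Uniform i.i.d. single-atom molecules; molecule 0 is the solute."""
    if spec.n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    n_solvent = spec.n_molecules - 1
    counts = _species_counts(spec.species_fractions, n_solvent)
    species = ["solute"] + [sp for sp in sorted(counts) for _ in range(counts[sp])]
    top = _single_atom_topology(species)
    edges = spec.box.edges
    frames = [
        Frame(
            time=f * spec.frame_spacing,
            coords=spec.rng(f).uniform(0.0, 1.0, (spec.n_molecules, 3)) * edges,
            box=spec.box,
        )
        for f in range(spec.n_frames)
    ]
    return Trajectory(frames), top, {"species_counts": counts}


def gen_lattice(spec: SyntheticSpec) -> tuple[Frame, Topology, dict]:
    """Perfect SC or FCC lattice filling the box; central site is solute.

    The box edge is divided into m unit cells (m from ``n_molecules``:
    m³ sites for SC, 4·m³ for FCC), so the lattice tiles periodically.
    """
    edges = spec.box.edges
    if np.ptp(edges) > 1e-9:
        raise ValueError("lattice generation needs a cubic box")
    L = float(edges[0])
    if spec.kind == "sc_lattice":
        m = max(2, round(spec.n_molecules ** (1.0 / 3.0)))
        cells = np.array(
            [[i, j, k] for i in range(m) for j in range(m) for k in range(m)],
            dtype=float,
        )
        pts = cells * (L / m)
        info = {"lattice_constant": L / m, "shell1": 6, "shell2": 18}
    elif spec.kind == "fcc_lattice":
        m = max(2, round((spec.n_molecules / 4.0) ** (1.0 / 3.0)))
        base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        cells = np.array(
            [
                base + [i, j, k]
                for i in range(m)
                for j in range(m)
                for k in range(m)
            ]
        ).reshape(-1, 3)
        pts = cells * (L / m)
        info = {"lattice_constant": L / m, "shell1": 12}
    else:
        raise ValueError(f"kind {spec.kind!r} is not a lattice")
    solute = int(np.argmin(np.linalg.norm(pts - 0.5 * edges, axis=1)))
    species = ["A"] * len(pts)
    species[solute] = "solute"
    top = _single_atom_topology(species, solute_id=solute)
    info["n_sites"] = len(pts)
    return Frame(time=0.0, coords=pts, box=spec.box), top, info


def _uniform_in_ball(rng, n, center, radius):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, (n, 1)) ** (1.0 / 3.0)
    return center + v * r


def _uniform_outside_ball(rng, n, edges, center, radius):
    out = np.empty((n, 3))
    have = 0
    tries = 0
    while have < n:
        tries += 1
        if tries > 10_000:
            raise ValueError(
                f"exclusion ball radius {radius} Å leaves almost no free "
                f"volume in a box of edges {edges}"
            )
        cand = rng.uniform(0.0, 1.0, (max(2 * (n - have), 16), 3)) * edges
        # ball is centered in the box and radius < L/2, so no image checks
        d = np.linalg.norm(cand - center, axis=1)
        cand = cand[d >= radius]
        take = min(len(cand), n - have)
        out[have : have + take] = cand[:take]
        have += take
    return out


def gen_enriched_shell(spec: SyntheticSpec) -> tuple[Trajectory, Topology, dict]:
    """Central solute with species A enriched by factor f in a ball.

    Each A molecule is placed in the well with probability
    ``f·V_well/V_box`` and uniformly within its zone, so the imposed
    well-vs-whole-box concentration ratio of A equals f exactly; species B
    is uniform everywhere (ratio 1).
    """
    f = spec.enrichment_factor
    edges = spec.box.edges
    center = 0.5 * edges
    if spec.well_radius >= 0.45 * spec.box.min_edge:
        raise ValueError(
            f"well radius {spec.well_radius} Å too large for box edges "
            f"{edges}; needs to stay below 0.45x the smallest edge"
        )
    v_well = 4.0 / 3.0 * np.pi * spec.well_radius**3
    p_in = f * v_well / spec.box.volume
    if p_in > 1.0:
        raise ValueError(
            f"enrichment f={f} with well radius {spec.well_radius} Å needs "
            f"p = f·V_well/V_box = {p_in:.3f} <= 1; shrink the well or f"
        )
    n_solvent = spec.n_molecules - 1
    counts = _species_counts(spec.species_fractions, n_solvent)
    labels = sorted(counts)
    enriched = labels[0]  # first species alphabetically is the enriched one
    species = ["solute"] + [sp for sp in labels for _ in range(counts[sp])]
    top = _single_atom_topology(species)

    frames = []
    for fidx in range(spec.n_frames):
        rng = spec.rng(fidx)
        coords = np.empty((spec.n_molecules, 3))
        coords[0] = center
        row = 1
        for sp in labels:
            n_sp = counts[sp]
            if sp == enriched:
                in_well = rng.random(n_sp) < p_in
                n_in = int(in_well.sum())
                pos = np.empty((n_sp, 3))
                pos[:n_in] = _uniform_in_ball(rng, n_in, center, spec.well_radius)
                pos[n_in:] = _uniform_outside_ball(
                    rng, n_sp - n_in, edges, center, spec.well_radius
                )
            else:
                pos = rng.uniform(0.0, 1.0, (n_sp, 3)) * edges
            coords[row : row + n_sp] = pos
            row += n_sp
        frames.append(
            Frame(time=fidx * spec.frame_spacing, coords=coords, box=spec.box)
        )
    info = {
        "enriched_species": enriched,
        "imposed_ratio": f,
        "well_radius": spec.well_radius,
        "p_in": p_in,
        "species_counts": counts,
    }
    return Trajectory(frames), top, info


def gen_exchange_dynamics(spec: SyntheticSpec) -> tuple[Trajectory, Topology, dict]:
    """Two-state exchange between an inner zone and a reservoir.

    Each solvent molecule is an independent Markov chain with stationary
    inner-zone occupancy p and relaxation rate k: per frame of length dt,
    P(enter) = p·w and P(leave) = (1-p)·w with w = 1 - exp(-k·dt).  The
    residence autocorrelation of the inner zone then decays as
    p + (1-p)·exp(-k·t) exactly.  Ground-truth zone membership is
    returned as a ShellMap (inner = shell 1), so residence analysis can
    run without tessellation.
    """
    n_solvent = spec.n_molecules - 1
    species = ["solute"] + ["A"] * n_solvent
    top = _single_atom_topology(species)
    edges = spec.box.edges
    center = 0.5 * edges
    if 1.5 * spec.well_radius >= 0.45 * spec.box.min_edge:
        raise ValueError(
            f"inner-zone radius {spec.well_radius} Å too large for box "
            f"edges {edges}; the reservoir (beyond 1.5x the zone) would "
            "not fit"
        )
    p = spec.inner_occupancy
    k = spec.exchange_rate
    w = 1.0 - np.exp(-k * spec.frame_spacing)

    rng0 = spec.rng(0)
    state = (rng0.random(n_solvent) < p).astype(bool)
    shells = np.zeros((spec.n_frames, spec.n_molecules), dtype=np.intp)
    frames = []
    for fidx in range(spec.n_frames):
        rng = spec.rng(fidx)
        if fidx > 0:
            u = rng.random(n_solvent)
            flip_in = (~state) & (u < p * w)
            flip_out = state & (u < (1.0 - p) * w)
            state = state ^ flip_in ^ flip_out
        coords = np.empty((spec.n_molecules, 3))
        coords[0] = center
        n_in = int(state.sum())
        inner = _uniform_in_ball(rng, n_in, center, spec.well_radius)
        outer = _uniform_outside_ball(
            rng, n_solvent - n_in, edges, center, 1.5 * spec.well_radius
        )
        coords[1:][state] = inner
        coords[1:][~state] = outer
        shells[fidx, 1:] = np.where(state, 1, 2)
        frames.append(
            Frame(time=fidx * spec.frame_spacing, coords=coords, box=spec.box)
        )
    shell_map = ShellMap(shells, np.arange(spec.n_molecules))
    info = {
        "rate_k": k,
        "stationary_p": p,
        "mean_residence_time": (1.0 / k if k > 0 else np.inf),
        "shell_map": shell_map,
    }
    return Trajectory(frames), top, info


def _plate_coords(spec: SyntheticSpec, center: np.ndarray) -> np.ndarray:
    nx, ny = spec.plate_shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spec.plate_spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spec.plate_spacing
    grid = np.array([[x, y, 0.0] for x in xs for y in ys])
    return grid + center


def gen_planar_solute(spec: SyntheticSpec) -> tuple[Trajectory, Topology, dict]:
    """Rigid flat plate solute with a contact layer plus uniform background.

    The contact layer sits at a nearest-solute-atom distance inside
    ``contact_distance ± contact_width/2`` (rejection-sampled uniformly
    over that shell), emulating a structured first solvation shell of an
    anisotropic solute; the background is uniform beyond
    ``background_min_s``.  Because the plate is flat, contact-layer
    molecules span a wide range of center-of-mass distances and no single
    spherical cutoff can separate the first shell from the background.
    """
    edges = spec.box.edges
    center = 0.5 * edges
    plate = _plate_coords(spec, center)
    n_plate = len(plate)
    n_solvent = spec.n_molecules - 1
    n_bg = n_solvent - spec.n_contact
    if n_bg < 0:
        raise ValueError("n_contact exceeds the number of solvent molecules")

    atoms = [
        AtomRecord(atom_id=i, name="C", element="C", mass=12.011,
                   molecule_id=0, species="solute")
        for i in range(n_plate)
    ] + [
        AtomRecord(atom_id=n_plate + i, name="W", element="X", mass=1.0,
                   molecule_id=1 + i, species="W")
        for i in range(n_solvent)
    ]
    top = Topology(atoms, solute_id=0)

    lo = spec.contact_distance - spec.contact_width / 2.0
    hi = spec.contact_distance + spec.contact_width / 2.0

    def nearest_s(points):
        d = np.linalg.norm(points[:, None, :] - plate[None, :, :], axis=2)
        return d.min(axis=1)

    frames = []
    for fidx in range(spec.n_frames):
        rng = spec.rng(fidx)
        contact = np.empty((spec.n_contact, 3))
        have = 0
        while have < spec.n_contact:
            cand = center + rng.uniform(-hi - 4.0, hi + 4.0, (4096, 3))
            s = nearest_s(cand)
            cand = cand[(s >= lo) & (s < hi)]
            take = min(len(cand), spec.n_contact - have)
            contact[have : have + take] = cand[:take]
            have += take
        background = np.empty((n_bg, 3))
        have = 0
        while have < n_bg:
            cand = rng.uniform(0.0, 1.0, (max(2 * (n_bg - have), 64), 3)) * edges
            cand = cand[nearest_s(cand) > spec.background_min_s]
            take = min(len(cand), n_bg - have)
            background[have : have + take] = cand[:take]
            have += take
        coords = np.vstack([plate, contact, background])
        frames.append(
            Frame(time=fidx * spec.frame_spacing, coords=coords, box=spec.box)
        )
    info = {
        "n_plate_atoms": n_plate,
        "n_contact": spec.n_contact,
        "n_background": n_bg,
        "contact_distance": spec.contact_distance,
        "plate_extent": float(
            (max(spec.plate_shape) - 1) * spec.plate_spacing
        ),
    }
    return Trajectory(frames), top, info


_GENERATORS = {
    "ideal_gas": gen_ideal_gas,
    "sc_lattice": gen_lattice,
    "fcc_lattice": gen_lattice,
    "enriched_shell": gen_enriched_shell,
    "exchange_dynamics": gen_exchange_dynamics,
    "planar_solute": gen_planar_solute,
}


def generate(spec: SyntheticSpec):
    """Dispatch to the generator for ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Generate and write trajectory + topology + ground-truth sidecar.

    Emits ``trajectory.xyz`` (XYZ dialect with box metadata),
    ``topology.yaml`` and ``ground_truth.json``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = generate(spec)
    traj_or_frame, top, info = result
    frames = (
        traj_or_frame
        if isinstance(traj_or_frame, Trajectory)
        else Trajectory([traj_or_frame])
    )
    traj_path = out_dir / "trajectory.xyz"
    topo_path = out_dir / "topology.yaml"
    gt_path = out_dir / "ground_truth.json"
    write_xyz(frames, top, traj_path)
    write_topology(top, topo_path)
    serializable = {
        k: v for k, v in info.items() if isinstance(v, (int, float, str, dict, list))
    }
    serializable["kind"] = spec.kind
    serializable["seed"] = spec.seed
    with open(gt_path, "w") as fh:
        json.dump(serializable, fh, indent=2, default=float)
    return {
        "trajectory": str(traj_path),
        "topology": str(topo_path),
        "ground_truth": str(gt_path),
    }
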