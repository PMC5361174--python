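"""Periodic Voronoi tessellation, molecular cells, and solvation shells.

Every atomic site is tessellated under periodic boundary conditions by
replicating all sites into the 26 neighbouring images and keeping the
cells of primary-image sites.  Atomic cells are merged per molecule:
molecular volume is the sum of atomic volumes and molecular neighbours are
the union of atomic face neighbours belonging to other molecules.  Shell
indices are breadth-first graph distances from the solute over the
molecular neighbour graph (shell 1 = molecules sharing a face with the
solute, shell 2 = their neighbours, and so on).

Cell volumes are computed from the face decomposition: a Voronoi cell is
the union of pyramids with the site as apex and the faces as bases, and
the apex-to-face distance is half the site-to-neighbour distance, so
``V = sum(A_f * d_f / 3)`` is exact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import QhullError, Voronoi

from .core import Frame, SimulationBox, StructureError, Topology, Trajectory, wrap_frame

__all__ = [
    "MolecularCell",
    "ShellMap",
    "ShellCensus",
    "tessellate_frame",
    "assign_shells",
    "shell_map_for",
    "shell_census",
    "BULK_SHELL",
]

#: pooled bucket for molecules beyond ``max_shell`` in a census
BULK_SHELL = -1

#: faces smaller than this (Å^2) are dropped from the adjacency graph; far
#: below any physical contact face, it suppresses the spurious zero-area
#: ridges Qhull emits for degenerate (exact-lattice) site sets.
DEFAULT_MIN_FACE_AREA = 1e-6

_JITTER = 1e-8  # Å, deterministic degeneracy-breaking displacement


@dataclass
class MolecularCell:
    """Merged Voronoi cell of one molecule."""

    molecule_id: int
    volume: float
    neighbors: set[int] = field(default_factory=set)
    face_areas: dict[int, float] = field(default_factory=dict)


_OFFSETS = np.array(
    [
        [i, j, k]
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=float,
)


def _ghost_sites(sites: np.ndarray, box: SimulationBox, margin: float):
    """Primary sites plus 26-image ghost copies within ``margin`` of the box.

    Returns (points, origin) where ``origin[i]`` maps every point back to
    its primary site index.
    """
    n = len(sites)
    edges = box.edges
    pts = [sites]
    origin = [np.arange(n, dtype=np.intp)]
    for off in _OFFSETS:
        shifted = sites + off * edges
        mask = np.all((shifted > -margin) & (shifted < edges + margin), axis=1)
        if np.any(mask):
            pts.append(shifted[mask])
            origin.append(np.flatnonzero(mask).astype(np.intp))
    return np.vstack(pts), np.concatenate(origin)


def _convex_polygon_areas(verts: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Areas of k planar convex polygons with s unordered vertices each.

    ``verts`` is (k, s, 3); ``normals`` (k, 3) are the face normals.
    """
    centroid = verts.mean(axis=1, keepdims=True)
    rel = verts - centroid
    u = rel[:, 0, :]
    un = np.linalg.norm(u, axis=1, keepdims=True)
    un[un == 0] = 1.0
    u = u / un
    v = np.cross(normals, u)
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    vn[vn == 0] = 1.0
    v = v / vn
    x = np.einsum("ksd,kd->ks", rel, u)
    y = np.einsum("ksd,kd->ks", rel, v)
    order = np.argsort(np.arctan2(y, x), axis=1)
    x = np.take_along_axis(x, order, axis=1)
    y = np.take_along_axis(y, order, axis=1)
    return 0.5 * np.abs(
        np.einsum("ks,ks->k", x, np.roll(y, -1, axis=1))
        - np.einsum("ks,ks->k", y, np.roll(x, -1, axis=1))
    )


def _site_tessellation(sites: np.ndarray, box: SimulationBox, margin: float):
    """Voronoi volumes and faces of periodic sites.

    Returns (volumes[n], (i_primary, j_origin, area) arrays) where faces
    are listed once per primary endpoint (a primary-primary face appears
    twice, once from each side).
    """
    n = len(sites)
    pts, origin = _ghost_sites(sites, box, margin)
    vor = Voronoi(pts)

    rp = vor.ridge_points
    keep = (rp[:, 0] < n) | (rp[:, 1] < n)
    rp = rp[keep]
    rverts = [vor.ridge_vertices[i] for i in np.flatnonzero(keep)]
    if any(-1 in rv for rv in rverts):
        raise QhullError("unbounded ridge touching a primary cell")

    delta = pts[rp[:, 1]] - pts[rp[:, 0]]
    dist = np.linalg.norm(delta, axis=1)
    if np.any(dist == 0):
        raise QhullError("coincident sites")
    normals = delta / dist[:, None]

    areas = np.empty(len(rp))
    sizes = np.fromiter((len(rv) for rv in rverts), dtype=np.intp, count=len(rverts))
    for s in np.unique(sizes):
        idx = np.flatnonzero(sizes == s)
        if s < 3:
            areas[idx] = 0.0
            continue
        vi = np.array([rverts[i] for i in idx], dtype=np.intp)
        areas[idx] = _convex_polygon_areas(vor.vertices[vi], normals[idx])

    h = 0.5 * dist
    volumes = np.zeros(n)
    face_i, face_j, face_a = [], [], []
    for side in (0, 1):
        mask = rp[:, side] < n
        p = rp[mask, side]
        q = rp[mask, 1 - side]
        np.add.at(volumes, p, areas[mask] * h[mask] / 3.0)
        face_i.append(p)
        face_j.append(origin[q])
        face_a.append(areas[mask])
    return volumes, (
        np.concatenate(face_i),
        np.concatenate(face_j),
        np.concatenate(face_a),
    )


def tessellate_frame(
    frame: Frame,
    topology: Topology,
    min_face_area: float = DEFAULT_MIN_FACE_AREA,
    heavy_atoms_only: bool = False,
    check_volume: bool = True,
) -> dict[int, MolecularCell]:
    """Periodic Voronoi tessellation of a frame, merged to molecular cells.

    Sites are atoms (optionally heavy atoms only); degenerate site sets are
    retried up to three times with a deterministic 1e-8 Å jitter.  The cell
    volumes partition the box volume; a relative mismatch above 1e-6
    triggers the degeneracy retry as well.
    """
    if topology.n_molecules < 2:
        raise StructureError("tessellation needs at least 2 molecules")
    frame = wrap_frame(frame, topology)
    coords = frame.coords
    if heavy_atoms_only:
        site_idx = np.array(
            [i for i, a in enumerate(topology.atoms) if a.element != "H"],
            dtype=np.intp,
        )
        if len(site_idx) == 0:
            raise StructureError("no heavy atoms to tessellate")
    else:
        site_idx = np.arange(topology.n_atoms, dtype=np.intp)
    sites = np.mod(coords[site_idx], frame.box.edges)
    site_mol = topology.atom_molecule[site_idx]

    # Ghost replication margin: start narrow for speed, escalate to the
    # full 26-image replication; the exact volume-partition identity
    # certifies that no ghost was missed.  Degenerate (exact-lattice)
    # site sets additionally get a deterministic jitter.
    min_edge = frame.box.min_edge
    attempts = [
        (0.3 * min_edge, 0.0),
        (1.01 * frame.box.edges.max(), 0.0),
        (1.01 * frame.box.edges.max(), _JITTER),
        (1.01 * frame.box.edges.max(), _JITTER),
        (1.01 * frame.box.edges.max(), _JITTER),
    ]
    last_err: Exception | None = None
    result = None
    for attempt, (margin, jitter) in enumerate(attempts):
        pts = sites
        if jitter > 0:
            rng = np.random.default_rng(1234567 + attempt)
            pts = sites + rng.uniform(-jitter, jitter, size=sites.shape)
        try:
            volumes, faces = _site_tessellation(pts, frame.box, margin)
        except QhullError as exc:
            last_err = exc
            continue
        if check_volume:
            rel = abs(volumes.sum() - frame.box.volume) / frame.box.volume
            if rel > 1e-6:
                last_err = StructureError(
                    f"cell volumes miss box volume by relative {rel:.2e}"
                )
                continue
        result = (volumes, faces)
        break
    if result is None:
        raise StructureError(f"tessellation failed after retries: {last_err}")
    volumes, (face_i, face_j, face_a) = result

    mol_vol = np.zeros(int(topology.molecule_ids.max()) + 1)
    np.add.at(mol_vol, site_mol, volumes)
    cells = {
        int(m): MolecularCell(molecule_id=int(m), volume=float(mol_vol[m]))
        for m in topology.molecule_ids
    }

    mi = site_mol[face_i]
    mj = site_mol[face_j]
    inter = mi != mj  # drop intra-molecular and periodic self-faces
    mi, mj, fa = mi[inter], mj[inter], face_a[inter]
    # accumulate per unordered molecule pair so the two directions (whose
    # computed areas differ only by roundoff) share one symmetrized area;
    # filtering that single value keeps the neighbour relation symmetric
    n_mol_key = int(topology.molecule_ids.max()) + 1
    lo = np.minimum(mi, mj).astype(np.int64)
    hi = np.maximum(mi, mj).astype(np.int64)
    pair_key = lo * n_mol_key + hi
    uniq, inv = np.unique(pair_key, return_inverse=True)
    pair_area = np.zeros(len(uniq))
    np.add.at(pair_area, inv, 0.5 * fa)
    for key, area in zip(uniq, pair_area):
        if area <= min_face_area:
            continue
        a, b = int(key // n_mol_key), int(key % n_mol_key)
        cells[a].face_areas[b] = float(area)
        cells[a].neighbors.add(b)
        cells[b].face_areas[a] = float(area)
        cells[b].neighbors.add(a)
    return cells


def assign_shells(cells: dict[int, MolecularCell], solute_id: int) -> dict[int, int]:
    """Shell index of every molecule: BFS distance from the solute.

    Solute is shell 0, its face-sharing neighbours shell 1, their
    neighbours shell 2, and so on.
    """
    if solute_id not in cells:
        raise StructureError(f"solute molecule {solute_id} not among cells")
    shells = {solute_id: 0}
    queue = deque([solute_id])
    while queue:
        m = queue.popleft()
        for nb in cells[m].neighbors:
            if nb not in shells:
                shells[nb] = shells[m] + 1
                queue.append(nb)
    missing = set(cells) - set(shells)
    if missing:
        raise StructureError(
            f"neighbor graph disconnected; unreachable molecules {sorted(missing)[:5]}"
        )
    return shells


class ShellMap:
    """Per-frame shell assignment of every molecule.

    ``shells[f, i]`` is the shell index of molecule ``molecule_ids[i]`` in
    frame ``f`` (0 = solute).
    """

    def __init__(self, shells: np.ndarray, molecule_ids: np.ndarray):
        self.shells = np.asarray(shells, dtype=np.intp)
        self.molecule_ids = np.asarray(molecule_ids, dtype=np.intp)
        self._col = {int(m): i for i, m in enumerate(self.molecule_ids)}

    @property
    def n_frames(self) -> int:
        return self.shells.shape[0]

    def shell_of(self, frame_index: int, molecule_id: int) -> int:
        return int(self.shells[frame_index, self._col[molecule_id]])

    def frame_assignment(self, frame_index: int) -> dict[int, int]:
        return {
            int(m): int(k)
            for m, k in zip(self.molecule_ids, self.shells[frame_index])
        }

    def to_dataframe(self, topology: Topology):
        import pandas as pd

        rows = []
        for f in range(self.n_frames):
            for i, m in enumerate(self.molecule_ids):
                rows.append(
                    (f, int(m), topology.species_of[int(m)], int(self.shells[f, i]))
                )
        return pd.DataFrame(rows, columns=["frame", "molecule_id", "species", "shell"])


def shell_map_for(
    trajectory: Trajectory,
    topology: Topology,
    cells_per_frame: list[dict[int, MolecularCell]] | None = None,
    **tess_kwargs,
) -> ShellMap:
    """Tessellate every frame (unless cells are supplied) and assign shells."""
    if cells_per_frame is None:
        cells_per_frame = [
            tessellate_frame(f, topology, **tess_kwargs) for f in trajectory
        ]
    n_mol = topology.n_molecules
    shells = np.zeros((len(cells_per_frame), n_mol), dtype=np.intp)
    for f, cells in enumerate(cells_per_frame):
        assignment = assign_shells(cells, topology.solute_id)
        for i, m in enumerate(topology.molecule_ids):
            shells[f, i] = assignment[int(m)]
    return ShellMap(shells, topology.molecule_ids)


def neighbor_graph_dataframe(
    cells_per_frame: list[dict[int, MolecularCell]],
) -> "pandas.DataFrame":
    """Edge list of the molecular neighbour graph over all frames.

    One row per unordered face-sharing pair: frame, mol_i < mol_j, shared
    face area (Å^2).
    """
    import pandas as pd

    rows = []
    for f, cells in enumerate(cells_per_frame):
        for m, cell in cells.items():
            for nb, area in cell.face_areas.items():
                if m < nb:
                    rows.append((f, m, nb, area))
    return pd.DataFrame(rows, columns=["frame", "mol_i", "mol_j", "face_area"])


@dataclass
class ShellCensus:
    """Time-averaged per-shell per-species counts and shell volumes.

    Shells beyond ``max_shell`` are pooled under :data:`BULK_SHELL`.
    ``counts[(k, species)]`` is the mean molecule count CN_j(shell=k);
    ``volumes[k]`` the mean total cell volume of shell k in Å³.
    """

    max_shell: int
    species: list[str]
    counts: dict[tuple[int, str], float]
    volumes: dict[int, float]
    solute_volume: float
    box_volume: float
    n_frames: int
    per_frame_counts: dict[tuple[int, str], np.ndarray]
    per_frame_volumes: dict[int, np.ndarray]

    def count(self, shell: int, species: str) -> float:
        return self.counts.get((shell, species), 0.0)

    def volume(self, shell: int) -> float:
        return self.volumes.get(shell, 0.0)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k in list(range(1, self.max_shell + 1)) + [BULK_SHELL]:
            for sp in self.species:
                rows.append(
                    (
                        "bulk" if k == BULK_SHELL else k,
                        sp,
                        self.count(k, sp),
                        self.volume(k),
                    )
                )
        return pd.DataFrame(rows, columns=["shell", "species", "CN", "V_shell"])


def shell_census(
    trajectory: Trajectory,
    topology: Topology,
    max_shell: int = 3,
    shell_map: ShellMap | None = None,
    cells_per_frame: list[dict[int, MolecularCell]] | None = None,
    **tess_kwargs,
) -> ShellCensus:
    """Time-averaged shell occupation numbers and shell volumes."""
    if max_shell < 1:
        raise ValueError("max_shell must be >= 1")
    if cells_per_frame is None:
        cells_per_frame = [
            tessellate_frame(f, topology, **tess_kwargs) for f in trajectory
        ]
    if shell_map is None:
        shell_map = shell_map_for(trajectory, topology, cells_per_frame)
    if shell_map.n_frames != len(cells_per_frame):
        raise StructureError("shell map and trajectory frame counts differ")

    species = topology.species_labels
    n_frames = len(cells_per_frame)
    keys = [(k, sp) for k in list(range(1, max_shell + 1)) + [BULK_SHELL]
            for sp in species]
    pf_counts = {key: np.zeros(n_frames) for key in keys}
    pf_vols = {k: np.zeros(n_frames)
               for k in list(range(1, max_shell + 1)) + [BULK_SHELL]}
    solute_vol = np.zeros(n_frames)

    for f, cells in enumerate(cells_per_frame):
        for i, m in enumerate(shell_map.molecule_ids):
            m = int(m)
            k = int(shell_map.shells[f, i])
            if m == topology.solute_id:
                solute_vol[f] += cells[m].volume
                continue
            kk = k if k <= max_shell else BULK_SHELL
            pf_counts[(kk, topology.species_of[m])][f] += 1
            pf_vols[kk][f] += cells[m].volume

    return ShellCensus(
        max_shell=max_shell,
        species=species,
        counts={key: float(v.mean()) for key, v in pf_counts.items()},
        volumes={k: float(v.mean()) for k, v in pf_vols.items()},
        solute_volume=float(solute_vol.mean()),
        box_volume=float(np.mean([f.box.volume for f in trajectory])),
        n_frames=n_frames,
        per_frame_counts=pf_counts,
        per_frame_volumes=pf_vols,
    )
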