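"""Radial distribution functions, shell decomposition, and Kirkwood-Buff
integrals.

Two distance metrics are supported for the solute-solvent pair histogram:

``com_r``
    minimum-image distance between the solute center of mass and the
    solvent-molecule center of mass — the conventional g(r);
``nearest_atom_s``
    distance from the solvent center of mass to the *nearest solute atom*,
    better suited to anisotropic solutes, but still normalized with the
    spherical-shell volume and therefore biased close to an extended
    solute.

Each pair contribution can additionally be routed to the Voronoi shell the
solvent molecule occupies in that frame; the shell components sum back to
the total g(r) bin-exactly because every molecule belongs to exactly one
shell.

Bins are normalized with the exact spherical-shell volume
``4/3·pi·(r_hi^3 - r_lo^3)`` and the whole-box species density
``rho_j = N_j/V_box`` (the solute's excluded volume is deliberately not
corrected for, matching the conventional normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    StructureError,
    Topology,
    Trajectory,
    minimum_image_displacement,
    molecule_centers_of_mass,
)
from .voronoi import BULK_SHELL, ShellMap

__all__ = [
    "RdfCurve",
    "KbResult",
    "FirstMinimum",
    "com_rdf",
    "nearest_atom_rdf",
    "shell_decompose_rdf",
    "cumulative_cn",
    "first_minimum",
    "kb_integral",
    "excess_cn",
]

#: 1 Å^3/molecule = AVOGADRO_CM3 cm^3/mol
ANG3_TO_CM3_MOL = 0.6022140857


@dataclass
class RdfCurve:
    """Binned solute-solvent distribution function.

    ``shell_components[k]`` holds the per-bin g-contribution of Voronoi
    shell ``k`` (``BULK_SHELL`` pools everything beyond the requested
    shells); the components and their integer pair counts sum to the
    totals bin-exactly.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    bulk_density: float
    metric: str
    n_frames: int
    species: str
    shell_components: dict[int, np.ndarray] = field(default_factory=dict)
    shell_pair_counts: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_dataframe(self):
        import pandas as pd

        data = {"r": self.bin_centers, "g_total": self.values}
        for k in sorted(self.shell_components):
            name = "bulk" if k == BULK_SHELL else str(k)
            data[f"g_shell{name}"] = self.shell_components[k]
        return pd.DataFrame(data)


class FirstMinimum(NamedTuple):
    r: float
    ambiguous: bool


@dataclass
class KbResult:
    """Running Kirkwood-Buff integral and coordination numbers.

    ``r`` starts at 0; ``delta_g_running`` is the running integral of
    ``(g-1)·4·pi·r^2`` in Å^3 and ``cn_running`` the cumulative
    coordination number ``rho·∫ g·4·pi·r^2 dr``.
    """

    r: np.ndarray
    delta_g_running: np.ndarray
    cn_running: np.ndarray
    bulk_density: float
    R: float | None = None
    cn_at_R: float | None = None
    ambiguous_R: bool = False

    @property
    def delta_g(self) -> float:
        """KB integral at the largest r (Å^3)."""
        return float(self.delta_g_running[-1])

    @property
    def delta_g_cm3_mol(self) -> float:
        return self.delta_g * ANG3_TO_CM3_MOL


def _bin_edges(bin_width: float, r_max: float) -> np.ndarray:
    n_bins = int(np.ceil(r_max / bin_width))
    return bin_width * np.arange(n_bins + 1)


def _pair_distance_rdf(
    trajectory: Trajectory,
    topology: Topology,
    species: str,
    metric: str,
    bin_width: float,
    r_max: float | None,
    shell_map: ShellMap | None,
    shells: Iterable[int],
) -> RdfCurve:
    solute = topology.solute_id
    mol_ids = topology.molecules_of_species(species)
    if len(mol_ids) == 0:
        raise StructureError(f"no molecules of species {species!r}")
    min_edge = min(f.box.min_edge for f in trajectory)
    if r_max is None:
        r_max = 0.49 * min_edge
    if r_max > 0.5 * min_edge:
        raise ValueError(
            f"r_max = {r_max} Å exceeds half the smallest box edge "
            f"({0.5 * min_edge:.3f} Å); the minimum-image convention would "
            "miss periodic copies"
        )
    if shell_map is not None and shell_map.n_frames != len(trajectory):
        raise StructureError(
            f"shell map covers {shell_map.n_frames} frames, trajectory has "
            f"{len(trajectory)}"
        )
    shells = sorted(set(int(k) for k in shells))

    edges = _bin_edges(bin_width, r_max)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    shell_counts = (
        {k: np.zeros(n_bins, dtype=np.int64) for k in shells + [BULK_SHELL]}
        if shell_map is not None
        else {}
    )
    col = (
        np.searchsorted(shell_map.molecule_ids, mol_ids)
        if shell_map is not None
        else None
    )

    for f_idx, frame in enumerate(trajectory):
        coms = molecule_centers_of_mass(frame, topology)
        row = {int(m): i for i, m in enumerate(topology.molecule_ids)}
        solvent_coms = coms[[row[int(m)] for m in mol_ids]]
        if metric == "com_r":
            ref = coms[row[solute]]
            d = np.linalg.norm(
                minimum_image_displacement(solvent_coms, ref, frame.box), axis=1
            )
        elif metric == "nearest_atom_s":
            solute_atoms = frame.coords[topology.molecules[solute]]
            disp = minimum_image_displacement(
                solvent_coms[:, None, :], solute_atoms[None, :, :], frame.box
            )
            d = np.linalg.norm(disp, axis=2).min(axis=1)
        else:
            raise ValueError(f"unknown metric {metric!r}")

        in_range = d < edges[-1]
        bins = np.floor(d[in_range] / bin_width).astype(np.intp)
        np.add.at(counts, bins, 1)
        if shell_map is not None:
            ks = shell_map.shells[f_idx, col][in_range]
            pooled = np.where(np.isin(ks, shells), ks, BULK_SHELL)
            for k in shell_counts:
                np.add.at(shell_counts[k], bins[pooled == k], 1)

    rho = len(mol_ids) / np.mean([f.box.volume for f in trajectory])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = len(trajectory) * rho * shell_vol
    return RdfCurve(
        bin_edges=edges,
        values=counts / norm,
        pair_counts=counts,
        bulk_density=rho,
        metric=metric,
        n_frames=len(trajectory),
        species=species,
        shell_components={k: c / norm for k, c in shell_counts.items()},
        shell_pair_counts=shell_counts,
    )


def com_rdf(
    trajectory: Trajectory,
    topology: Topology,
    species: str,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RdfCurve:
    """Center-of-mass solute-solvent radial distribution function."""
    return _pair_distance_rdf(
        trajectory, topology, species, "com_r", bin_width, r_max, None, ()
    )


def nearest_atom_rdf(
    trajectory: Trajectory,
    topology: Topology,
    species: str,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RdfCurve:
    """g(s): solvent COM to *nearest solute atom* distance distribution.

    Normalized with the same spherical-shell volume as g(r); close to an
    extended solute part of that volume is excluded by the solute itself,
    so absolute values near contact are biased high by construction.
    """
    return _pair_distance_rdf(
        trajectory, topology, species, "nearest_atom_s", bin_width, r_max, None, ()
    )


def shell_decompose_rdf(
    trajectory: Trajectory,
    topology: Topology,
    species: str,
    shell_map: ShellMap,
    shells: Iterable[int] = (1, 2, 3),
    metric: str = "com_r",
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RdfCurve:
    """g(r) with every pair routed to the solvent molecule's Voronoi shell.

    The requested shells get individual components; all other shells are
    pooled under ``BULK_SHELL``.  Components sum to the total bin-exactly.
    """
    return _pair_distance_rdf(
        trajectory, topology, species, metric, bin_width, r_max, shell_map, shells
    )


def _running_integrals(rdf: RdfCurve):
    """Abscissae (0 + bin centers) and running CN / KB integrands."""
    r = np.concatenate([[0.0], rdf.bin_centers])
    g = np.concatenate([[0.0], rdf.values])
    cn_integrand = rdf.bulk_density * g * 4.0 * np.pi * r**2
    kb_integrand = (g - 1.0) * 4.0 * np.pi * r**2
    cn = cumulative_trapezoid(cn_integrand, r, initial=0.0)
    kb = cumulative_trapezoid(kb_integrand, r, initial=0.0)
    return r, cn, kb


def cumulative_cn(rdf: RdfCurve, R: float) -> float:
    """Cumulative coordination number CN(R) = rho ∫_0^R g·4·pi·r^2 dr."""
    r, cn, _ = _running_integrals(rdf)
    if not (0.0 <= R <= r[-1]):
        raise ValueError(f"R = {R} Å outside the binned range [0, {r[-1]:.3f}]")
    return float(np.interp(R, r, cn))


def kb_integral(rdf: RdfCurve, r_upper: float | None = None) -> KbResult:
    """Running Kirkwood-Buff integral ΔG(r) = ∫ (g-1)·4·pi·r^2 dr.

    The running curve is returned because convergence with r is usually
    poor and should be inspected, not assumed.
    """
    r, cn, kb = _running_integrals(rdf)
    if r_upper is not None:
        if not (0.0 < r_upper <= r[-1]):
            raise ValueError(f"r_upper = {r_upper} Å outside binned range")
        keep = r <= r_upper
        r_cut = np.append(r[keep], r_upper)
        kb = np.append(kb[keep], np.interp(r_upper, r, kb))
        cn = np.append(cn[keep], np.interp(r_upper, r, cn))
        r = r_cut
    return KbResult(
        r=r, delta_g_running=kb, cn_running=cn, bulk_density=rdf.bulk_density
    )


def first_minimum(rdf: RdfCurve, smoothing_window: int = 5) -> FirstMinimum:
    """First local minimum of the smoothed g(r) after its first maximum.

    A centered moving average (``smoothing_window`` bins) suppresses bin
    noise.  When several candidate minima lie within 5% depth of the
    chosen one the result is flagged ambiguous — shell-boundary placement
    by g(r) minima is not unique for structured curves, which is the
    motivation for the parameter-free Voronoi assignment.
    """
    g = rdf.values.astype(float)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.concatenate([np.repeat(g[0], pad), g, np.repeat(g[-1], pad)])
        g = np.convolve(padded, kernel, mode="valid")[: len(rdf.values)]
    centers = rdf.bin_centers

    interior = np.arange(1, len(g) - 1)
    maxima = interior[(g[interior] > g[interior - 1]) & (g[interior] >= g[interior + 1])]
    if len(maxima) == 0:
        raise ValueError("no local maximum: curve has no shell structure")
    first_max = maxima[0]
    after = interior[interior > first_max]
    minima = after[(g[after] < g[after - 1]) & (g[after] <= g[after + 1])]
    if len(minima) == 0:
        raise ValueError("no minimum after the first maximum")
    chosen = minima[0]
    depth = g[chosen]
    scale = max(abs(depth), 1e-12)
    ambiguous = bool(
        np.any(np.abs(g[minima[1:]] - depth) <= 0.05 * scale)
    )
    return FirstMinimum(r=float(centers[chosen]), ambiguous=ambiguous)


def excess_cn(kb: KbResult) -> float:
    """Excess coordination number ΔCN = CN(R) - (4·pi/3)·R^3·rho."""
    if kb.R is None or kb.cn_at_R is None:
        raise ValueError("KbResult carries no shell radius R / CN(R)")
    return float(kb.cn_at_R - 4.0 / 3.0 * np.pi * kb.R**3 * kb.bulk_density)


def kb_analysis(
    rdf: RdfCurve,
    R: float | None = None,
    smoothing_window: int = 5,
    r_upper: float | None = None,
) -> KbResult:
    """Full KB workup: running integrals, shell radius, CN(R).

    ``R`` defaults to the first minimum of g(r); it can be overridden
    manually, mirroring the by-inspection override the ambiguity of the
    first-minimum procedure sometimes requires.
    """
    ambiguous = False
    if R is None:
        fm = first_minimum(rdf, smoothing_window)
        R, ambiguous = fm.r, fm.ambiguous
    result = kb_integral(rdf, r_upper)
    result.R = float(R)
    result.cn_at_R = cumulative_cn(rdf, R)
    result.ambiguous_R = ambiguous
    return result
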