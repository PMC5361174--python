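"""Solute-solvent pair interaction energies (Coulomb + Lennard-Jones).

Energies are direct minimum-image pair sums with a radial cutoff and no
long-range correction: a per-molecule decomposition of the interaction is
only meaningful for a pairwise-decomposable sum, so the real-space
truncated Coulomb form is used rather than a lattice sum.  Combining
rules are Lorentz-Berthelot by default (arithmetic sigma, geometric
epsilon); a geometric-sigma alternative is available.

Only inter-molecular (solute-solvent) pairs are ever summed, so no
intramolecular exclusion bookkeeping is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, StructureError, Topology, Trajectory, minimum_image_displacement
from .voronoi import ShellMap

__all__ = [
    "COULOMB_K",
    "InteractionProfile",
    "pair_coulomb",
    "pair_lj",
    "first_shell_energy_profile",
]

#: Coulomb prefactor e^2/(4·pi·eps0) in kJ·Å/(mol·e^2)
COULOMB_K = 1389.354


def _pair_distances(
    frame: Frame, topology: Topology, mol_a: int, mol_b: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ia = topology.molecules[mol_a]
    ib = topology.molecules[mol_b]
    disp = minimum_image_displacement(
        frame.coords[ia][:, None, :], frame.coords[ib][None, :, :], frame.box
    )
    return ia, ib, np.linalg.norm(disp, axis=2)


def pair_coulomb(
    frame: Frame,
    topology: Topology,
    mol_a: int,
    mol_b: int,
    cutoff: float | None = 14.0,
) -> float:
    """Coulomb energy between two molecules (kJ/mol), minimum image.

    Atom pairs beyond the cutoff are skipped (plain truncation, no shift).
    """
    if mol_a == mol_b:
        raise ValueError("pair energy needs two distinct molecules")
    ia, ib, r = _pair_distances(frame, topology, mol_a, mol_b)
    qq = np.outer(topology.charges[ia], topology.charges[ib])
    mask = r > 0
    if cutoff is not None:
        mask &= r < cutoff
    return float(COULOMB_K * np.sum(qq[mask] / r[mask]))


def pair_lj(
    frame: Frame,
    topology: Topology,
    mol_a: int,
    mol_b: int,
    cutoff: float | None = 14.0,
    combining: str = "lorentz_berthelot",
) -> float:
    """Lennard-Jones energy 4·eps·[(sig/r)^12 - (sig/r)^6] between two
    molecules (kJ/mol), minimum image, truncated without shift."""
    if mol_a == mol_b:
        raise ValueError("pair energy needs two distinct molecules")
    ia, ib, r = _pair_distances(frame, topology, mol_a, mol_b)
    eps = np.sqrt(np.outer(topology.lj_epsilon[ia], topology.lj_epsilon[ib]))
    si = topology.lj_sigma[ia]
    sj = topology.lj_sigma[ib]
    if combining == "lorentz_berthelot":
        sig = 0.5 * (si[:, None] + sj[None, :])
    elif combining == "geometric":
        sig = np.sqrt(np.outer(si, sj))
    else:
        raise ValueError(f"unknown combining rule {combining!r}")
    mask = (r > 0) & (eps > 0)
    if cutoff is not None:
        mask &= r < cutoff
    sr6 = (sig[mask] / r[mask]) ** 6
    return float(np.sum(4.0 * eps[mask] * (sr6**2 - sr6)))


@dataclass
class InteractionProfile:
    """Per-species first-shell interaction statistics (kJ/mol per
    molecule).  ``n_samples`` counts (frame, molecule) events."""

    mean_coulomb: dict[str, float]
    sd_coulomb: dict[str, float]
    mean_vdw: dict[str, float]
    sd_vdw: dict[str, float]
    n_samples: dict[str, int]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "species": sp,
                    "mean_coulomb": self.mean_coulomb[sp],
                    "sd_coulomb": self.sd_coulomb[sp],
                    "mean_vdw": self.mean_vdw[sp],
                    "sd_vdw": self.sd_vdw[sp],
                    "n_samples": self.n_samples[sp],
                }
                for sp in sorted(self.n_samples)
            ]
        )


def first_shell_energy_profile(
    trajectory: Trajectory,
    topology: Topology,
    shell_map: ShellMap,
    cutoff: float | None = 14.0,
    combining: str = "lorentz_berthelot",
) -> InteractionProfile:
    """Average solute interaction of one first-shell molecule, by species.

    For every frame and every molecule in Voronoi shell 1, the
    solute-molecule Coulomb and van-der-Waals energies are accumulated;
    species means are totals over sample counts, i.e. interaction per
    solvent molecule actually at the solute surface.
    """
    if shell_map.n_frames != len(trajectory):
        raise StructureError("shell map and trajectory frame counts differ")
    samples: dict[str, list[tuple[float, float]]] = {}
    solute = topology.solute_id
    for f_idx, frame in enumerate(trajectory):
        assignment = shell_map.shells[f_idx]
        for i, m in enumerate(shell_map.molecule_ids):
            if assignment[i] != 1:
                continue
            m = int(m)
            ec = pair_coulomb(frame, topology, solute, m, cutoff)
            ev = pair_lj(frame, topology, solute, m, cutoff, combining)
            samples.setdefault(topology.species_of[m], []).append((ec, ev))
    if not samples:
        raise StructureError("first shell is empty in every frame")

    mean_c, sd_c, mean_v, sd_v, n = {}, {}, {}, {}, {}
    for sp, vals in samples.items():
        arr = np.asarray(vals)
        mean_c[sp] = float(arr[:, 0].mean())
        mean_v[sp] = float(arr[:, 1].mean())
        sd_c[sp] = float(arr[:, 0].std(ddof=1)) if len(arr) > 1 else 0.0
        sd_v[sp] = float(arr[:, 1].std(ddof=1)) if len(arr) > 1 else 0.0
        n[sp] = len(arr)
    return InteractionProfile(
        mean_coulomb=mean_c, sd_coulomb=sd_c, mean_vdw=mean_v, sd_vdw=sd_v,
        n_samples=n,
    )
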