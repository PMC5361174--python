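"""Geometric hydrogen-bond detection between the solute and the solvent.

A hydrogen bond D-H···A is recorded when the minimum-image H···A distance
is strictly below ``d_max`` (default 2.4 Å) and the angle at the hydrogen
between the bond vector H→D and the connecting vector H→A is strictly
above ``angle_min`` (default 135°), so a perfectly linear bond measures
180°.  Both comparisons are strict; the thresholds follow the common
geometric criterion for strong hydrogen bonds (a looser 2.6 Å distance
criterion finds correspondingly more bonds).

Donor hydrogens are atoms flagged ``is_donor_h`` (they must have a
covalent bond partner recorded in the topology); acceptors are atoms
flagged ``is_acceptor`` — by convention all N and O atoms unless the
topology narrows the set (e.g. to exclude methylated ring nitrogens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, StructureError, Topology, Trajectory, minimum_image_displacement

__all__ = ["HbondCriterion", "Hbond", "HbondCount", "detect_hbonds", "hbond_profile"]


@dataclass(frozen=True)
class HbondCriterion:
    d_max: float = 2.4  # Å, H···A distance, strict upper bound
    angle_min: float = 135.0  # degrees at the hydrogen, strict lower bound

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.angle_min < 180.0):
            raise ValueError("angle_min must lie in (0, 180) degrees")


@dataclass(frozen=True)
class Hbond:
    """One detected bond; atom fields are global atom indices."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # Å, H···A
    angle: float  # degrees at H
    solute_is_donor: bool


def _donor_pairs(topology: Topology, molecule_ids) -> list[tuple[int, int]]:
    """(heavy donor, hydrogen) index pairs for the given molecules."""
    pairs = []
    wanted = set(int(m) for m in np.atleast_1d(molecule_ids))
    for idx, atom in enumerate(topology.atoms):
        if not atom.is_donor_h or atom.molecule_id not in wanted:
            continue
        partners = topology.bond_partners(idx)
        if not partners:
            raise StructureError(
                f"donor hydrogen {atom.atom_id} has no bonded heavy atom"
            )
        pairs.append((partners[0], idx))
    return pairs


def _acceptors(topology: Topology, molecule_ids) -> np.ndarray:
    wanted = set(int(m) for m in np.atleast_1d(molecule_ids))
    return np.array(
        [
            i
            for i, a in enumerate(topology.atoms)
            if a.is_acceptor and a.molecule_id in wanted
        ],
        dtype=np.intp,
    )


def _bonds_between(
    frame: Frame,
    topology: Topology,
    donors: list[tuple[int, int]],
    acceptors: np.ndarray,
    criterion: HbondCriterion,
    solute_is_donor: bool,
) -> list[Hbond]:
    if not donors or len(acceptors) == 0:
        return []
    out = []
    acc_pos = frame.coords[acceptors]
    for d_idx, h_idx in donors:
        h = frame.coords[h_idx]
        to_acc = minimum_image_displacement(acc_pos, h, frame.box)
        dist = np.linalg.norm(to_acc, axis=1)
        close = dist < criterion.d_max
        if not np.any(close):
            continue
        to_d = minimum_image_displacement(frame.coords[d_idx], h, frame.box)
        nd = np.linalg.norm(to_d)
        if nd == 0:
            raise StructureError(f"donor and hydrogen coincide at atom {h_idx}")
        cosang = (to_acc[close] @ to_d) / (dist[close] * nd)
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for a_local, dd, ang in zip(np.flatnonzero(close), dist[close], angles):
            if ang > criterion.angle_min:
                out.append(
                    Hbond(
                        donor=d_idx,
                        hydrogen=h_idx,
                        acceptor=int(acceptors[a_local]),
                        distance=float(dd),
                        angle=float(ang),
                        solute_is_donor=solute_is_donor,
                    )
                )
    return out


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criterion: HbondCriterion = HbondCriterion(),
    species: str | None = None,
) -> list[Hbond]:
    """All solute-solvent hydrogen bonds in one frame, both directions.

    ``species`` restricts the solvent partner; by default every solvent
    molecule is considered.  Solute-as-donor and solute-as-acceptor bonds
    are both returned (distinguished by ``solute_is_donor``).
    """
    solute = topology.solute_id
    if species is None:
        partner_mols = topology.solvent_ids
    else:
        partner_mols = topology.molecules_of_species(species)
        if len(partner_mols) == 0:
            raise StructureError(f"no molecules of species {species!r}")
    bonds = _bonds_between(
        frame,
        topology,
        _donor_pairs(topology, [solute]),
        _acceptors(topology, partner_mols),
        criterion,
        solute_is_donor=True,
    )
    bonds += _bonds_between(
        frame,
        topology,
        _donor_pairs(topology, partner_mols),
        _acceptors(topology, [solute]),
        criterion,
        solute_is_donor=False,
    )
    return bonds


@dataclass
class HbondCount:
    """Per-frame solute H-bond counts for one partner species."""

    species: str
    per_frame_donor: np.ndarray  # solute donates
    per_frame_acceptor: np.ndarray  # solute accepts
    mean_donor: float
    mean_acceptor: float
    mean_total: float
    sd_total: float

    @property
    def per_frame_total(self) -> np.ndarray:
        return self.per_frame_donor + self.per_frame_acceptor


def hbond_profile(
    trajectory: Trajectory,
    topology: Topology,
    criterion: HbondCriterion = HbondCriterion(),
) -> dict[str, HbondCount]:
    """Average solute hydrogen-bond counts per partner species."""
    counts = {
        sp: (np.zeros(len(trajectory)), np.zeros(len(trajectory)))
        for sp in topology.species_labels
    }
    mol_species = {int(m): topology.species_of[int(m)] for m in topology.solvent_ids}
    for f, frame in enumerate(trajectory):
        for bond in detect_hbonds(frame, topology, criterion):
            partner_atom = bond.acceptor if bond.solute_is_donor else bond.hydrogen
            sp = mol_species[int(topology.atom_molecule[partner_atom])]
            counts[sp][0 if bond.solute_is_donor else 1][f] += 1
    out = {}
    for sp, (don, acc) in counts.items():
        tot = don + acc
        out[sp] = HbondCount(
            species=sp,
            per_frame_donor=don,
            per_frame_acceptor=acc,
            mean_donor=float(don.mean()),
            mean_acceptor=float(acc.mean()),
            mean_total=float(tot.mean()),
            sd_total=float(tot.std(ddof=1)) if len(tot) > 1 else 0.0,
        )
    return out
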