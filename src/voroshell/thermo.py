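"""Shell concentrations and per-shell solvation free energies.

From the Voronoi census, the concentration of solvent species j in shell k
is ``c_j(shell) = CN_j(shell) / V(shell)`` with V(shell) the total cell
volume of the shell, and the per-shell solvation free energy is

    ΔA_j(shell) = -R·T · ln( c_j(shell) / c_j(bulk) ),

with the whole-box bulk concentration ``c_j(bulk) = N_j / V_box``.
Negative ΔA means the species is enriched at that shell (preferred
solvation); positive ΔA means depletion (dewetting).  ΔA approaches zero
for distant shells of a homogeneous system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .voronoi import BULK_SHELL, ShellCensus

__all__ = [
    "R_GAS_KJ",
    "ANG3_INV_TO_MOL_L",
    "ShellThermo",
    "shell_concentration",
    "bulk_concentration",
    "solvation_free_energy",
]

R_GAS_KJ = 8.31446e-3  # kJ/(mol K)
#: 1 molecule/Å^3 in mol/L (1e27 Å^3/L divided by Avogadro's number)
ANG3_INV_TO_MOL_L = 1660.5390672


@dataclass
class ShellThermo:
    """Concentration and solvation free energy of one species in one shell.

    Concentrations are in molecules/Å^3 (``*_mol_l`` properties convert to
    mol/L); ΔA is in kJ/mol at temperature T.  An empty shell carries
    ``delta_a = +inf`` (infinitely unfavourable) together with the zero
    count so the caller can see how starved the estimate is.
    """

    species: str
    shell: int
    cn: float
    v_shell: float
    c_shell: float
    c_bulk: float
    delta_a: float
    T: float

    @property
    def c_shell_mol_l(self) -> float:
        return self.c_shell * ANG3_INV_TO_MOL_L

    @property
    def c_bulk_mol_l(self) -> float:
        return self.c_bulk * ANG3_INV_TO_MOL_L


def shell_concentration(
    census: ShellCensus,
    species: str,
    shell: int,
    estimator: str = "ratio_of_means",
) -> float:
    """Concentration of a species in a Voronoi shell (molecules/Å^3).

    ``ratio_of_means`` (default) divides the time-averaged count by the
    time-averaged shell volume — stabler for sparse species than the
    ``mean_of_ratios`` alternative, which averages per-frame ratios.
    """
    if species not in census.species:
        raise ValueError(f"species {species!r} not in census {census.species}")
    if estimator == "ratio_of_means":
        v = census.volume(shell)
        if v <= 0:
            raise ValueError(f"shell {shell} has zero volume")
        return census.count(shell, species) / v
    if estimator == "mean_of_ratios":
        counts = census.per_frame_counts[(shell, species)]
        vols = census.per_frame_volumes[shell]
        if np.any(vols <= 0):
            raise ValueError(f"shell {shell} has zero volume in some frame")
        return float(np.mean(counts / vols))
    raise ValueError(f"unknown estimator {estimator!r}")


def bulk_concentration(census: ShellCensus, species: str) -> float:
    """Whole-box density of the species, molecules/Å^3."""
    shells = list(range(1, census.max_shell + 1)) + [BULK_SHELL]
    n_total = sum(census.count(k, species) for k in shells)
    return n_total / census.box_volume


def solvation_free_energy(
    census: ShellCensus,
    T: float = 300.0,
    species: str | None = None,
    shells: list[int] | None = None,
    estimator: str = "ratio_of_means",
) -> list[ShellThermo]:
    """Per-shell solvation free energies ΔA_j(shell) at temperature T."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    species_list = [species] if species is not None else census.species
    if shells is None:
        shells = list(range(1, census.max_shell + 1))
    out = []
    for sp in species_list:
        c_bulk = bulk_concentration(census, sp)
        if c_bulk <= 0:
            raise ValueError(f"species {sp!r} has zero bulk concentration")
        for k in shells:
            c_shell = shell_concentration(census, sp, k, estimator)
            delta_a = (
                math.inf if c_shell == 0 else -R_GAS_KJ * T * math.log(c_shell / c_bulk)
            )
            out.append(
                ShellThermo(
                    species=sp,
                    shell=k,
                    cn=census.count(k, sp),
                    v_shell=census.volume(k),
                    c_shell=c_shell,
                    c_bulk=c_bulk,
                    delta_a=delta_a,
                    T=T,
                )
            )
    return out


def thermo_dataframe(rows: list[ShellThermo]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species": r.species,
                "shell": r.shell,
                "CN": r.cn,
                "V_shell": r.v_shell,
                "c_shell_mol_l": r.c_shell_mol_l,
                "c_bulk_mol_l": r.c_bulk_mol_l,
                "delta_A_kJ_mol": r.delta_a,
                "T": r.T,
            }
            for r in rows
        ]
    )
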