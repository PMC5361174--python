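# voroshell

Parameter-free solvation-shell analysis of molecular-dynamics
trajectories by periodic Voronoi tessellation: shell-resolved radial
distribution functions, Kirkwood–Buff coordination and free-energy
observables, residence kinetics, hydrogen bonding, and per-shell
interaction energetics.

## The problem

The classical route to solvation structure integrates the radial
distribution function g_ij(r) over spherical shells around the solute's
center of mass: the coordination number is

    CN_j = ρ_j ∫₀ᴿ g_ij(r) · 4πr² dr,

with the shell radius R taken from the first minimum of g_ij(r), and the
Kirkwood–Buff integral ΔG_ij = ∫ [g_ij(r) − 1]·4πr² dr links that
structure to thermodynamic affinities (the excess coordination number is
ΔCN_j = CN_j − (4π/3)R³ρ_j).  For an *anisotropic* solute — a flat
aromatic, an elongated molecule — this construction mixes solvation
shells: at a given r the spherical shell contains first-, second- and
even third-shell molecules, R itself is ambiguous when g(r) has several
shallow minima, and the inferred CN can be badly wrong.

`voroshell` instead decomposes all of space into Voronoi cells (each
cell holds the points closer to its molecule, via its atoms, than to any
other molecule).  Molecules whose cells share a face with the solute's
cell form the first solvation shell; neighbors of those form the second
shell, and so on — a parameter-free assignment that needs no radius and
respects the solute's shape.  On top of the shell map the package
computes:

* **Shell-decomposed g(r)** — every solute–solvent pair contribution is
  routed to the solvent molecule's current Voronoi shell; the components
  sum back to the total g(r) bin-exactly.  A nearest-solute-atom
  distance variant g(s) is also provided.
* **Per-shell concentrations and solvation free energies** — each shell
  has a well-defined volume (the summed cell volumes), so
  c_j(shell) = CN_j(shell)/V(shell) and
  ΔA_j(shell) = −RT·ln[c_j(shell)/c_j(bulk)]; negative values mean
  preferred solvation, positive values dewetting.
* **Residence kinetics** — the binary shell-membership function n_j(t)
  of each molecule, its multiple-time-origin autocorrelation (whose t=0
  value *is* the shell coordination number), and a bi-exponential fit
  whose amplitude-weighted relaxation time is the mean residence time.
* **First-shell energetics** — per-molecule Coulomb and Lennard-Jones
  interaction of each first-shell solvent molecule with the solute
  (minimum image, truncated at a configurable cutoff,
  Lorentz–Berthelot combining).
* **Hydrogen bonds** — geometric criterion: H···acceptor distance
  < 2.4 Å and donor–H···acceptor angle at the hydrogen > 135°, both
  strict; counted per partner species, solute-as-donor and
  solute-as-acceptor separately.

Periodicity is handled by 26-image ghost replication of the atomic
sites (restricted to a boundary margin and automatically escalated until
the cell volumes reproduce the box volume to 10⁻⁶ relative — an exact
self-check of the tessellation).

A synthetic-configuration module generates solute-in-binary-solvent
fixtures with analytic ground truth (ideal gas, SC/FCC lattices,
enrichment-biased shells, two-state exchange dynamics, planar solutes),
so the entire chain is testable without any MD data.

## Worked example

A solute whose first shell is enriched threefold in species A by
construction, analyzed blind:

```python
from voroshell import (SyntheticSpec, generate, shell_census,
                       solvation_free_energy)

spec = SyntheticSpec(kind="enriched_shell", n_molecules=500,
                     n_frames=100, enrichment_factor=3.0,
                     well_radius=9.0, seed=7)
trajectory, topology, truth = generate(spec)

census = shell_census(trajectory, topology, max_shell=3)
for row in solvation_free_energy(census, T=300.0):
    print(f"{row.species}  shell {row.shell}:  CN = {row.cn:5.2f}   "
          f"c = {row.c_shell_mol_l:6.2f} M   dA = {row.delta_a:+.2f} kJ/mol")
```

prints

```
A  shell 1:  CN = 11.02   c =  79.36 M   dA = -2.62 kJ/mol
A  shell 2:  CN = 49.64   c =  72.50 M   dA = -2.40 kJ/mol
A  shell 3:  CN = 94.21   c =  41.02 M   dA = -0.98 kJ/mol
B  shell 1:  CN =  3.65   c =  26.28 M   dA = +0.12 kJ/mol
B  shell 2:  CN = 17.00   c =  24.83 M   dA = +0.27 kJ/mol
B  shell 3:  CN = 56.69   c =  24.68 M   dA = +0.28 kJ/mol
```

The enriched species reads ΔA(shell 1) = −2.62 kJ/mol against the
imposed −RT·ln 3 = −2.74 kJ/mol (the residual gap is the intrinsic
cell-size selection bias of Voronoi shells on structureless solvents —
see `docs/methods.md`), the enrichment decays towards zero with shell
index, and the unbiased species B stays near zero.  The well extends
past shell 1, which is why shell 2 also reads enriched here.

## Command line

```
voroshell synth --kind ideal_gas --n-molecules 500 --n-frames 100 -o fix/
voroshell all -t fix/trajectory.xyz -p fix/topology.yaml -o analysis/
```

Subcommands `shells`, `rdf`, `thermo`, `residence`, `energy`, `hbonds`,
`synth` and `all` write figure-ready CSV files plus a JSON manifest
(inputs, parameters, version, wall time) for provenance.  Trajectories
are read from an XYZ dialect carrying the box on the comment line, GRO
(nm converted to Å), or PDB (CRYST1); the topology — species, masses,
partial charges, Lennard-Jones parameters, donor/acceptor flags,
bonds — is one YAML file.

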