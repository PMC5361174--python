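# Methods

## Shell assignment by periodic Voronoi tessellation

Every atomic coordinate is a Voronoi site.  Sites are replicated into
the 26 periodic neighbor images — in practice only the copies within a
margin of the box boundary, starting at 0.3× the smallest edge and
escalating to full replication if needed — and the tessellation of the
combined set is computed with Qhull.  Cells of primary-image sites are
kept; a cell's volume is assembled from its faces as a sum of pyramids
(apex at the site, base on the face, height half the site–neighbor
distance), which is exact for Voronoi cells.  The identity
Σ cell volumes = box volume is checked every frame at 10⁻⁶ relative
tolerance; a violation (or an unbounded primary cell) triggers the next
escalation stage, so a too-narrow ghost margin can never silently
corrupt a result.  Exactly degenerate site sets (perfect lattices are
cospherical) additionally get a deterministic jitter of 10⁻⁸ Å from a
fixed seed, far below any physical length.

Atomic cells are merged per molecule: molecular volume is the summed
atomic volume, molecular neighbors the union of atomic face neighbors in
other molecules.  This implements "closer to the reference molecule" as
closest-atom distance — the natural reading for extended molecules.  The
plain (unweighted) tessellation is used; atomic radii play no role.
Hydrogens are sites by default (`heavy_atoms_only` disables them for
sensitivity checks).

Face areas are computed per unordered molecule pair and symmetrized
(the two per-direction sums agree to roundoff); pairs with a shared area
below `min_face_area` (default 10⁻⁶ Å²) are not considered neighbors.
The threshold exists for exactly one reason: jittered degenerate
lattices produce spurious faces of numerically-zero area between cells
that only touch along an edge or vertex (simple-cubic cells touch 12
edge neighbors; their true shared face area is zero), and filtering at a
level ~10 orders of magnitude below any physical contact face removes
them without affecting disordered systems.

Shell indices are breadth-first distances from the solute on the
molecular neighbor graph: the solute is shell 0, its face-sharing
neighbors shell 1, their neighbors shell 2, and so on.  Because the
tessellation partitions space, every molecule receives exactly one
shell.

## Distribution functions and Kirkwood–Buff observables

The solute–solvent pair histogram supports two metrics: center-of-mass
distance r (minimum image; centers of mass are mass-weighted after
minimum-image reconstruction of each molecule from its first atom) and
the nearest-solute-atom distance s.  Bins (default width 0.1 Å, default
range 0.49× the smallest box edge — the minimum-image validity limit)
are normalized with the exact spherical-shell volume
(4π/3)(r₊³ − r₋³) and the whole-box species density ρ_j = N_j/V_box; the
solute's excluded volume is deliberately not corrected for, matching the
conventional normalization.  For g(s) the same spherical normalization
is applied and documented as biased near an extended solute, where part
of the nominal shell volume is occupied by the solute itself.

Shell decomposition routes each pair to the solvent molecule's Voronoi
shell in that frame; requested shells get individual components and
everything else is pooled, so the per-bin integer pair counts of the
components sum to the total exactly.

Coordination numbers CN(R) = ρ_j ∫₀ᴿ g·4πr² dr and running
Kirkwood–Buff integrals ∫ (g−1)·4πr² dr use trapezoidal quadrature on
{0} ∪ bin centers; CN at an off-grid R is linearly interpolated from the
cumulative curve.  The shell radius R defaults to the first strict local
minimum after the first maximum of the moving-average-smoothed curve
(window 5 bins); when other minima lie within 5% depth of the chosen one
the result carries an ambiguity flag, and R can always be overridden
manually — the ambiguity is intrinsic to the spherical construction and
is one motivation for the Voronoi route.

## Shell thermodynamics

c_j(shell) = CN_j(shell)/V(shell) from the time-averaged census
(ratio of means by default — stabler for sparse species than averaging
per-frame ratios, which is available as an option), c_j(bulk) =
N_j/V_box, and

    ΔA_j(shell) = −R·T · ln[c_j(shell) / c_j(bulk)],

with R = 8.31446 J/(mol·K) and T defaulting to 300 K.  An empty shell
reports +∞ with its zero count attached.  Unit conversions: 1 Å⁻³ =
1660.54 mol/L; 1 Å³ = 0.602 cm³/mol.

**Known estimator bias.**  On a *structureless* solvent (ideal-gas
positions) the first-shell concentration reads systematically ~5–6% low,
i.e. ΔA(shell 1) ≈ +0.15 kJ/mol instead of 0 at 300 K, decaying with
shell index.  This is stochastic geometry, not a defect of the code:
cells adjacent to the solute's cell are a face-count-weighted sample of
the cell population, and many-faced cells are systematically larger than
the typical cell, so the shell volume is inflated relative to its
occupancy.  The effect was confirmed with an independent oracle
(Delaunay adjacency plus Monte-Carlo nearest-site volumes) and is
maximal for a Poisson point pattern, whose cell-volume dispersion is
extreme; in dense liquids, where excluded volume makes cell volumes
nearly uniform, the bias largely vanishes — consistent with ΔA ≈ 0
readings for pure water around hydrophobic solutes.  Consequences for
synthetic validation: ideal-gas ΔA recoveries carry a +0.1 to +0.17
kJ/mol offset and an imposed 3× enrichment reads ≈ −2.6 rather than
−2.74 kJ/mol.  Tests assert the idealized zero-bias expectations at
their stated tolerances and the two sub-assertions that fall inside the
bias band fail honestly; treat ΔA differences of this magnitude on
dilute systems as method noise.

## Residence kinetics

n_i(t) ∈ {0, 1} marks molecule i's membership of the requested shell
(first by default).  The correlation C(t) = ⟨Σ_i n_i(t₀)n_i(t₀+t)⟩ uses
every frame as a time origin (lag k averaged over its T−k origins,
computed by FFT); C(0) equals the time-averaged shell coordination
number by construction, an identity tested at 10⁻⁹ relative.  The raw
intermittent definition is used — a molecule that leaves and re-enters
contributes nothing while absent, with no grace window (an optional
`absence_tolerance` in frames closes short gaps for sensitivity
analysis).  No box-exit exclusion is applied: with ghost-image
tessellation a molecule's shell assignment is well defined wherever it
has diffused, so the wrap-around artifact such exclusions guard against
cannot occur.

The normalized curve is fit with

    (1 − c) · [a·exp(−t/τ₁) + (1 − a)·exp(−t/τ₂)] + c ,

where c is the finite-system re-entry plateau, pinned to CN(0)/M for M
molecules of the species (exact for exchangeable molecules).  Pinning
matters: estimating the plateau from per-molecule mean occupancies is
biased high by the sampling variance of those means (which biases the
fitted time low), while fitting c freely is near-degenerate with a
small-amplitude slow exponential at the τ bound (which can inflate the
amplitude-weighted time severalfold on noisy tails).  For production-scale
systems (thousands of molecules, first-shell CN a few tens) c ≲ 0.005
and the model reduces to the plain constrained bi-exponential.  The
mean residence time is (a₁τ₁ + a₂τ₂)/(a₁ + a₂); initial guesses are τ₁
from the 1/e crossing, τ₂ = 10τ₁, equal amplitudes; bounds a ∈ [0,1],
τ ∈ (0, 100·max_lag].

## Energetics and hydrogen bonds

Solute–solvent pair energies are direct minimum-image sums:
Coulomb k_e·q_iq_j/r with k_e = 1389.354 kJ·Å/(mol·e²) and
Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combining
(geometric-σ optional), truncated without shift at 14 Å by default (the
common simulation cutoff).  A lattice-sum treatment of electrostatics is
deliberately not used: a per-solvent-molecule decomposition of the
solute interaction is only meaningful for a pairwise-decomposable sum,
so the numbers are the real-space truncated interaction and should be
read comparatively, not as absolute solvation energies.  First-shell
profiles average over every (frame, shell-1 molecule) event and report
per-species means, standard deviations and sample counts.

Hydrogen bonds use the geometric criterion d(H···A) < 2.4 Å *and*
∠(D–H···A) > 135° measured at the hydrogen (linear = 180°), both strict
inequalities; loosening either threshold can only add bonds, a
monotonicity that is property-tested.  Acceptors default to all N and O
atoms and are overridable per atom in the topology (e.g. to exclude
methylated ring nitrogens).  Detection is brute-force over donor–
acceptor pairs (no cell list): solute-centric counting is linear in
system size and far from being a bottleneck.

## Synthetic systems: what they do and do not show

The generators draw from a counter-based stream keyed by (seed, frame),
so any frame is generatable independently and runs are byte-reproducible.
Defaults place molecules at a liquid-water-like number density of
0.0334 Å⁻³ so shells and cells have physical dimensions; frame spacing
defaults to 0.1 ps.

* *Ideal gas*: i.i.d. uniform positions, species by exact
  largest-remainder apportionment of the requested fractions.  Flat
  g(r); homogeneous ΔA up to the estimator bias above.
* *Lattices*: simple-cubic (6/18 first/second-shell neighbors, cubic
  cells of exactly a³) and fcc (12 first-shell neighbors) — exact
  integer ground truths for adjacency and volumes.
* *Enriched shell*: central solute; each molecule of the enriched
  species falls inside a well of radius 9 Å (≈3× the mean spacing, so
  the well provably contains the whole first shell) with probability
  f·V_well/V_box and is uniform within its zone.  This allocation makes
  the imposed well-vs-whole-box concentration ratio exactly f for any
  well size — the analytic target for the ΔA recovery.
* *Exchange dynamics*: independent two-state Markov chains between an
  inner ball (shell 1 by construction; the ground-truth shell map is
  returned, so residence analysis needs no tessellation here) and a
  reservoir, parameterized by relaxation rate k and stationary occupancy
  p; the normalized correlation is p + (1−p)e^(−kt) exactly, and the
  mean residence time 1/k.  Recovery runs use 500 solvent molecules,
  4000 frames at 0.1 ps and a 40 ps fit window — sizes at which the fit
  was verified stable across seeds.
* *Planar solute*: a rigid 4×4 plate (1.4 Å spacing) with a contact
  layer at a nearest-atom distance of 3.0 ± 0.3 Å plus a uniform
  background beyond 4.5 Å.  The structured layer gives the anisotropic
  solute a genuine first shell and the g(r) a first minimum, so the
  spherical-cutoff procedure can be applied and shown to fail: its CN at
  the first minimum differs from the Voronoi first-shell CN by ~90% on
  this fixture, and most first-shell pairs lie beyond the minimum.

These fixtures have no interactions, no molecular shape (except the
plate) and no correlated dynamics; passing their tests validates the
*analysis machinery* — tessellation geometry, counting identities,
estimator algebra, fit recovery — not force-field physics or sampling
quality of real trajectories.

## Problem sizes and costs

Validation runs use 100–500 molecules and 30–150 frames for tessellation
chains (a 500-molecule frame tessellates in ~0.1 s) and up to 500
molecules × 4000 frames for the FFT-based residence pipeline; the full
test suite and the acceptance script each finish in a few minutes on one
CPU.

## Limitations

Orthorhombic boxes only; no radical (radius-weighted) tessellation; no
Ewald electrostatics; no finite-size Kirkwood–Buff corrections; no
continuous (grace-windowed) residence definition beyond the absence
tolerance; single solute per system by design.  The shell-concentration
bias on dilute/structureless systems is documented above and is a
property of the method itself.
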