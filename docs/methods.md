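# Methods

This note documents the models implemented in `ciukit`, the assumptions they
make, the defaults they ship with, and what the synthetic fixtures do and do
not demonstrate.

## Ionizable-site model

A protein ion's charge lives on a discrete set of ionizable sites: the
N-terminus, lysine, arginine and histidine (basic; +1 when protonated, 0
otherwise), and the C-terminus, aspartate and glutamate (acidic; 0 when
protonated, −1 when deprotonated). Each site is represented by a single
anchor atom carrying the point charge: Lys NZ, Arg CZ, His NE2, Asp CG,
Glu CD, the backbone N of the first residue and the carbonyl C of the last
residue of each chain. Protonation is pure bookkeeping on these sites —
explicit hydrogens are never required or placed — so structures with or
without hydrogens are treated identically. Histidine is always listed as a
chargeable site; callers who want it neutral can remove it from the basicity
table or post-filter the site list.

Altloc handling keeps the highest-occupancy conformer; insertion codes are
appended to the residue-number key; deposited residue numbering is preserved.

## Mobile-proton energy functional

The energy of a protonation state is

E(state) = − Σ_{protonated basic sites} B(kind)
         + Σ_{i<j} k_e · q_i q_j / (ε_r · max(r_ij, r_min))

with B the intrinsic basicity (kJ/mol), k_e = 1389.35 kJ·mol⁻¹·Å·e⁻²,
ε_r = 1 (vacuum) and r_min = 1 Å guarding degenerate geometries. The default
basicity table follows the gas-phase-basicity ordering
Arg (1006.6) > His (950.2) > Lys (918.0) > N-terminal amine (886.6) kJ/mol
and is an ordinary editable input, not a constant of the method.

Two deliberate simplifications. First, acidic deprotonation carries no
intrinsic term, so the functional favours zwitterionic salt-bridge pairs
whenever a basic site can absorb the extra proton — the global minimum at
low net charge is typically not the all-neutral state. This matches the
design intent (charge placement driven by basicity competition and Coulomb
repulsion) but means absolute energies should not be read as gas-phase
thermochemistry. Second, Coulomb screening is a single scalar ε_r; there is
no distance-dependent dielectric.

### Assignment search

`assign_protons` is a random-restart steepest descent over z-preserving
single-proton moves: relocate a proton between basic sites, relocate the
charge hole between acidic sites, or toggle an acid/base pair in either
direction. Restarts (20 by default) are stratified across every feasible
(protonated-basic, deprotonated-acidic) partition of the net charge, and
when no single move improves, a two-move lookahead steps through the best
uphill intermediates before giving up. Ties are always broken by the
lexicographically smallest state vector, so a fixed seed gives bit-identical
output. `brute_force_assign` enumerates all states (bounded at 20 sites) and
is the oracle the search is validated against; the suite checks energy
equality on randomized mixed-site systems.

### Trajectory reassignment and schedules

Protons are redistributed every 20 ps of simulated time (the rearrangement
period), each frame independently of the last — reassignment is memoryless,
the simplest contract consistent with periodic redistribution; no hysteresis
is modelled. All frames share one derived seed, so identical geometries give
identical configurations. `thermal_schedule` builds stepped heating ramps
(default use: 300 K start, +50 K every 4 ns, 20 ns total, CCS every 2 ps);
`coulombic_schedule` is a single steady segment (300 K, 100 ns, CCS every
10 ps).

## Projection-approximation CCS

The PA CCS is the orientation-averaged projected area of the union of atom
spheres with radius r_element + r_probe. Element radii default to H 1.2,
C 1.7, N 1.55, O 1.52, S/P 1.8 Å (user-replaceable); probe radii default to
1.0 Å (helium) or 1.6 Å (N₂). The estimator draws uniformly random rotations
(normalized 4-normal quaternions), and for each rotation estimates the
union-of-disks area by hit-or-miss sampling over the projected bounding box.
Each rotation's area is unbiased, so the mean is an unbiased orientation
average; the standard error is the between-rotation sample standard
deviation over √n_rotations, which automatically includes the within-rotation
sampling noise. Defaults are 300 rotations × 3000 samples for single
conformers; validation of the 3·SE coverage statement uses 200 rotations so
the estimated SE is itself accurate. `grid_reference_ccs` is a deterministic
cross-check (golden-spiral direction lattice, pixel quadrature) used only as
a reference.

PA ignores multiple scattering and long-range interactions and therefore
underestimates trajectory-method CCS for extended ions; `scale_factor`
(default 1.0, applied multiplicatively and recorded in the result) lets
users apply an empirical PA→TM correction. Trajectory smoothing is a
centered moving mean with shrinking windows at the edges (window odd,
length-preserving), applied once or repeatedly.

## TWIMS calibration

Calibration follows the standard corrected-time power-law protocol:
t′ = t − C·√(m/z)/1000 (C, the EDC delay coefficient, is always user input),
Ω′ = Ω_lit/(z·√(1/m + 1/m_gas)), then a least-squares line on
(ln t′, ln Ω′) yields exponent x and scale A, with R² and residuals kept as
diagnostics. Unknowns are read back as Ω = A·t′^x·z·√(1/m + 1/m_gas). The
reduced-mass term uses the reference-gas mass (He, 4.0026 Da) on both sides
so the fit/apply round trip is exact and N₂-measured, He-calibrated values
stay on the He scale; the drift-gas mass (N₂, 28.0134 Da) is recorded for
provenance. Applying the model outside the fitted t′ range warns rather than
fails.

Distribution summaries use the intensity-weighted mean and standard
deviation, IWM = ΣI·t/ΣI and IWSD = √(ΣI·(t−IWM)²/ΣI). The population form
(divide by ΣI, no n−1 analogue) is used; for the smooth, many-point
distributions these metrics are meant for, the distinction is negligible.
The axis may equally be arrival time (ms) or CCS (Å²); the unit is recorded.

## Ensemble analysis

Salt bridges: a contact is scored per (acidic, basic) residue pair when the
minimum O–N distance is ≤ 4.0 Å (inclusive). Oxygen sets: Asp OD1/OD2,
Glu OE1/OE2, C-terminal O/OXT; nitrogen sets: Lys NZ, Arg NE/NH1/NH2,
His ND1/NE2, N-terminal N. Pairs are reported once, oriented acidic→basic;
same-residue pairs (terminal residues that are themselves ionizable) are
skipped.

Theoretical CCS distributions are Gaussian KDEs with Silverman bandwidth
(floor 1 Å² for degenerate samples) on a 512-point grid spanning
[min − 3h, max + 3h], renormalized on the grid so the trapezoid integral is
exactly 1 (an unrenormalized ±3h window would clip ≈0.3% of the mass).
Distribution agreement is quantified by the overlapping coefficient
∫min(p, q) after resampling both densities onto a common grid — symmetric,
in [0, 1], 1 only for coincident distributions.

Superposition is the Kabsch SVD solution restricted to proper rotations,
computed on Cα atoms (all atoms when no Cα exists). Conformer families come
from average-linkage hierarchical clustering of the pairwise superposed-RMSD
matrix cut at a user cutoff; labels are ordered by family size then first
member. This is a declared stand-in for published-tool cluster analyses
whose parameters are not public, not a reproduction of any of them. The
compact/extended dividing value for counting unfolded outcomes defaults to
1100 Å² and is exposed as a parameter.

## Synthetic fixtures

Peptides are built by NeRF chain extension from idealized backbone internal
coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329 Å; ω = 180°) with presets
extended (−135°, 135°) and helical (−57°, −47°); the helical preset
reproduces the ~1.5 Å/residue rise. Side chains are minimal: only CB plus
the anchor and salt-bridge atoms, laid on an idealized extended axis.
Unfolding ensembles interpolate per-residue dihedrals from a seeded
compact basin (jittered helical) toward extended, with optional Gaussian
dihedral noise; at zero noise the compact start is re-jittered
deterministically until the radius of gyration is non-decreasing along the
series, so "ordered compact → extended" holds by construction.

The default test sequence is a 56-residue NTL9-like construct: the
lysine-rich loop KDVKGKGKK (placed at residues 7–15) and the C-terminal
KQKEQR tail embedded in poly-alanine linkers.

What the fixtures do **not** emulate: force-field energetics, side-chain
packing, steric self-avoidance of noisy conformers, solvent history, or
instrument peak shapes beyond Gaussian mixtures. Green tests therefore
demonstrate that the algorithms are implemented correctly and behave with
the right trends and invariants — not that any particular real protein's
CCS values are reproduced.

## Demo pipeline and problem sizes

`demo_pipeline` runs, for each charge state z = +4…+8, an 8-conformer
ensemble drawn from a ±0.08 window of the compact→extended interpolation
centred further toward extension the higher z; assigns z protons per
conformer; computes each conformer's PA CCS (80 rotations × 1200 samples);
builds the KDE CCSD; and tabulates salt bridges of the most extended frame.
These sizes keep a full run under a minute on one core while leaving the
charge-vs-CCS trend far above the Monte-Carlo noise (steps of ~100 Å²
against per-ensemble standard errors of a few Å²). All randomness derives
from a single seed; reports are byte-identical across runs with equal seeds.

## Known limitations

- The energy functional's missing deprotonation penalty (above) makes
  low-charge minima zwitterion-rich; interpret configurations, not energies.
- PA CCS has no trajectory-method physics; extended-ion values are
  systematically low without a user-supplied scale factor.
- The stochastic assignment search is oracle-exact on every enumerable
  system exercised, but global optimality is not guaranteed in general;
  site counts in the hundreds may need more restarts.
- XYZ input carries no topology, so ionizable-site discovery and salt-bridge
  detection need PDB input.
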