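# Methods

`tgsite` re-implements, as a reusable library, the post-simulation analysis
used to ask whether perfluoroalkyl substances (PFAS) bound at hormonogenic
Site B of human thyroglobulin (hTG) perturb the geometry and interaction
network that thyroid-hormone synthesis depends on. The package analyses
trajectories; it does not run molecular dynamics, docking, or charge
derivation, and it implements only the generalized-Born (GB) arm of the
end-point energetics (no Poisson–Boltzmann solver).

## Frame selection

Production analyses use the final portion of a simulation once RMSD and
energy have plateaued. `select_frames(trajectory, window_ns, stride)` keeps
frames with time strictly greater than `end − window` (half-open, so the
boundary frame is not double-counted), then every `stride`-th of those.
A window covering the whole run keeps every frame, making the whole-run
selection an identity. Plain multi-MODEL PDB carries no time metadata, so
trajectories read from PDB are assigned a configurable uniform frame
spacing, default 1 ps — the spacing under which a 20 ns run analysed over
its last 5 ns at stride 10 yields exactly 500 frames. The 1 ps default is
an inference from that arithmetic, not a measured fact about any given
input; override `frame_spacing_ps` when the true write frequency differs.

## Orientation of the hormonogenic tyrosines

Hormone (T4) synthesis requires the donor and acceptor diiodotyrosine (ITY)
side chains to be close to the arrangement seen in the cryo-EM structure:
inter-plane angle ≈ 76° and donor-oxygen to acceptor-carbon distance
≈ 6.4 Å. Per frame the package computes:

- **Ring-plane normal** — the normalized cross product of the two vectors
  from the CG atom to the two ring iodines. Iodines are taken in atom-name
  sort order: swapping them flips the normal and maps θ to 180° − θ, so a
  fixed order is required for reproducibility.
- **Inter-plane angle** — arccos of the clamped dot product of unit
  normals, kept on [0°, 180°] (not folded to [0°, 90°]; orientations near
  170° are physically distinct from those near 10°).
- **Reactive-atom distance** — Euclidean distance between the donor
  hydroxyl oxygen (`OH`) and the acceptor ring carbon bearing the hydroxyl
  (`CZ`). The literature names only "the oxygen" and "the carbon"; the
  default atom choice is therefore configurable and the reference distance
  carries a ±0.3 Å ambiguity from it.
- **Side-chain center-of-mass distance** — mass-weighted centroids with
  backbone atoms (N, CA, C, O and their hydrogens) excluded.

Distributions are reported as normalized 2-D histograms (default bins
2° × 0.25 Å, smooth at ~500 frames); `fraction_near_reference` measures how
often the site visits a coupling-competent geometry. Orientation clustering
uses DBSCAN on raw (angle°, distance Å) points without rescaling — the
radius eps = 2 is interpreted in those mixed units, with min_samples = 6;
an average-linkage hierarchical alternative cut at distance 3.0 is provided
but DBSCAN is the default. A cluster's representative frame is the record
nearest its centroid.

## Hydrogen-bond occupancy and network comparison

Donors are N/O/S atoms with a bonded hydrogen; with no bond table (common
for PDB), a hydrogen within 1.2 Å of its nearest N/O/S is considered
bonded. Acceptors are N/O/S and, by default, fluorine, because
perfluorinated tails participate in the contact analysis (disable with a
flag). An event requires heavy-atom distance ≤ 3.0 Å and D–H···A angle
≥ 135° — stated explicitly because "default parameters" of analysis tools
are version-dependent. Intra-residue pairs are excluded.

Occupancy is reported per residue pair as the percentage of frames with at
least one event through any atom pair, matching residue-pair-level
reporting; tables are sorted by descending occupancy with index-pair
tie-breaks. Regions (disjoint residue sets tagged loop/helix) let
`count_region_interactions` and `compare_networks` express the rigidity
analysis: extra persistent bonds inside a helix region upon ligand binding
mean a stiffer helix–loop–helix element. The default region map ships only
the helix segment S2534…ITY2540 (the other regions are defined by a figure
not reproducible here) and is user-overridable via YAML.

## Energetics

**Nonbonded pairwise terms.** Coulomb with k_C = 332.0636 kcal·Å/(mol·e²)
and interior dielectric ε_in = 1; 12-6 Lennard-Jones in r_min/ε form with
Lorentz–Berthelot-style combining (r_min,ij = r_min,i/2 + r_min,j/2,
ε_ij = √(ε_i ε_j)); no cutoff within selected pairs; distances below 0.1 Å
are treated as clashes and raise.

**Per-residue decomposition** averages the ligand–residue gas-phase
elec+vdW cross terms over frames for residues within 10 Å of the ligand in
any analysed frame (union rule; the frame rule is not specified in the
literature). Decomposition here is deliberately gas-phase nonbonded only —
per-residue GB attribution is not included. Group sums aggregate totals as
charged (basic+acidic) versus polar+nonpolar; hormonogenic ITY residues are
reported separately and excluded from both groups, since their contribution
is discussed separately from the four polarity classes.

**GB-OBC.** Intrinsic radii come from the parameter table (an
mbondi2-style column). Reduced radii ρ̃ = ρ − 0.09 Å; the pairwise
descreening integral uses the standard analytic form for the integral of
r⁻⁴ over a neighbor sphere (with the interior correction when spheres
overlap) and unit screening factors, since the parameter table carries no
per-element screening column. Effective radii follow
R⁻¹ = ρ̃⁻¹ − ρ⁻¹ tanh(αΨ − βΨ² + γΨ³) with α = 1.0, β = 0.8, γ = 4.8.
An isolated atom has R = ρ̃ exactly; burial increases R monotonically.
The pair energy uses the Still screening function
f = √(r² + R_iR_j e^{−r²/4R_iR_j}) over the full double sum including self
terms, with ε_out = 78.5 and Debye–Hückel salt screening
(κ ≈ 0.329·√I Å⁻¹ at 298 K; default 0.1 M). A single ion reduces exactly
to the Born equation.

**SASA.** Shrake–Rupley with 960 deterministic golden-spiral points per
atom and a 1.4 Å probe, using the GB intrinsic radii as atomic radii. The
nonpolar term is γ_np·SASA with γ_np = 0.005 kcal/(mol·Å²) and zero offset
— a documented, configurable default (the source analyses do not state
theirs).

**End-point ΔG.** Single-trajectory protocol: receptor and ligand
coordinates are extracted from each complex frame, so internal bonded
terms cancel identically and only the cross nonbonded terms plus the
solvation differences remain:
ΔG = E_elec + E_vdw + ΔG_GB + γ_np·ΔSASA, averaged over frames with the
sample standard deviation. These estimates rank relative binding
strengths; they are not absolute affinities, and no entropy estimate is
attempted. `rank_binders` orders by mean ΔG (most negative first, name
tie-break).

## Convergence diagnostics

RMSD uses optimal rigid-body (Kabsch) superposition of backbone heavy
atoms onto the first analysed frame (the reference frame is configurable;
the literature does not state one). RMSF superposes frames onto the mean
structure (two passes), then averages per-atom RMS deviations within each
residue. `plateau_check` encodes "reached a plateau over the final window"
as: least-squares slope magnitude ≤ slope_tol (default 0.1 Å/ns for RMSD)
and standard deviation ≤ sd_tol over the window (default 5 ns). An energy
series can be supplied where simulation energies are available; the
pipeline always applies the check to RMSD.

## The synthetic-system generator

The generator emulates exactly the features the analyses measure, with
recorded ground truth:

- Two ITY-like residues: an idealized phenol ring with 3,5-iodines, CG,
  hydroxyl, and (for the donor) a minimal backbone. The donor is fixed;
  the acceptor is posed rigidly per frame so that the realised inter-plane
  angle and reactive-atom distance equal draws from a configurable mixture
  of truncated normals (angle truncated to [0°, 180°], distance to > 0)
  to within 1e-6 — the rotation sets the angle exactly and the subsequent
  translation cannot change it.
- Pocket residues of all four polarity classes (SER/ALA/LYS/ASP
  mini-templates) on an 11 Å sphere, side chains facing the pocket and
  bodies extending outward. Directions are restricted to a deterministic
  band leaving free corridors for the swinging acceptor, the static donor,
  and a ligand channel above the ring plane; the seed rotates the starting
  point in the band. This guarantees clash-free frames by construction
  (verified in tests: no inter-residue contact below 1.5 Å).
- Declared hydrogen-bond pairs (serine donor → aspartate acceptor): each
  frame a Bernoulli draw at the planted occupancy places the acceptor
  oxygen at 2.8 Å along the O–H axis (D–H···A = 180°) or at 5.0 Å
  (cleanly outside the 3.0 Å criterion); the aspartate body trails along a
  pre-verified corridor.
- PFCA/PFSA ligands of any chain length: idealized zig-zag CF₂ chain
  capped by CF₃ with a carboxylate or sulfonate head. Template charges are
  fixed stand-ins (head carries the full −1 e; each CFx unit is neutral) —
  semi-empirical charge derivation is out of scope, and every test depends
  only on internal consistency, not on matching any published charge set.
- Pocket atoms receive 0.05 Å Gaussian jitter so RMSD/RMSF are
  nondegenerate; the ITY residues are exempt so planted geometry stays
  exact. All randomness flows from one integer seed; ground truth is
  serialized as JSON beside the trajectory.

What the generator does **not** emulate: a real protein fold, physical
energetics of the toy site (no minimization), correlated dynamics,
water-mediated interactions, or realistic charge distributions. Passing
recovery tests therefore demonstrates the correctness of the measurement
machinery, not the realism of any simulation.

## Problem sizes and numerics

Recovery checks use 2000-frame synthetic trajectories (component-mean
recovery to 3 standard errors: ≤ 0.5° and ≤ 0.05 Å; occupancy within a
99% binomial interval). The pipeline smoke tests use ~60-frame runs with a
coarser 120-point SASA grid; end-point ΔG demonstrations use 100 frames at
the full 960-point grid. Degenerate inputs: collinear plane atoms, empty
selections, zero-length normals, windows exceeding the span, and parameter
rows missing for any atom all raise immediately with the offending
residue/atom named. Ties in ranking are broken alphabetically; ties in
occupancy tables by ascending residue-index pair.

## Known limitations

- The GB arm only; published Poisson–Boltzmann numbers are out of scope.
- Decomposition excludes per-residue solvation attribution (flagged above).
- The reference reactive-atom choice is a documented interpretation; when
  analysing real structures, confirm the donor/acceptor atom names.
- DBSCAN's eps in mixed (degree, Å) units follows the published
  convention; rescaling the axes would change cluster membership.
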