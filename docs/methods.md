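# Methods

This note documents the models and procedures poreflux implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinate and unit conventions

Coordinates are Å, times ns, energies kJ/mol throughout; converters are
applied at parse time (GRO nm→Å, HILLS ps→ns).  Atom indices are 0-based;
residue IDs keep the topology numbering verbatim (no renumbering), so a
channel numbered in the familiar TREK-2 convention keeps, e.g., residue 315
as 315.  PDB files without chain identifiers fall back to TER-record
chains, else a single chain "A", with a warning.

## Pore axis and permeation

The pore axis is the membrane normal (z); the per-frame origin is the
mass-weighted centre of the SF backbone atoms.  Reported axial coordinates
(D_z) place that centre at +7 Å, the convention used for occupancy plots and
site definitions.  Positive D_z points extracellular, so "outward" events
are cytosol → extracellular, the direction conducted at positive voltage.

An ion permeates when, while radially inside a cylindrical gate (default
radius 8 Å — wide enough to enclose the SF and cavity, narrow enough to
exclude bulk; configurable), it passes from below a lower plane to above an
upper plane or vice versa without leaving the cylinder in between.  The
planes default to the SF axial extent ±3 Å.  This two-plane criterion is
robust to boundary recrossings: entering and retreating is never an event.
Apparent single-frame jumps longer than half the box are treated as
periodic-image artifacts and reset the tracking state; a genuine single-step
jump across both planes is counted but flagged `undersampled`.

Conductance is γ = N·e/(t·V) with e the elementary charge; no assumptions
beyond one charge per event.  Five events over 1 µs at +200 mV give
4.005 pS.

## Occupancy normalization and S0–S5

Ion-frames inside the cylinder are histogrammed over z (and optionally r);
density is counts per 0.001 Å³ of bin volume per 1 µs of total time.  In 2D
the bin volume is the annulus π(r_out²−r_in²)Δz, which removes the trivial
growth of counts with radius.  When replicates are combined, the time
normalization uses their summed duration.

S0–S5 boundaries are not a printed quantity anywhere we know of; the
defaults are contiguous 3.4 Å-tall intervals — roughly the carbonyl-plane
spacing of a K⁺ filter — anchored so the SF backbone centre (z = 7 Å) is the
S2/S3 boundary, S0 most extracellular.  They are plain data
(`SiteDefinition`) and fully overridable; site tables computed from the
defaults should be read as convention-dependent.

## ψ flips, circular KDE, θ-angle

ψ is the signed N–Cα–C–N(next) torsion, wrapped to (−180°, 180°].  Flip
classification is circular band membership around a crystallographic
reference value: default half-width ±40° (±60° for well-separated synthetic
states) with 10° hysteresis — a frame leaves the crystallographic state only
beyond band+hysteresis and returns only inside band−hysteresis, which
suppresses chatter when ψ sits on the band edge.  Zero hysteresis reduces
exactly to plain membership.  The band is a stated proxy: published figures
show ψ distributions, not a threshold.

Angle densities use a wrapped-Gaussian kernel evaluated at the minimum
angular image and renormalized to integrate to 1 over the circle.

The θ-angle is the unsigned angle between the per-frame helix vector
(Cα of the first residue → geometric centre of Cα of residues 315–333,
endpoints inclusive, range configurable) and the same vector in a reference
structure.  Because θ carries no sign, direction is annotated by comparing
against both up- and down-state reference vectors.

## Contacts and difference maps

One representative side-chain heavy atom per residue type (Cα for glycine)
keeps the contact computation linear in residues; the table covers all 20
standard types and accepts extensions for modified residues.  A pair is in
contact when the minimum-image distance is strictly below 5 Å.  Sequence
neighbours (|Δresid| < 2 within a chain) are excluded by default — they are
trivially in contact and would dominate — with the exclusion configurable to
0 for exact reproduction attempts.  The difference map retains pairs with
|Δp| strictly above 0.25, both signs kept and labelled, classified
inter-/intra-chain by chain identity; difference_map(up, down) is the exact
negation of difference_map(down, up).

## Structure network

Cα dynamic cross-correlations C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) are
computed after a rigid-body (Kabsch) fit to a reference frame; note the fit
absorbs common-mode motion by construction.  Edges carry weight
−log(contact probability), mapping interaction persistence to additive path
cost (p = 1 → cost 0).  A node may lie on a path only if its correlation to
at least one path endpoint reaches the cutoff, a dimensionless 0.8.  Paths
are Dijkstra shortest paths per (source, target) pair; the metapath keeps
edges appearing in ≥ 20% of retained paths (configurable) — "most frequent
connections" is otherwise unquantified.

## Well-tempered metadynamics and basins

Hill heights in a HILLS log are taken as deposited, i.e. already scaled by
the well-tempered rule (the PLUMED convention), so the estimator is
F(s) = −γ/(γ−1)·Σᵢ hᵢGᵢ(s), min-shifted to 0.  Torsional CVs are periodic;
Gaussians use the minimum angular image.  The default protocol is
h₀ = 1.2 kJ/mol, σ = 0.25 rad, γ = 8 at 300 K (k_BT = 2.494 kJ/mol); σ is
read in radians — a 0.25° hill would be physically meaningless for a torsion.
Surfaces are stored in CV units with degree axes available for display.

Basins are local minima deeper than `min_depth` below their lowest
connecting saddle, found by watershed flooding in order of increasing F
(topological persistence).  The default depth, 4 kJ/mol, equals one contour
step of the conventional FES plots; ripples from finite hills are therefore
never basins.

## ABMD

The ratchet bias never opposes progress: ρ_best is the running extremum
toward the target (capped at it), and the spring acts only on retreats,
|F| = k·(ρ − ρ_best) with k = 5000 kJ/mol/nm² and target 0.5 nm by default.
"Total force" is ambiguous in the field's usage between Σ|F| and Σ F²; both
are computed and labelled, and neither is asserted against published bar
values.

## Electrophysiology fits

Fold activation is FA = I_activated/I_basal.  The dose–response model is the
standard 4-parameter Hill curve %inh(x) = base + (max−base)/(1+(x_half/x)^rate)
with base = 0, max = 100 fixed unless freed — printed forms of this equation
in the literature are frequently garbled, and this parameterization matches
the stated half-maximal semantics of IC50.  Fitting is
`scipy.optimize.curve_fit` with x_half initialized at the geometric mean of
the doses, rate = 1, rate bounded to [0.3, 5]; standard errors come from the
fit covariance.  The fit is exactly dose-scale equivariant in the noiseless
case.

## Synthetic generators

Every generator is a pure function of its seed and returns its planted
truth; no analysis code reads it.  Defaults mirror the study conditions at
desk scale: 1 µs runs at 0.5 ns/frame, 5 permeation events/µs at +200 mV, a
5 Å-half-length SF in an 8 Å cylinder, two-state ψ telegraph with
exponential dwells, Bernoulli contacts, the h₀ = 1.2/σ = 0.25/γ = 8 hill
protocol, and a 7 µM IC50 Hill curve.

The permeation generator drives one dedicated ion monotonically through the
pore per Poisson event (12 frames per traversal, so crossings are resolved
at stride 2 and detection is never resolution-limited), keeps "teaser" ions
recrossing the lower plane only, and keeps bulk ions radially outside the
gate.  The hills generator runs a Metropolis walk at k_BT on the known
surface plus the accumulated bias (kept on the reconstruction grid and
updated per hill), with heights decaying by h₀·exp(−V_bias/((γ−1)k_BT)).

What the generators do **not** emulate: water and lipids, force-field
energetics, ion–ion correlations and knock-on conduction, voltage physics
(events are planted, not driven by a field), correlated contact dynamics, or
realistic protein geometry beyond what each analysis needs.  Passing tests
therefore demonstrate that the *bookkeeping and estimators* are correct
under known statistics — not that any particular physical system behaves
this way.

## Problem sizes

Tests and the acceptance script run at desk scale by design: hundreds of
frames per synthetic trajectory (tens of ions), 50-run detection ensembles,
10⁴-frame contact series, 2×10⁴ hills on a 73×73 grid, 200–500 dose–response
replicates.  These sizes give the statistical power each check needs (3-SD
binomial and Poisson bands, 1% flip-fraction recovery, 2 kJ/mol FES errors)
while keeping the whole suite in minutes.

## Known limitations

- Orthorhombic boxes only (minimum image on box lengths).
- The pore axis is fixed to z; tilted channels should be pre-aligned.
- Trajectory containers are in-memory; streaming iteration is available for
  frame-wise work, but the analysis battery materializes coordinates.
- Basin detection operates on the reconstruction grid; sub-grid basin
  locations are not interpolated.
- Correlation filtering uses endpoint correlation, not path-integrated
  correlation, which is one of several readings of correlation-refined
  shortest paths.
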