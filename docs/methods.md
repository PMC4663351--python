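# Methods

This note documents the models, conventions, and numerical choices
behind `bilayerbind`, and what the synthetic-data generators do and do
not emulate.

## System model and units

All analyses operate on a `Topology` (names, residues, molecule kinds,
partial charges, C6/C12 Lennard-Jones coefficients, implicit-hydrogen
counts, hydrogen-bond donor/acceptor flags) plus time-ordered `Frame`s
(positions, orthorhombic box).  Internal units are nm, ns, kJ·mol⁻¹,
degrees, and elementary charges; Ångström exists only at the PDB
boundary.  Triclinic boxes are rejected: with orthorhombic boxes the
minimum-image convention is exact and cheap, and the membrane systems
this package targets are rectangular.  Per-atom parameters come from a
YAML sidecar keyed by (residue name, atom name) rather than from
force-field topology files; the package analyzes simulations, it does
not prepare them.

## Depth coordinates and leaflet assignment

The bilayer normal is the z axis.  Leaflets are found per frame from
the phosphorus z coordinates: lipid molecules are first made whole
across the periodic z boundary, the P values are recentred about their
periodic (circular) mean, and the sorted values are split at the
largest gap.  A largest gap under 0.3 nm means no two-leaflet structure
exists and is an error.  The frame's depth references are the mean P
plane of each leaflet, the midplane, and the proximal leaflet (the one
nearest the peptide centroid).  All depth differences are taken
minimum-image in z, so an atom and its reference plane sitting in
different periodic images cannot produce a spurious box-length offset.

Residue centroids are unweighted means of the selected atoms; the main
chain is N, Cα, C, O; side chains are the remaining heavy atoms
(glycine therefore has no side-chain centroid and reports NaN).  The
closest residue is the arg-min of centroid depth, ties broken toward
the lower residue index.  "Adsorbed" is operationalized as: residue
centroid within `z_threshold` (default 0.3 nm) above the proximal P
plane, sustained for at least `dwell` (default 1 ns).  Both values are
configurable; the underlying simulation literature describes adsorption
narratively without thresholds, so these defaults simply make the event
detectable and reproducible.  Contacts are heavy-atom pairs within
0.45 nm (configurable), a common literature convention.

## Hydrogen bonds

A bond D–H···A is counted when simultaneously r(D···A) < 0.35 nm,
r(H···A) < 0.25 nm, and the angle at the hydrogen exceeds 150°, under
minimum-image distances.  Donor/acceptor capability is a per-atom flag
in the sidecar, so lipid→peptide and peptide→lipid bonds are both
countable (`directions="both"` by default; switchable, since published
counts do not always state the direction convention).  Hydrogens are
attached to their donor geometrically (element-H atoms of the same
residue within 0.125 nm); a donor-flagged atom with no attached
hydrogen is an error, not a silent skip.  Note the angle vertex: some
MD tool chains use a donor-vertex angle instead, so exact parity with
them is not claimed.  Group-resolved counts partition the headgroup
into choline (or glycerol), phosphate, and ester atoms; overlapping
group definitions are rejected.

## Nonbonded energies

The group interaction energy U(A+B) − U(A) − U(B) is, for
pairwise-additive potentials, identically the sum over cross-group
pairs; that cross sum is what `group_interaction` evaluates:
plain-cutoff Coulomb (prefactor 138.935458 kJ·mol⁻¹·nm·e⁻², cutoff
1.2 nm) plus C6/C12 Lennard-Jones (cutoff 1.4 nm), with geometric-mean
combination of per-atom C6/C12.  Because only cross pairs between
disjoint molecules are summed, bonded-exclusion bookkeeping never
arises.  There is no Ewald reciprocal-space term, no reaction field,
and no dispersion correction: reanalysis energies here are meant for
signs, rankings, and time evolution, and will not match the absolute
values of a particle-mesh-Ewald engine.  Truncation is exact — a pair
at or beyond its cutoff contributes precisely zero — which the tests
exploit.  Per-lipid normalization divides by the total lipid count, not
only contacting lipids (the published convention is ambiguous; total
count is the reproducible choice).

## Bilayer observables

**Electron density.**  Atoms are binned by z relative to the per-frame
bilayer midplane; each contributes its electron count — atomic number
plus one per implicit hydrogen (CH2 → 8, CH3 → 9), with no
partial-charge correction — and densities are counts/(Lx·Ly·w) averaged
over frames.  The fixed default bin width is 0.05 nm (an adaptive,
box-height-dependent width would make profiles non-deterministic across
box fluctuations).  Binning whole electrons at the atom position makes
the profile integrate exactly to the group's electron content, which is
asserted to 1e-9 relative.

**Order parameter.**  S_CD = ½⟨3cos²θ − 1⟩ with θ the angle between a
C–H vector and z, averaged over both hydrogens, lipids, and frames.
For united-atom chains the two C–H directions of each CH2 are
reconstructed assuming ideal tetrahedral geometry from the two chain
neighbours: with u the C(i−1)→C(i+1) direction and a the unit vector
opposite the bond bisector (orthogonalized against u), the hydrogens
lie at ±half the tetrahedral angle from a in the plane normal to u.
Terminal carbons have no reconstruction neighbours and are reported
absent (NaN, zero samples), never as zero — a zero is a physical value
here.  An explicit-hydrogen mode bypasses reconstruction.  A filter
restricts the average to lipids whose minimum heavy-atom distance to
the peptide is below a cutoff (default off, 1 nm when enabled).  The
exact reconstruction scheme used in the original analyses of such data
is generally unstated, so parity with any particular published curve is
not claimed; the closed-form limits (θ = 0 → 1, θ = 90° → −0.5, magic
angle → 0, isotropic → 0) are exact.

**Thickness and area per lipid.**  Thickness is the frame-averaged
difference between upper- and lower-leaflet mean phosphorus z.  Local
thickness restricts each leaflet mean to lipids whose minimum *lateral*
(xy) heavy-atom distance to the peptide is below the cutoff: a 3D
distance from a surface-bound peptide can never reach the distal
leaflet at a 1 nm cutoff, which would leave the quantity undefined, so
the footprint metric is used.  Area per lipid is the time average of
Lx·Ly divided by lipids per leaflet.

## Binding orientation

The helix axis over the core helical region (residues 8–19 by default)
is the common normal of the Cα second differences — the smallest
principal direction of their scatter.  For ideal helical geometry every
second difference points radially, making this exact; a least-squares
line through a fractional number of turns (12 residues × 100° = 3⅓
turns) is systematically tilted by ~2°, which is why the line fit was
rejected.  The axis sign runs N→C; at least four Cα atoms are required.

The rotational phase ψ is the azimuth, measured from the "down"
direction (−z projected off the axis, increasing right-handed about the
axis), of the molecule-fixed anchor face: the mean radial direction of
the anchor residues' side chains (R11, F15, S19 by default — the face
that is membrane-buried in the Fd pose).  This makes ψ a true rotation
coordinate: rolling the helix by Δ about its axis shifts ψ by Δ.  A
depth-weighted mean of *observed* membrane-facing residues was
considered and rejected: for a rigid helix that direction always points
at the membrane, so it carries no rotational information.  The depth
profile still gates the computation — a flat core-helix side-chain
depth profile means no membrane-facing asymmetry and is an error, as is
an axis tilted more than 60° out of the membrane plane.

Classes are ψ quadrants with boundaries at 45°, 135°, 225°, 315°:
Fd ↔ ψ ∈ [−45°, 45°), then Fa, Fb, Fc under successive +90° rotations.
The Fd anchor and the cyclic order are fixed by the definition; which
physical helix faces the labels Fa/Fb/Fc denote is a package convention
that cannot be pinned down further from published figure panels alone.
Classification uses the circular mean of per-frame ψ over the final
time window (default 20 ns), reporting the circular resultant length as
a confidence; a peptide with no residue inside the adsorption threshold
during the window is "unbound".  Initial states are built
deterministically: axis aligned with x, the reference residue's (K1)
side chain rolled to point at the membrane for S(0), the peptide raised
until the minimum heavy-atom separation from the bilayer reaches
1.4 nm, and copies rotated by 90°/180°/270° about the helix axis (each
re-checked for clearance).

## Synthetic generators

The generators produce the study-scale systems the analyses were
designed around, with every target recorded as ground truth.

**Bilayer.**  2 × 64 pseudo-lipids by default (configurable), each
~14 sites: a choline (PC, charge +1, no H-bond capability) or glycerol
(PG, neutral, donor+acceptor with an explicit hydroxyl H) head site, a
phosphorus with two phosphate oxygens (group charge −1, acceptors), two
neutral ester oxygens (acceptors), and an all-trans united-atom sn-1
tail.  Lipids sit on a lateral grid with box area = lipids × target
area per lipid (default 0.616 nm² ≈ the zwitterionic-bilayer scale);
phosphorus planes at ±thickness/2 (default 3.67 nm) with optional
per-lipid rigid z jitter (default σ = 0.02 nm, a realistic headgroup
roughness that still recovers targets within 1%).  The PC choline site
sits 0.10 nm outside the P plane and the PG glycerol site nearly level
with it (+0.02 nm), reproducing the headgroup layering difference
between the two chemistries; esters sit 0.20 nm inside.  Tails are
tilted from the inward normal by an angle drawn per lipid (default
fixed 30°), with zigzag planes at equally spaced azimuths across a
leaflet — equal spacing makes the azimuthal average in S_CD exact, so a
fixed tilt τ yields S_CD = (1 − 3cos²τ)/4 to machine precision
(−0.3125 at 30°, 0 at the magic angle).  An optional Gaussian dimple
(depth, radius) thins the upper leaflet locally for local-thickness
tests.  No water or ions are generated: no in-scope analysis touches
solvent.

**Peptide.**  An ideal α-helix (rise 0.15 nm, twist 100°/residue,
Cα radius 0.23 nm) of the 37-residue amylin sequence by default, with
N, H, Cα, C, O backbone sites and radial side-chain stubs (CB + SC,
0.4 nm; none for glycine; hydroxyl/amine hydrogens on S/T/Y/K/R).
Charges: +1 on the free N-terminus (distinct atom name NT), +1 on the
K and R side-chain sites; the C-terminus is amidated (neutral), giving
amylin a net charge of +3.  The helix is calibrated after construction
so the recovered anchor-face phase equals the requested ψ₀ exactly.

**Scripted trajectories.**  The rigid helix is rolled to a scheduled
ψ(t) and tilted/translated so the residue-1–19 and residue-20–37 region
centroids hit scheduled heights above the upper P plane
(piecewise-linear keyframes; the two-point placement is solved in
closed form per frame).  The default script emulates C-terminal-first
adsorption: the C-terminal region reaches the surface at 12 ns and the
N-terminal region at 50 ns, settling slightly C-down.  H-bonds are
planted by relocating chosen lipid acceptor atoms onto ideal geometries
(D–A 0.30 nm, H–A 0.20 nm, angle 180°) along backbone N–H directions of
donors spaced three residues apart, so planted counts are exact while
the peptide hovers clear of the headgroups.  The ground-truth record
carries per-frame ψ, planted counts per group, and per-residue first
adsorption times computed directly from the generated coordinates with
an independent run-length scan.  A script that would push peptide atoms
deeper than a quarter of the bilayer thickness below the upper P plane
is rejected.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: there are no forces or thermostats (purely
scripted kinematics), no water or ions, no lipid conformational
disorder beyond headgroup jitter and tail tilt, chemically simplified
side chains (radial stubs, single interaction site), and planted rather
than emergent hydrogen bonds.  Tests against this ground truth verify
that the *analyses* compute their definitions correctly, not that the
underlying biophysics of any particular simulation is reproduced.

## Problem sizes and tolerances

Tests and the acceptance script run on reduced systems chosen to
exercise every code path while keeping the whole suite fast: bilayers
of 16–64 lipids per leaflet, trajectories of 2–60 frames, exhaustive
H-bond oracles at 25 donors/40 acceptors per frame (100 frames), energy
oracles at 30 + 30 atoms, and orientation recovery over 100 seeded runs
per quadrant class at ±20° frame-to-frame phase noise.  Oracle
agreements (H-bonds, contacts) are exact; energy and conservation
identities hold to 1e-9 relative; generator targets are recovered
exactly at zero jitter and within 1% at the default jitter; phase
equivariance holds within 2°.  All randomness flows from explicit seeds
(`numpy.random.default_rng`), and identical specs produce bit-identical
outputs.

## Known limitations

- Cutoff electrostatics only; energies are not comparable in magnitude
  to Ewald-based engine output.
- The Fa/Fb/Fc label-to-face attachment is conventional (Fd and the
  cyclic order are fixed).
- The S_CD hydrogen reconstruction assumes ideal tetrahedral CH2
  geometry; double-bond-specific conventions for unsaturated carbons
  are not implemented.
- Leaflet assignment assumes a planar bilayer normal to z; curved or
  strongly undulating membranes are out of scope.
- XTC round trips carry the format's 0.001 nm coordinate precision;
  threshold-straddling events can shift by one frame through files.
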