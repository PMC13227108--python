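# Methods

## The rigid base-pair representation

dnaforge models double-stranded DNA as an ordered chain of base-pair
reference frames: an origin (nm) plus a right-handed orthonormal triad, with
z along the helix axis toward the 3' end of the reference strand and x
toward the major groove (the standard base reference frame).  The relative
geometry of two consecutive frames is expressed in six step coordinates —
translations (shift, slide, rise; nm) and rotations (tilt, roll, twist;
degrees) — using the axis–angle (rotation vector) parameterization with
half-rotation mid-frames, the Curves+ convention.  The map between frame
pairs and step 6-vectors is exactly invertible for relative rotations below
180°; a 180° relative rotation has no unique axis and raises rather than
silently picking one.  Chained frame reconstructions are re-orthonormalized
(SVD projection) every 100 steps to cap floating-point drift; validity drift
over 10^4 chained applications stays below 1e-9.

Intra-base-pair parameters (shear, stretch, stagger, buckle, propeller,
opening) use the same algebra between the two co-oriented base frames of a
pair: the antisense (Crick) base frame is flipped 180° about its own x axis
before pairing, and the base-pair frame is the half-rotation mid-frame of
the two.  For structures generated from scratch both strand frames coincide
with the base-pair frame, so the intra parameters are identically zero;
they become informative when frames are fitted from atomic coordinates.

## Structure generation

Shapes are specified by control points (≥ 4, nm).  A cubic interpolating
spline runs through them — natural end conditions for open curves,
C²-periodic for closed ones; the curve interpolates rather than
approximates because users position control points deliberately.  The
arc-length table is built by adaptive Gauss–Kronrod quadrature (relative
tolerance 1e-8) and inverted by bracketed root finding, giving sample
points equidistant in arc length.  Without a target base-pair count the
spacing is 0.34 nm (the mean B-DNA rise) and the count follows from the arc
length — floor(L/0.34)+1 points for open curves, round(L/0.34) for closed —
with the residual spread uniformly over all gaps and the effective spacing
logged.  With a target count the spacing rescales to the fixed geometry.
The two default shapes need no spline: a straight line along +z, and (for
closed topology without control points) a planar circle of circumference
n_bp × 0.34 nm, both constructed in closed form with exact spacing.

Frame triads are laid down by discrete parallel transport: z follows the
local tangent and the normal is carried by the minimal rotation between
consecutive tangents, so the transported field is twist-free.  The initial
normal is the global +x axis projected perpendicular to the first tangent
(+y when the tangent is within ~2.5° of x) — a deterministic rule so that
identical inputs give identical structures.

Helical twist is then imposed.  Open chains receive 360/10.5° per step
(10.5 bp/turn, overridable).  Closed chains must carry an integer number of
turns: the relaxed twist is Tw₀ = round(n_bp/10.5) (half rounds to even),
and a requested linking-number difference dLk (integer; supercoiling) is
realized through the White–Fuller theorem Lk = Tw + Wr by setting the total
twist to Tw_new = Tw₀ + dLk − Wr, where Wr is the writhe of the sampled
centre line computed at construction time.  This makes the generated Lk
equal Tw₀ + dLk regardless of any writhe already present in the chosen
shape (verified to 1e-6 turns on circles, ellipses, saddles and strongly
writhed trefoil-like loops).

## Writhe, twist and linking number

Writhe uses the exact pairwise solid-angle form of the discrete Gauss
double sum over segment pairs (the Klenin–Langowski method 1a), skipping
adjacent segments including the wrap pair; at 200-segment resolution it
agrees with a 10×-refined discretization of the same smooth curve to
better than 1e-3.  Mirroring a curve negates its writhe exactly.

Twist, for the linking number, is the polygonal ribbon twist: the rotation
of the base-pair x axis about the centre line referenced to discrete
parallel transport of the segment tangents, summed around the chain.  With
this definition Lk = Tw + Wr is the Gauss linking number of the two edge
curves of the ribbon — an integer to numerical precision (~1e-8) and an
exact invariant of any deformation that does not pass the chain through
itself.  The sum of step-parameter twists differs from the ribbon twist by
second-order bending–twist coupling terms (~1e-3 turns on a 200 bp
minicircle); it is reported by the rigid-parameter module but deliberately
not used for Lk, where it would break the topological identity.
Writhe and Lk are computed over the base-pair origin centre line, not the
backbone atom curves, consistent with the generation-side writhe.

## Elastic model and Monte Carlo relaxation

The energy is a quadratic rigid-base-step Hamiltonian,
E = ½ Σᵢ (xᵢ − x₀)ᵀ K (xᵢ − x₀) in kT at 300 K, over all steps (including
the wrap step when closed), plus a hard-sphere excluded volume.  The
default equilibrium step is x₀ = (0, 0, 0.34 nm, 0, 0, 34.286°).  The
default stiffness is diagonal and sequence-independent, derived from
literature-standard elastic lengths: bending persistence length 50 nm gives
⟨tilt²⟩ = ⟨roll²⟩ = rise/l_p per step, torsional persistence length 100 nm
gives the twist variance, and translations are stiff springs with 0.01 nm
fluctuation.  All entries are overridable; sequence-dependent stiffness is
out of scope.

Excluded volume is a hard wall of diameter 2.0 nm between base-pair origins
whose chain separation is at least 8 steps (circular separation for closed
chains).  Eight steps is the smallest exemption for which ideal B-DNA
(8 × 0.34 = 2.72 nm) clears the diameter with margin; smaller exemptions
would reject the ideal helix itself.  Violations reject the move (infinite
energy), and every move additionally caps the per-bead displacement at half
the hard-sphere diameter, so two chain segments can never cross between
accepted states: the linking number of closed chains is conserved exactly,
and the sampler verifies Lk before/after and fails loudly if it ever
changed.

Moves are Metropolis with symmetric proposals at temperature T (default
300 K; the Boltzmann factor is exp(−ΔE·300 K/T) with E in kT at 300 K):

* **crankshaft** — rotate the frames strictly between two chain points
  about the axis joining their origins (endpoints untouched); the workhorse
  for closed chains and the move that converts twist into writhe;
* **terminal pivot** (open chains) — rotate a terminal segment about a
  hinge by a small random rotation;
* **local** — perturb a single frame's origin (σ = 0.01 nm) and triad
  (σ = 4°), equipping the sampler with translational degrees of freedom;
  with a single free step the sampled parameter variances reproduce
  K⁻¹kT within a few percent (equipartition).

Moves touching fixed indices are rejected outright.  By default the two
terminal frames of open chains are pinned and closed chains are fully
mobile; structures returned by `extend`/`connect` carry an explicit free
set (the new bases plus a margin of original bases) and everything else is
held.  Rigid block moves change only the two boundary steps, so the energy
update is O(1) per move.  The RNG is a single seeded `numpy` Generator;
identical seed, config and input reproduce the trajectory bit for bit.

Convergence is assessed by least-squares fitting c + a·exp(−t/τ) to the
per-sweep energy trace: converged means the trace spans at least five decay
times and the fitted plateau is stable (relative change < 5% between fits
on the two halves).  Runs that impose dLk ≠ 0 cross a buckling barrier
(the circle is metastable until writhe nucleates), so they additionally
require the writhe trace to fluctuate about a fixed value (plateau over the
last 20%).  Relaxation of a 200 bp minicircle with dLk = 6 develops
|Wr| ≈ 3 within a few hundred sweeps while Lk stays exactly at Tw₀ + 6.

For linear chains without excluded volume the quadratic model is sampled
exactly by drawing steps from N(x₀, K⁻¹); `sample_ensemble` uses this for
ensemble statistics such as persistence-length estimation, where the
tangent correlation ⟨zᵢ·zᵢ₊ₘ⟩ is fitted to exp(−m·h/l_p) by log-linear
least squares on correlations above 0.05 and lags up to n_bp/2.

## Sequence alphabet and atomic templates

Thirteen nucleobase codes are supported at the sequence/pairing level:
canonical A, T, G, C, U; fluorescent E (2-aminopurine → T) and D
(tricyclic cytosine analog → G); Hachimoji B↔S and P↔Z; hydrophobic
L (d5SICS) ↔ M (dNaM).  The complement map is one-way for U, E and D,
whose partners pair back to the canonical bases — so
complement(complement(s)) = s holds only on the mutual sub-alphabet.
Atomic templates ship for the canonical five; the other codes raise on
atomic build unless the user registers a template.

Templates hold heavy atoms in the standard base reference frame: planar
ring geometry per the published standard reference frames, plus one
idealized, synthetic C2'-endo-like sugar–phosphate set shared by all bases
and attached rigidly.  Because nucleotides are placed as rigid bodies,
inter-residue O3'–P distances are approximate — generated structures are
starting configurations for refinement, not final backbone geometry.
The antisense base is placed with the pair frame composed with a 180°
rotation about x (the standard complementary-strand flip); refitting base
frames from generated atoms therefore recovers the generating frames to
machine precision, and ~1e-6 nm through a PDB round trip.

Editing operates on annotations materialized at atomic-build time: a
Hoogsteen flip rotates the base atoms (not sugar/phosphate) 180° about the
glycosidic bond (C1'–N9 for purines, C1'–N1 for pyrimidines) and toggles
the pair's HG tag, making the default flip an exact involution; methylation
adds one carbon at C5 of cytosine (5-methylcytosine, residue name 5CM) or —
a choice made here, since N7 is the common alkylation site — at N7 of
guanine (7MG).  CpG auto-methylation scans the reference strand; a
both-strands option also methylates the complementary-strand cytosine of
each site.

`extend` continues a linear duplex beyond a terminus, by default straight
along the terminal frame's z at ideal rise and twist, or along a user
spline anchored at the terminal origin; original frames are preserved
bitwise.  `connect` bridges the 3' end of one duplex to the 5' end of
another on the straight segment between them.  When the bridge length is
free it is chosen to minimize the helical register penalty — the squared
wrapped deviation of the twist required between the two fixed terminal
frames from n × 360/10.5 over candidate n near gap/0.34, ties to the
smaller n.  Rise deviation is not penalized jointly; the seeded bridge is
handed to the minimizer with the bridge plus margin bases free.

## Validation and loading

Frame-array input is validated for shape (t, n_bp, 4, 3), sequence length
and triad orthonormality: deviation below 1e-6 passes, up to 1e-3 is
repaired by SVD re-orthonormalization (logged), worse fails.  A structure
is classified circular when the first and last base-pair origins are within
1 nm *and* the chain exceeds 20 bp — the length guard prevents short
fragments with coincidentally close ends from being misclassified — unless
the caller states the topology explicitly.  PDB files (multi-model =
trajectory) are read through Biopython; base frames are fitted per residue
by least-squares superposition of the template ring atoms (SVD/Kabsch), and
strands are paired by index complementarity.  Unknown residue names fail
loudly rather than guessing.

## What the synthetic fixtures do and do not show

Test fixtures are generated programmatically: ideal linear duplexes,
relaxed and supercoiled minicircles, and noisy pseudo-trajectories with
seeded Gaussian frame perturbations (σ = 0.01 nm, 1°).  These exercise the
geometric pipeline exactly but are not molecular dynamics data: they carry
no sequence-dependent structure, no correlated thermal motion and no
backbone/solvent detail, so passing tests demonstrate correctness of the
geometry, topology and statistics, not force-field-level realism of any
particular DNA sequence.

## Problem sizes used in the checks

The shipped checks run on desk-scale systems chosen to keep the full suite
fast while still exercising every code path: 80–300 bp chains, a 200 bp
minicircle with dLk = 6 relaxed for up to 800 MC sweeps, equipartition
over 1e5 accepted single-step moves, and persistence-length recovery from
200 sampled 300 bp conformations.  Structure generation and analysis are
effectively instantaneous at these sizes; MC relaxation of the minicircle
takes on the order of a minute.

## Known limitations

* Backbone closure between consecutive rigid nucleotides is approximate;
  no backbone refinement is attempted.
* Non-canonical bases are bookkeeping-only (no atomic templates, and they
  are rejected by the elastic model's minimizer).
* The elastic model is sequence-independent and diagonal by default;
  couplings can be supplied but are not derived from data.
* Hoogsteen flips are geometric: G·C Hoogsteen pairs requiring protonated
  cytosine get no special chemistry.
* Single-stranded DNA, RNA hybrids and branched architectures are out of
  scope, as are binary trajectory formats (PDB and frame-array text only).
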