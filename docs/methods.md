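# Methods

This note records the models implemented in `allokit`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Conservation and coevolution

Per-column conservation is the Kullback–Leibler divergence of the
observed amino-acid frequencies from background,
`KL_c = Σ_a P(a) ln(P(a)/Q(a))`, in nats. The background `Q` defaults to
database-wide (Swiss-Prot) composition and can be overridden by a
two-column TSV. Gaps are excluded from column frequencies; columns with
more than 50% gaps are scored but flagged unreliable. KL is non-negative
by the Gibbs inequality, and a column whose frequencies match `Q`
exactly scores zero — both are tested.

Pairwise mutual information between columns uses pairwise-complete
observations (sequences ungapped at both columns); pairs with fewer than
10 joint observations are masked. Raw MI in nats is bounded by the
smaller column entropy. Two corrections are layered on top:

* **APC** — the average-product correction `MI_i· MI_·j / MI_··`
  subtracted from each entry, computed over unmasked off-diagonal
  entries; removes the shared-background component that otherwise
  dominates MI rankings.
* **z-score** — the APC-corrected matrix standardized against a null
  obtained by independently permuting every column (50 shuffles by
  default, seeded). Shuffling preserves column compositions while
  destroying covariation, so the null captures finite-sample MI inflation
  per pair.

The cumulative score `cMI_x` sums a column's MI values strictly above a
threshold; the default threshold 6.5 is applied to the z-scored matrix.
Raw MI in nats is bounded by ln 20 ≈ 3.0 and can never reach 6.5, so a
raw-scale threshold of 6.5 would zero every profile; on the standardized
scale 6.5 is a stringent significance cut. A raw-threshold mode remains
available for users who supply their own scale.

The proximity score `pMI_x` is the mean of cMI over the residue itself
plus all residues within 5 Å (shortest heavy-atom distance).
Self-inclusion keeps isolated residues defined. Alignment columns map
onto structure residues through a global pairwise alignment of the query
sequence against the structure-derived sequence (match +2, mismatch −1,
gap open −5, extend −0.5); mappings below 90% identity are rejected. For
homodimers each protomer is mapped independently and pMI neighborhoods
may span the dimer interface.

## Coarse-grained dynamics

**Square-well DMD.** Residues are C-alpha beads of unit mass. Bonded
neighbors are confined to `[(1−σ)r⁰, (1+σ)r⁰]` with σ = 0.05 around
their native spacing (ideal 3.8 Å); nonconsecutive pairs closer than
r_c = 8 Å in the native structure get σ = 0.1 wells; more distant pairs
do not interact. Between events beads move ballistically. At a wall the
normal component of the pair's relative velocity is reflected
(equal-mass exchange), conserving energy and momentum to machine
precision — the engine's conservation drift and wall violations are
asserted at 1e-8/1e-9 in the tests. Event times are exact roots of the
per-pair quadratic; events live in a binary heap invalidated lazily by
per-pair epoch counters, and a test hook verifies each popped event
against exhaustive minimum-time search.

Velocities are initialized from the Maxwell–Boltzmann distribution at
the requested reduced temperature (k_B T = 1 by default) with the
center-of-mass drift removed. An optional Andersen-style thermostat
resamples all velocities at a fixed time interval; it is off by default
(microcanonical), and on for canonical-ensemble checks such as the
two-bead radial density, which must then be uniform over the accessible
shell volume, p(d) ∝ d² on [d_min, d_max].

Frames are sampled on a uniform *time* grid, with the spacing chosen so
that `sample_every` events elapse per frame at the collision rate
observed during burn-in (default: the first fifth of the run). Sampling
at collision instants would oversample wall configurations; a time grid
gives correctly time-weighted equilibrium statistics.

**Elastic-network surrogate.** Long all-atom trajectories are out of
scope; their role is filled by frames drawn from the multivariate
Gaussian whose covariance is the pseudo-inverse of the anisotropic
elastic-network Hessian (unit springs between C-alpha pairs within 10 Å;
six rigid-body modes excluded; more than six near-zero modes is treated
as a disconnected network and raises). Every downstream stage consumes
only frames or a covariance, so externally generated ensembles can be
dropped in through the multi-model PDB reader.

**Reductions.** The covariance `C = (1/F) Σ ΔR ΔRᵀ` is computed after
optional least-squares (Kabsch) superposition of frames onto the running
mean (two refinement passes); superposition is on by default for real
trajectories and skipped for synthetic Gaussian ensembles, which contain
no rigid-body motion by construction. Mean-square fluctuations are the
traces of the diagonal 3×3 blocks, and `B = (8π²/3)·msf`. The slow-mode
profile is the eigenvalue-weighted average of per-residue squared
eigenvector displacements over the three largest covariance modes,
normalized to sum to one. Extrema are detected on a moving-average
smoothed profile (window 3 in the pipeline) within user-supplied
segments (one per protomer, so smoothing never crosses a chain
boundary); minima qualify as hinges when below the 25th percentile of
their segment, maxima as mobile regions above the 75th. The percentile
gate and window are configuration knobs; 25% was chosen so that
single-residue pivot dips survive the smoothing.

## Surface metrics

SASA uses a deterministic dot-sphere construction: 960 golden-spiral
points per heavy atom at radius r_vdw + 1.4 Å, occluded dots removed via
a k-d tree neighbor search, surviving dots each carrying an equal share
of the expanded-sphere area. An isolated atom reproduces 4π(r+probe)²
to the dot-count resolution. Relative accessibility divides residue SASA
by the theoretical Gly-X-Gly maximum (Tien et al. 2013 values built in,
overridable); classes are exposed (> 50%), buried (< 20%), intermediate,
with a deeply buried flag below 10%.

Residue depth reuses the surviving dots as a discrete solvent-accessible
surface: per atom, depth = max(0, distance to nearest dot − (r_vdw +
probe)), so atoms owning surface dots are at depth 0; per residue both
the mean and minimum over atoms are reported. This surface-dot proxy is
deterministic and dependency-free; it is monotone-equivalent to
solvated-box depth methods on compact structures but is an
approximation, and absolute depths should not be compared across
algorithms. C-alpha-only inputs are scored in a coarse mode with bead
radius 3.0 Å and the RSA classes suppressed.

## Perturbation response scanning

With the covariance standing in for the inverse Hessian (thermal
prefactor absorbed — only profile shapes matter), the response of
residue j to a force f at residue i is the 3-block product `C_ji f`.
The scan applies 250 random unit forces per residue; the response map
entry is the mean squared displacement. Averaging `|C_ji f|²` over
uniform unit directions has the closed form `||C_ji||_F² / 3`
(E[f fᵀ] = I/3), which the package exposes as `prs_expected` and the
tests use as the scan's oracle.

Force directions are sampled as random orthonormal triads (QR frames of
Gaussian matrices): each direction is marginally uniform on the sphere,
and every complete triad averages the quadratic form exactly, reducing
the per-entry quadrature error at 250 forces from ~10% (iid sampling) to
under 1%. Plain iid sampling remains available.

Because this covariance is symmetric, the raw response map is symmetric
and its row and column means coincide. Effector/sensor asymmetry lives
on the *normalized* map (each row divided by its diagonal
self-response): effectors are stiff residues whose influence is large
relative to their own mobility, sensors are residues that respond
strongly regardless of where the force lands. Profiles are row/column
means excluding the diagonal (a config flag restores inclusion); peaks
are z-scores above 1.5 with a 3-residue minimum separation.

## Residue interaction network

Mutual information between two residues' 3-D fluctuation vectors uses
the closed-form Gaussian estimator
`I = ½ ln[det C_ii det C_jj / det C_joint]`, mapped to
`R_MI = sqrt(1 − exp(−2I/d))` ∈ [0, 1] with d = 3. When a pMI profile is
supplied, each residue gains a fourth, static coevolution channel
modeled as a unit-variance Gaussian coordinate whose inter-residue
correlation is the product of max-normalized pMI values; MI is additive
over independent channels, so strongly coevolving pairs gain
`−½ ln(1−ρ²)` of information and d becomes 4. This is one concrete
reading of a composite structure-plus-coevolution residue vector; a
pure-dynamics mode (no pMI) is the default whenever no alignment is
supplied, and the matrix records which mode produced it.

Edges connect pairs whose R_MI strictly exceeds 0.5 in at least one
independent ensemble (max-over-ensembles rule), with weight
`−log R_MI` (R_MI capped at 1 − 1e-12 so weights stay finite).
Contact gating restricts edges to structural contacts — 5 Å heavy-atom
for all-atom structures, the 8 Å C-alpha cutoff for coarse bead models —
to suppress spurious long-range correlation edges. All-pairs distances
come from Floyd–Warshall on the dense weight matrix; edge betweenness is
the fraction of shortest paths through an edge with equal tie-splitting
(Brandes' algorithm, cross-checked against exhaustive enumeration);
effector→sensor routes are the k shortest loopless paths (Yen), ranked
by total weight, with per-node traversal counts exposing gate-keeper
residues.

## PTM classification

A mapped PTM site is *conserved* when its column KL exceeds the
alignment mean by k·SD (k = 1 by default, exposed as
`--conservation-k`). Roles are non-exclusive sets: hinge within 2
residues of a slow-mode minimum; effector/sensor above z = 1.5 on the
respective PRS profile; carrier within the window of a slow-mode maximum
or in the top sensor quartile. For homodimers, profiles are averaged
across protomers before classification (a warning fires when the
protomers disagree by more than 20% relative — Monte Carlo noise at a
few hundred frames routinely trips this; it is informational). Every
assignment row carries all supporting scores, so the table reproduces
the role calls exactly.

## Synthetic study systems

The toy homodimer is two identical protomers of three compact
random-growth bead domains (pseudo-NTD/MD/CTD, 10 beads each, 3.8 Å
bonds, 3.6 Å minimum separation), dimerized through their CTD blobs, and
rejected and regrown when the blobs fail to form a genuine NTD–MD
interface or the protomers clash. Ground truth is planted in the
*dynamics*, not just annotated: the covariance generator assembles an
explicit spring network in which

* same-chain NTD/MD cross-domain contacts are softened (0.15 vs 1.0) so
  a slow inter-domain swing exists, with anchors forced onto six
  distinct NTD beads so the interface never degenerates into a rotation
  axis;
* the linker bead — the hinge — is pinned to the four nearest CTD-core
  beads and its neighborhood amplitude-contracted (scale 0.45, wings
  0.65), making it an immobilized pivot whose slow-mode dip survives
  profile smoothing;
* the effector bead gains springs to anchor beads in every domain of
  both chains, placed in quiet regions (near the pivot in the NTD, near
  the CTD junction in the MD), and its amplitude is contracted to 0.2 —
  a stiff, globally coupled bead, which is precisely the PRS effector
  signature;
* the four tail beads keep only soft backbone springs (0.25) plus faint
  second/third/fourth-neighbor stabilizers — a floppy appendage whose
  lever amplification makes it the dominant sensor;
* under-coordinated body beads are tied to their nearest neighbors
  until they carry four springs, so sparse random growth cannot create
  unplanned floppy sites.

Amplitude contraction is a diagonal similarity scaling of the
covariance; it preserves positive semidefiniteness and every
correlation, only shrinking the scaled beads' fluctuation amplitudes.
These choices were fixed by verifying, across dozens of generator seeds,
that the planted hinge is a detected slow-mode minimum, the planted
effector tops the normalized effector profile, and the tail fills the
top sensor decile; recovery holds for roughly 97% of random geometries
(occasional extreme geometries leave one tail bead just outside the
decile).

The synthetic alignment draws background columns iid from database
composition; conserved columns emit a peak amino acid with probability
0.95; in a coevolving pair, the second column copies a seeded bijective
recoding of the first with probability 0.9 (the study condition for
recovery tests: N = 200 sequences, L = 50 columns, 5 planted pairs).
Gaps are sprinkled at 2% everywhere except the query row, which anchors
structure mapping. Default ensemble sizes are 400 frames × 2 independent
ensembles for the pipeline and 10⁴ frames for covariance-recovery
checks; DMD diagnostics use 10⁵ events on the 60-bead dimer. These sizes
give comfortable statistical margins for every planted signal while the
whole test suite stays interactive.

What the generators do *not* emulate: real protein geometry (side
chains, secondary structure, realistic packing), phylogenetic
correlation among sequences (alignment rows are exchangeable),
anharmonic or multi-basin dynamics, and PTM chemistry. Passing tests
therefore demonstrate that each algorithm recovers the signal class it
targets at realistic signal-to-noise — not that any particular
biological system will show such signals.

## Numerical choices and limitations

* Natural logarithms throughout; information in nats.
* Contacts use strict `distance < cutoff`; the R_MI edge rule is strict
  `> 0.5`; cMI sums strictly above threshold.
* Altloc resolution keeps the highest-occupancy conformer (first on
  ties); hydrogens are identified by element, with an atom-name
  heuristic for files without element columns.
* The ENM pseudo-inverse drops exactly six modes; a seventh near-zero
  mode raises rather than silently regularizing.
* DMD event times guard against beads numerically at a wall by clamping
  the outward discriminant at zero; start geometries violating a well
  are projected inside iteratively (and logged) before the run.
* Equal-weight shortest-path ties: betweenness splits equally;
  the reported representative path follows predecessor order.
* The pipeline funnels all randomness through one master seed expanded
  per stage; reports are byte-identical across reruns of the same
  configuration.
* Absolute SASA/depth values depend on radii, dot density, and the
  surface-dot depth convention; only classes and orderings should be
  compared across tools.
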