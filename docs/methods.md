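# Methods

## The physical model

Transcranial direct current stimulation (tDCS) drives a weak direct
current (~1–2 mA) through scalp electrodes; the quantity that matters for
neuromodulation is the electric field it induces in the cortex.  At DC,
capacitive and inductive effects in tissue are negligible and the problem
is quasi-static volume conduction: the potential V satisfies

    div( sigma grad V ) = 0

inside the head, with sigma the local isotropic conductivity, and the
electric field is E = −grad V.  The boundary conditions are the dose: the
total injected current enters through the anode, the cathode conductor is
held at ground (V = 0), and every other external surface is insulated.
The problem is linear in the injected current — doubling the current
doubles V and E everywhere — which is what makes dose normalization by
current rescaling exact.

Tissue conductivities (S/m) are representative DC literature averages:
skin 0.465, skull 0.01, CSF 1.65, gray matter 0.276, white matter 0.126,
air 1e-7, electrode metal 5.8e7, saline-soaked sponge 1.4, conductive gel
0.3.  The CSF/skull contrast (165×) dominates the current pathways: the
skull throttles entry, and the CSF sheet shunts current tangentially and
channels it around the cortex.

## Head phantoms

Real pipelines segment subject MRIs into the six tissue classes (skin,
skull, CSF, gray, white, air).  This package substitutes parametric
voxelized phantoms so every geometric quantity has a closed form:

* **Layered sphere** — concentric shells (white core, gray, CSF, skull,
  skin) in an air box.  Each voxel is classified by its *center* distance
  from the phantom center; no partial-volume fractions.  This mirrors a
  1 mm voxelized segmentation workflow and keeps brute-force geometric
  oracles trivial.
* **Gyrated sphere** — the gray/CSF interface radius is modulated as
  r(θ,φ) = r0 + A·sin(kθ)·sin(kφ + phase), with the gray thickness
  preserved along the radius, so troughs are CSF-filled grooves (sulci)
  and crests are gyral crowns.  The phase derives from an integer seed by
  a fixed multiplicative-hash map (seed·2654435761 mod 2³², scaled to
  [0, 2π)), so identical seeds give bit-identical phantoms anywhere.
* **Slab** — a homogeneous box with plate electrodes, the Ohm's-law test
  bed: |E| = I/(A·sigma).

Three packaged "subject" presets (M1, M2, F) differ in outer radius
(94/90/84 mm) and skull thickness (7/5.5/4 mm), spanning the ranges that
plausibly drive inter-individual variation in adults.  They are
conventions chosen once, not reconstructions of any real anatomy: no
quantitative per-subject anatomy was available to copy.

What the phantoms deliberately do not model: realistic cortical folding
(the sinusoid is a single-wavelength caricature), anisotropic skull or
white matter, tissue heterogeneity within a class, and any specific
subject geometry.  Tests passing on phantoms therefore demonstrate solver
and metric correctness and mechanism-level claims (CSF channeling,
skull attenuation, ring containment), not subject-level field
predictions.

## Montages

* **Pad (motor–supraorbital)**: two 50×50 mm pads with 5 mm saline-sponge
  contact, anode at a C3-like angle (θ=45°, φ=180°), cathode at a
  contralateral supraorbital angle (θ=70°, φ=315°).  Default total
  current 1 mA.
* **4×1 high-definition ring**: a 12 mm central anode disc at the same
  scalp angle as the pad anode, four 12 mm cathode discs at 90°
  azimuthal increments, each 60 mm from the anode measured *geodesically
  along the scalp* (chord distance would understate separation on small
  heads); 2 mm gel contact.

Rasterization grows contact-medium voxels outward from the skin surface
following the exterior Euclidean distance field (which tracks the local
outward normal on any head shape), then one conductor layer (1 mm
nominal).  Contact/conductor thicknesses are physically typical values
recorded in code defaults; each band is at least one voxel thick at
coarse resolutions.  No tissue voxel is ever overwritten, overlapping
footprints are an error naming both electrodes, and the exterior
conductor faces where current is applied are recorded per electrode.

## Discretization and solver

Seven-point finite volume on the voxel grid.  The face conductance
between adjacent voxels is the harmonic mean of their conductivities
times face area over spacing (G = σ_h·h for cubic voxels of edge h, in
SI units).  Air voxels are retained at sigma = 1e-7 S/m rather than
masked, so the insulated boundary emerges physically; the outer grid
boundary is additionally zero-flux.

Boundary conditions: the anode's total current is applied as a uniform
Neumann flux over its exterior conductor faces ("resistive" mode); the
cathode conductor voxels are eliminated as Dirichlet ground.  Because the
conductor is metallic, the uniform-flux approximation is benign; an
alternative "equipotential" mode collapses the anode conductor into a
single floating-potential unknown carrying the total current.  The two
modes agree on tissue potentials to ~1e-7 relative on test phantoms.

The free-voxel operator is symmetric positive definite and is solved
with Jacobi-preconditioned conjugate gradients from a zero initial
guess to a true relative residual of 1e-6 (the iteration targets a
factor below that and restarts from the current iterate if the
recursive residual has drifted, so the *reported* residual always meets
the tolerance).  Fixed iteration order and zero start make solves
bit-reproducible.

Numerical choices worth knowing:

* **Conductor conductivity cap.**  Metal at 5.8e7 S/m spans ~15 orders of
  magnitude against air and breaks double-precision CG (observed residual
  floor ~4e-6 and solver breakdown).  Assembly clips conductivities at
  1e6 S/m.  A conductor at 1e6 S/m is still ≥6 orders above any tissue,
  i.e. equipotential to within ~1e-6, and the slab closed form confirms
  tissue fields are unchanged to ~1e-8 relative.  The conductivity table
  itself keeps the nominal metallic value.
* **Current audit.**  After each solve the discrete flux G·(V_in − V_out)
  is integrated over the closed voxel-face surface around each
  electrode's voxels.  Anode +I and cathode −I are recovered to ~1e-8
  relative; a symmetric polar 4×1 ring splits −0.25 mA per cathode to
  ~4e-8.  The audit uses the solved field, so it is an end-to-end check
  of assembly, boundary conditions, and convergence.
* **Singularity guard.**  Before solving, the non-air voxel graph is
  checked for a connected path between anode and cathode conductors.

## Field analysis

E = −grad V by central differences, switching to one-sided differences
(from the tissue side) where the stencil would cross into air, so scalp
fields are not contaminated by the near-insulating exterior.  One-sided
stencils are *not* used at interior tissue interfaces: they were measured
to increase the gray-shell error against the analytic oracle (they are
noisier, and the cell-centered potential already averages across the
interface), so interior derivatives stay central.

The operational cortical surface is the set of gray voxels 6-adjacent to
CSF.  Outward normals come from the negated, normalized gradient of a
Gaussian-smoothed (σ = 2 voxels) gray-matter indicator; on spheres they
align with the exact radial direction to <5° at the 95th percentile.
The signed normal component is reported as ef_normal = −E·n̂_outward, so
positive = inward (anodal, somatically depolarizing) current, negative =
outward — the convention is recorded on the map object.

## Metrics and dose normalization

* **Peak cortical EF** — the maximum |E| over cortical-surface locations
  (ties broken lexicographically), with a robust companion (99.9th
  percentile) because voxelized fields carry discretization spikes.  The
  raw maximum remains the headline number.
* **Fold variation** — max/min over per-head peaks; scale invariant.
* **Containment** — fraction of suprathreshold cortex (≥50% of the robust
  peak, a stated convention) whose radial scalp projection lies inside
  the ring's scalp disc.  On sphere phantoms the HD ring contains ≥99%
  while pads leave the majority outside the same disc.
* **Dose normalization** — scale_factor = reference_peak / subject_peak;
  normalized_current = base_current × scale_factor.  Exact by linearity;
  the round trip (re-solving at the normalized current) reproduces the
  reference peak to well under 1%.

## The analytic oracle

An independent closed-form check: an N-layer concentric sphere with two
point current electrodes on the scalp.  Per Legendre degree n the radial
profile in each layer is A(r/R)ⁿ + B(R/r)ⁿ⁺¹; coefficients propagate
core-outward through a per-degree 2×2 interface recursion written in
radius ratios (numerically stable to high degree), and the outer-surface
flux condition for a surface point source fixes the overall scale per
degree.  The n = 0 monopole cancels between the paired electrodes, so the
potential carries a free additive constant; comparisons against grounded
solves align means first.  Self-checks: the single-layer case matches the
known homogeneous-sphere closed form to machine precision; the analytic
gradient matches finite differences of the potential; V, tangential E,
and normal current density are continuous across interfaces; truncation
is monitored by a last-term bound and raises rather than silently
under-resolving.

## Validation results and known limitations

On the slab the solver matches Ohm's law to ~1e-8.  On a homogeneous
sphere it matches the oracle to 1.7% at 2 mm voxels.  On the 4-layer
sphere with the full conductivity contrast (skin 6 / skull 5 / CSF 3 /
gray 4 mm shells), the gray-shell relative L2 discrepancy against the
oracle is ~93% at 4 mm, ~18–21% at 2 mm, and ~9–10% at 1 mm voxels —
clean first-order convergence, but with a large constant that appears as
a systematic *transfer* bias (cortical fields uniformly high: ×1.17 at
2 mm, ×1.086 at 1 mm).

The bias is a staircase thin-shell artifact, not a defect of assembly or
of the oracle: it multiplies across shells (skull-only ×1.10, CSF-only
×1.06, skin-only ×1.03 at 2 mm), and vanishes when the contrast is
removed.  Mechanistically, the discrete network under-resists a thin
resistive barrier (current percolates through locally thin spots of the
voxelized skull) and the single-valued voxel potential short-circuits
interfaces.  Alternatives were measured and did not remove it:
direction-agnostic partial-volume conductivities make it worse
(arithmetic mixing destroys series resistance; harmonic mixing lets air
slivers insulate the scalp), subvoxel-integrated face conductances help
only the CSF term, and node-based trilinear hexahedral elements reduce
the 2 mm potential error to ~10% but remain staircase-limited.  Accurate
absolute transfer at mm resolution fundamentally wants a
geometry-conforming mesh, which is outside this package's voxel scope.

Consequences for use: *relative* quantities — fold variation across
heads, containment comparisons, dose-normalization ratios, montage
rankings — are insensitive to the shared transfer bias and are what the
phantom studies here report; absolute peak fields at coarse voxels should
be read as systematically high by the factors above.  The validation
runner (`tdcsim.validation.sphere_oracle_comparison`) recomputes these
discrepancies so the bias is measured, not assumed.

## Problem sizes

Tests and the acceptance script run at 2 mm voxels (grids ≈ 70–100³,
solves of ~10⁵–10⁶ unknowns converging in 600–1300 CG iterations, seconds
to half a minute each), chosen so the complete suite and script run on a
single CPU in minutes.  The same code paths run unchanged at 1 mm; the
1 mm numbers quoted above were produced with the identical pipeline.
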