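# Methods

This note documents the models implemented in `explode_orient`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Orientation statistics on SO(3)

Orientations are unit quaternions `q = (w, x, y, z)`; `q` and `−q` are the
same rotation. Haar-uniform sampling normalizes a 4D standard normal
vector onto S³. The relative orientation between two exposures is the
magnitude of the single axis–angle rotation between them,

    θ = 2 arccos(|w_rel|),   w_rel = Re[R_i R_j⁻¹] = ⟨q_i, q_j⟩,

where the absolute value folds the quaternion double cover so θ ∈ [0, π]
regardless of sign conventions, and the arccos argument is clamped to
[−1, 1] against floating-point drift.

For independent uniform rotations θ has density `p(θ) = (2/π) sin²(θ/2)`
on [0, π] (the normalized form; the same density is often quoted as
`½ sin²(θ/2)`, which integrates to π/4 — the constant
`UNNORMALIZED_PDF_FACTOR` converts between the conventions). The mean is
`π/2 + 2/π ≈ 2.2074 rad` in closed form; the median solves
`(θ − sin θ)/π = ½`, giving ≈ 2.3099 rad by a bracketing root-finder
(tolerance 1e−10). Any orientation-retrieval error that reaches ≈ 2.2 rad
is therefore indistinguishable from random guessing; we use the mean as
the saturation reference throughout.

## Synthetic structures

`synthesize_cloud` emulates a small protein as a globular random cloud:
atoms uniform in a ball of radius `(3n / 4πρ)^{1/3}` with
ρ = 0.11 atoms/Å³ (typical folded-protein atom density, hydrogens
included), a hard minimum interatomic distance of 1.0 Å (covalent-bond
order of magnitude, placed by dart throwing with a cell list), and
H/C/N/O/S composition 0.50/0.32/0.09/0.09/0.005 by atom count (average
protein stoichiometry). PDB input is supported through biotite for real
structures; clouds are always re-centered so the explosion origin is the
center of mass.

What the generator does **not** emulate: covalent topology, secondary
structure, side-chain packing, or any spatial element correlations. Real
proteins produce more structured, higher-contrast ion patterns (e.g.
sulfur and backbone-carbon jets) than these statistically isotropic
clouds, so retrieval results here are a conservative floor rather than a
forecast for real samples.

Structural heterogeneity between explosion realizations of "the same"
molecule is emulated by isotropic Gaussian coordinate jitter, default
σ = 0.3 Å per realization — the magnitude of thermal/conformational
variation is a free choice of this package, of the order of atomic
thermal displacements at room temperature.

## Ionization model

The X-ray pulse (default: fluence 5·10⁶ photons/nm², photon energy 2 keV,
Gaussian envelope peaking at 20 fs with 10 fs FWHM) is not resolved in
time. Charges are assigned once, before the dynamics (sudden
approximation): per-atom charges are Poisson with mean proportional to an
element weight (default: atomic number Z, so heavier atoms lose more
electrons), capped at the element's electron count. Because the cap —
mostly hydrogen's +1 — biases the realized mean downward, the means are
rescaled by a solved scalar (Brent's method on the expected capped total)
so that the expected average ionization equals the target exactly:
default 1.2 charges/atom, the "just above +1 per atom" regime in which a
protein is fully atomized, scaling linearly with pulse fluence relative
to the default.

The proportional-to-Z weighting is an assumption (exposed as a
configurable weight vector); nothing in the toy model pins how ionization
distributes across elements.

## Explosion dynamics

Velocity-Verlet integration from rest of pairwise Coulomb forces with
Plummer softening,

    V_ij = k q_i q_j / √(r² + ε²),   k = e²/4πε₀ = 14.3996 eV·Å,

default ε = 0.1 Å, time step 0.5 fs, maximum time 250 fs with early
termination once the remaining potential energy is below 1% of the total.
Only charged atoms participate (neutrals feel no force; they are excluded
from the ejecta by default, since they are never accelerated toward a
detector). Internal units are Å/fs/amu/e/eV; 1 Å/fs = 10⁵ m/s.

Numerical validation is by invariants rather than by copying any
reference integrator's step: total energy (kinetic + softened potential)
must be conserved within 5% or the run aborts advising a smaller step —
at the default step the drift is ~10⁻⁴ — and momentum stays at its
initial zero to rounding. The 0.5 fs step is appropriate because the toy
model contains no sub-femtosecond electron dynamics; the fastest motion
is a proton in a ~10 eV/Å field.

A known consequence of the sudden approximation: all the Coulomb energy
is present from t = 0, so ion speeds come out near the top of (and
slightly above) the 10⁴–10⁵ m/s range expected when ionization builds up
over tens of femtoseconds. A ~1000-atom cloud at 1.2 charges/atom gives a
median asymptotic speed of ≈ 1.5·10⁵ m/s.

## Virtual detector

Two flat square panels, side 120 mm, 18×18 pixels, at ±30 mm along the
lab z axis. Each asymptotic ion direction is ray-cast from the origin;
the panel intersection is binned by half-open intervals per axis with the
single top/right edge folded into the last cell ("nearest pixel center"
for an 18×18 grid of cell centers, with measure-zero ties resolved
deterministically — an exactly on-axis ray lands in cell (9, 9)). Rays
within 10⁻¹² of the detector plane or intersecting outside the square are
discarded; `n_detected + n_discarded = n_ions` always. The front panel
occupies rows 0–17, the back panel rows 18–35, both indexed by lab-frame
transverse coordinates (no mirroring) — the stacking and indexing
conventions are documented choices, required for pixel-space distances to
be well defined. Two panels at this geometry subtend 59.03% of the
sphere (analytic square solid angle), which the projection reproduces.

Detector efficiency is independent binomial thinning of each recorded
count. Blur is a per-panel 2D Gaussian (σ = 0.5 px default) with
constant-zero padding: panels are physically separate, so the kernel must
not leak across the stack boundary, and detectors have hard edges, so
intensity is preserved only away from panel borders. Blurred images are
float views, kept apart from raw integer footprints by type.

## Retrieval

Footprint distance is the plain Euclidean norm over all 648 stacked
pixels of raw counts (not normalized images); blur-before-distance is on
by default (σ = 0.5) because its stated purpose is robustness to small
spatial offsets, with a flag to disable. For N footprints all N(N−1)/2
pairs are formed; distances via `scipy.spatial.distance.pdist`, angles
from the stored ground-truth quaternions.

The distance axis is binned uniformly (default 100 bins spanning
[min d, max d]); the upper envelope takes the max angle per occupied bin;
the cutoff is the occupied-bin center at which the forward-difference
slope between consecutive occupied bins is largest, ties broken toward
the smaller distance. The slope over [c_k, c_{k+1}] is attributed to c_k,
so a step envelope yields the left edge of its jump. Pairs with
d ≤ cutoff give the retrieved count and mean angle; an empty retrieval is
flagged rather than averaged.

The argmax-of-derivative cutoff is a changepoint estimator applied to a
noisy envelope: at small pattern counts it is bistable between the
signal-tail/bulk boundary (desired) and a point inside the bulk's own
rising edge (which sweeps up nearly all pairs, returning the saturation
mean). Large pattern counts populate the small-distance tail — mostly
same-realization pairs at nearby orientations — and stabilize it; the
pooled analyses in the acceptance tests therefore combine the pairs of
five independent replicates before the envelope is built, or take medians
across replicates.

## Reproducibility variance and fluence robustness

Footprints of K fixed-orientation realizations are normalized to unit
total intensity; the per-pixel population variance (divisor K, as the
estimator is defined; at K = 100 the difference from K−1 is ~1%) is
averaged over pixels into a single scalar per structure. This scalar
drops steeply with atom count (roughly as the inverse detected-ion
count), which is the mechanism linking protein size to retrieval quality.
The fluence-robustness metric compares per-pixel mean raw-count images of
two fixed-orientation sets (summed and per-pixel mean absolute
difference, over all 648 stacked pixels); raw counts are used because the
quantity of interest is an ion-count error. The published ion-count error
values for this comparison come from a cluster-scale Monte-Carlo/MD
ionization code applied to a specific protein and are not reproducible
with this toy simulator; the metric, not those numbers, is what this
package provides.

## Pipeline, seeding, problem sizes

All stochastic stages draw from `numpy` `SeedSequence` streams addressed
by `(master_seed, stage, index…)` spawn keys, so any stage is
reproducible in isolation and under reordering. The full-scale defaults
(100 simulations × 100 patterns, efficiencies {0.3, 0.6, 1.0}, 100
envelope bins) mirror the reference study conditions; the packaged
experiments run scaled down — e.g. 50 explosion realizations × 20
orientations of a 3000-atom cloud for the end-to-end check, five
replicates of 10 realizations × 100 patterns for the efficiency trend,
and six realizations per size in {200, 800, 3200} atoms across five seeds
for the variance trend — sizes chosen so the whole suite runs on a single
CPU in minutes while keeping the statistical signal unambiguous.

## Known limitations

- Isotropic synthetic clouds understate pattern contrast; see above.
- The sudden approximation overestimates ion speeds by a small factor.
- At 30% detector efficiency, binomial thinning noise (variance
  2p(1−p)·N per pair) exceeds the attenuated pattern-difference signal
  (∝ p²) for the ~1000-ion footprints produced here, so the retrieved
  pair count at low efficiency is dominated by the cutoff estimator's
  bistability rather than by genuine matches. The mean-angle trend with
  efficiency survives aggregation across replicates; the pair-count
  trend need not, and the tests record this behaviour honestly.
- No time-of-flight, mass, charge or coincidence information is modelled
  on the detector; no diffraction-based reconstruction is included.
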