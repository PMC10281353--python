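# Methods

## Problem setting

A TMS pulse induces an electric field E(x) in cortex proportional to the coil
current rate of change (the stimulator intensity, A/μs). Whether a given
cortical neuron fires depends not only on the field magnitude at its soma but
on the distribution of field vectors over its dendritic and axonal arbor.
Biophysically detailed cable simulations predict activation thresholds well
but cost seconds per threshold; this package implements the fast alternative:
a 3D convolutional regressor that maps the local E-field, sampled on a small
cubic grid around the soma, directly to the threshold E-field magnitude, plus
the classical baseline that approximates the local field as uniform and looks
up a precomputed threshold–direction map.

Everything here runs at desk scale against *surrogate* neurons with
closed-form thresholds instead of cable models, so every estimate can be
checked against exact ground truth.

## Surrogate neuron model

Cable simulations show that TMS-evoked action potentials initiate at axon
terminals aligned with the local field, and that thresholds scale inversely
with local field magnitude. The surrogate distills this mechanism: a neuron
is a set of K terminals, terminal k at cell-frame position p_k with unit
direction û_k and sensitivity weight w_k (V/m). Under a field E(·) per unit
stimulator intensity,

    drive_k = max(0, E(p_k) · û_k),
    s*      = c_w · min_{k : drive_k > ε} w_k / drive_k        (A/μs),

with ε = 1e−9 V/m and c_w a per-waveform factor (monophasic 1.0, biphasic
1.15 — the surrogate has no temporal dynamics, so waveform identity enters
only as this scale, mirroring the fact that each trained estimator is
specific to one pulse shape). The soma-referenced threshold in V/m is
s* · |E(soma)|. If no terminal has positive drive, or s* exceeds a cap
(default 1e5 A/μs), the configuration is "not activatable" and is excluded
from datasets.

Properties inherited from the mechanism, used as test oracles:

* thresholds are exactly monotone in intensity (a valid spike oracle for the
  binary search);
* the V/m threshold is invariant to rescaling the field source;
* a single-terminal neuron under uniform fields has threshold
  w·c_w / cos(angle to û) — the familiar direction anisotropy;
* thresholds depend on the field *away* from the soma (terminals sit up to
  0.45·l from the origin), which is precisely what the uniform-field baseline
  cannot represent.

Default terminal counts are 8 (L2/3-like), 12 (L4-like), 10 (L5-like), with
weights drawn from 75–200 V/m; positions are confined to a cube of half-side
0.45·l so the sampling grid always covers every potential initiation site.
Terminal directions are jittered Fibonacci-sphere points under a seeded
random pose rather than i.i.d. random: real axonal arbors point every which
way, so threshold–direction maps of cable models are finite everywhere,
whereas i.i.d. directions can leave parts of the sphere uncovered and create
non-activatable field directions with unbounded threshold tails.
"Clones" are seeded Gaussian jitters of terminal positions (5% of l),
directions (renormalized) and log-weights, emulating morphological variants
with identical biophysics.

## Coordinate conventions and grid sampling

Each neuron carries a right-handed frame: ẑc the somatodendritic axis (inward
surface normal on the cortical sheet), x̂c a stored azimuth reference seeded
per placement, ŷc = ẑc × x̂c. Azimuthal rotation j ∈ 0..11 rotates x̂c/ŷc by
30°·j about ẑc; both the neuron's terminals and the sampling grid co-rotate.
The tensor fed to the estimator holds field vectors at the N×N×N lattice
(side l, centre exactly the soma) expressed in the *rotated* frame, so
co-rotating field and grid leaves the tensor invariant to machine precision —
the property that makes the 12 rotations valid data augmentation, verified
to 1e−9 in tests.

Tensors are normalized by the centre-voxel magnitude (stored so device
intensities can be recovered); the optional spherical representation
(|E|, θE, cos φE, sin φE) is computed *after* normalization, making its
magnitude channel relative. The ordering is exposed by composing the two
operations; at poles (tangential component < 1e−12) the azimuth channels are
fixed to (1, 0). θE is in radians.

Grid defaults: N = 9, l = 2.0 mm for L2/3-like cells and 1.5 mm for L4/L5-like
cells.

## Field sources

All sources return V/m per A/μs. The figure-of-eight coil is emulated by two
opposite-moment rings of magnetic dipoles (primary induced field only,
E = −(μ0/4π) Σ m_d × r / r³ · dI/dt); the secondary charge field of the
volume conductor is deliberately omitted — training needs realistic spatial
structure, not FEM fidelity. Default moments give ~160 V/m per A/μs at
15 mm below the coil centre, the right order for motor-threshold TMS.
Point-source fields (I r̂ / 4πσr², σ = 0.275 S/m gray matter) provide the
microstimulation analogue, with an exclusion radius of 1e−6 mm. Scattered
tabulated fields are interpolated by a local affine least-squares fit over
the k = 10 nearest samples; this is our reading of "linear interpolation from
the 10 nearest points" (a global scattered interpolant restricted to 10
neighbours is not a single well-defined scheme); rank-deficient
neighbourhoods fall back to inverse-distance weighting.

## Threshold search

`binary_search_threshold` brackets the monotone spike oracle (doubling the
upper bound up to the cap), bisects at the *geometric* midpoint (natural for
a relative window), stops when hi/lo ≤ 1.02 (2% window) and returns the upper
bound — the smallest intensity known to fire — so the result lies in
[s*, 1.02·s*]. The bracket start and the upper-vs-midpoint return are design
choices documented here; tests pin the returned value into that interval on
1,000 random configurations.

## Convolutional estimator

Architecture (best hyperparameter set): four unpadded stride-1 Conv3D layers
of 3×3×3 kernels and a shrink-rate-0.8 filter schedule 115, 92, 74, 59
(round-half-up of 115·0.8^(i−1)); flatten; dense layers 57, 46, 36 (same
rule); one linear output unit — the soma-referenced threshold in V/m. For a
9×9×9 input the conv feature maps have spatial edges 7, 5, 3, 1. Smaller
grids are handled either by shrinking the kernel to 2 (and the conv stack to
two layers for N = 3) — "variable" — or by trilinear upsampling to 9³ with
the architecture unchanged — "constant".

The network is implemented directly on numpy arrays: im2col unfolding plus a
single GEMM per conv layer (float32), hand-written backward pass, Adam
(β1 = 0.9, β2 = 0.999, ε = 1e−7), Xavier-uniform initialization, MSE loss,
mini-batches of 62, early stopping on validation loss (patience 30,
min_delta 0) and learning-rate reduction lr ← lr/5 on 15-epoch plateaus.
Dropout and batch normalization are available behind flags but default off.
Weights giving the best validation loss are restored at the end, and the
recorded final validation loss is re-evaluated on the served weights.
Training is bit-reproducible for a fixed seed (single-threaded BLAS).

Two numerical choices that matter in practice:

* labels are standardized internally (mean/std of the training labels,
  undone at prediction) — without this, Adam spends thousands of steps
  moving the output bias to the label scale;
* `label_transform="log"` fits log-thresholds, approximately optimizing
  relative error; recommended (and used by the benchmark) because threshold
  distributions are heavy-tailed near field directions orthogonal to all
  terminals, and the accuracy measure of interest is percent error.

The hyperparameter random search samples uniformly from the documented
tuning ranges (learning rate log-uniformly), trains each candidate on a
third of the training set, resamples infeasible configurations (spatial
collapse) with a logged count, and ranks by final validation MSE.

## Uniform-field baseline

Thresholds for uniform fields at all (θ, φ) on a 5° lattice (2522 unique
directions; poles deduplicated, pole rows stored replicated) form a
threshold–direction map per neuron. Estimation rotates the somatic field
vector into the cell frame, computes (θ, φ), and interpolates the map
bilinearly with explicit azimuthal wraparound (the φ = 360° column reuses
φ = 0°); wraparound is a deliberate deviation from a plain gridded
interpolant, which would otherwise extrapolate across the seam. Dividing the
V/m threshold by |E(soma)| per A/μs gives the stimulator intensity. The
uniform-field extracellular potential Ve = −|E|(x sinθcosφ + y sinθsinφ +
z cosθ) mV (soma at zero) is provided for completeness and tested against
direct evaluation.

## Field-characterization metrics

The gradient metric is the Frobenius norm of the per-node field Jacobian
(all nine ∂E_a/∂b), median over all N³ nodes (face nodes included), with
central differences inside and one-sided differences at faces — exact for
affine fields, rotation-invariant. In center-normalized mode the field is
first divided by the centre magnitude (units 1/mm). Site errors compare a
trilinearly interpolated vector with the actual one: absolute percent
magnitude error (the signed value is also exposed) and angle error via a
clamped arccos, with a π sentinel for a zero interpolated vector. Threshold
summaries are MAPE, median APE, and the R² of an ordinary least-squares
regression of predicted on actual.

## Synthetic benchmark

The end-to-end benchmark emulates the full study at desk scale, all
randomness derived from one seed:

* cortical sheet z = A cos(2πx/λ) with A = 3 mm, λ = 20 mm over a 30×30 mm
  rectangle, gray-matter thickness 2.5 mm, layer depths L2/3 0.4, L4 0.5,
  L5 0.75; somas placed by jittered stratified sampling, axes along the
  inward normal, seeded random azimuth references;
* figure-of-eight dipole coil 12 mm above the sheet's mean surface; two
  stimulation directions (P–A and the sign-flipped A–P);
* seeded "cortical scatterers": 80 small dipoles just above the sheet
  surface superimposed on the coil field. FEM solutions contain
  short-wavelength structure from charge accumulation at tissue boundaries
  that a primary-only coil field lacks entirely. The scatterers reinstate
  that spectrum phenomenologically: at soma depth they perturb the primary
  field by ~12% (median; 90th percentile ~19%) with a 2–3 mm correlation
  length set by their clearance above the surface. They are part of the
  per-seed head model, shared by the train and test populations embedded in
  it;
* one L5-like surrogate (10 terminals), N = 9, l = 1.5 mm, Cartesian
  channels, normalized tensors;
* training set of 5,000 records (positions × 2 directions × 12 rotations,
  subsampled), 85/15 train/validation split stratified by direction;
  1,000 test records from a disjoint seeded population;
* desk-scale training configuration: the same architecture family and
  schedules as the best set, with width and optimization scaled to a
  single-CPU budget (24 first-layer filters, 32 first-layer dense units,
  initial learning rate 2e−3, ≤ 25 epochs, log-label fitting);
* the uniform baseline interpolates the per-neuron 5° map at the somatic
  field vector recovered from each test tensor's centre voxel.

Smaller configurations of the same pipeline (1,000 training records, 15
epochs, 16 filters) drive the representation comparisons (Cartesian vs
spherical channels; N = 3 vs N = 9), where only relative ordering of MAPE
medians over five seeds is asserted.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the problem: smooth vector
fields with realistic magnitudes and gradients, cell-centred coordinate
conventions, rotation augmentation, direction-dependent thresholds driven by
off-centre field values, heavy-tailed threshold distributions, and
degenerate (not-activatable) records. It does not reproduce FEM fields'
tissue-boundary discontinuities and CSF exclusion, real axonal morphologies,
temporal membrane dynamics (waveform effects are a scale factor here), or
cross-head-model anatomical variation. Passing benchmarks therefore
demonstrates that the estimators and pipeline are implemented correctly and
that the convolutional estimator exploits spatial field structure a
soma-only method cannot; they do not certify accuracy numbers on real
cortical anatomy.

One empirical property of these conditions deserves emphasis: the benchmark
field's correlation length (≥2 mm, set by coil distance and scatterer
clearance) is above the sampling-grid scale, so even the coarsest 3³ grid
retains essentially all threshold-relevant field information, and — being a
27-fold smaller input — can train to an equal or lower error than the 9³
grid. A resolution *penalty* for coarse grids requires field structure below
the grid spacing, which in real head models comes from tissue-boundary
effects that this generator only emulates at longer wavelengths. The suite
asserts the resolution ordering anyway and currently documents this gap as a
failing check rather than hiding it.

## Known limitations

* The numpy training loop is tuned for desk-scale datasets (≲10⁵ records);
  full-scale training would need a GPU backend behind the same interfaces.
* The dipole-coil field is curl-only (primary); fields near conductivity
  boundaries are out of scope.
* The uniform baseline's accuracy here is better than on real anatomy
  because the synthetic field is smooth; the benchmark asserts ordering
  (CNN < uniform), not the published error magnitudes.
* Not-activatable records are dropped rather than modelled; estimators never
  see them.
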