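# Methods

`pirwatch` implements an unsupervised abnormal-activity detector for
ceiling-mounted, FOV-modulated pyroelectric infrared (PIR) sensor nodes,
together with a physics-inspired simulator that stands in for volunteer
recordings.  This note documents the models, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## Sensing model

A node at height `h` observes a ground disk of radius `R = 3 m`.  Opaque masks
partition the disk into `L` sampling cells with pairwise-distinct binary
visibility signatures: fan masks restrict a sensor to one angular sector
(excluding a central occlusion disk of radius 0.3 m that fan-masked sensors
cannot see), ring masks shrink the cone so a sensor sees only radii below its
projected ring radius (central disk included).  With 4 fan masks and ring radii
(2.4, 1.6, 0.8) m this gives `M = 7` sensors, `L = 4 x 4 + 1 = 17` cells: one
one-hot sector bit pattern times four nested ring-membership patterns, plus
the no-fan/all-rings central cell.  The node output is

    m(t) = quantize( V (h * S)(t) + noise ),

where `V` is the binary 7 x 17 visibility matrix, `S_i(t)` the thermal flux
from cell `i` (target intensity times the overlap fraction of the body
footprint disk with the cell, evaluated on a fixed mirror-symmetric point grid
so fractions sum exactly to the in-FOV fraction), and `h` the PIR channel
response.  `h` is a first-order high-pass (0.1 Hz) cascaded with a first-order
low-pass (5 Hz), peak gain normalized to 1: a pyroelectric element responds
only to radiation *change*, so exact zero DC gain is the defining property;
filters are initialized at steady state so a target already present at t = 0
produces no turn-on artifact.  Quantization is signed 8-bit, half-to-even,
with full scale 2.0 amplitude units; sensor noise is white Gaussian with
standard deviation 0.02 (about 1.3 LSB).  Sampling rate is 25 Hz.

### Synthetic activity campaign

The default dataset emulates a recording campaign of 8 subjects x 5 activities
(falling, sitting down, standing up, walking, jogging) x 10 repetitions = 400
recordings, 80 of them falls.  Kinematics (chosen once, as plausible magnitudes
for a 3 m-radius monitored area; they claim no fidelity to any particular
hardware):

- walking: straight chord at 0.8–1.2 m/s, random direction, perpendicular
  offset U(0, 1.5) m, entering and leaving 0.3 m outside the FOV;
- jogging: the same path model at 1.8–2.5 m/s;
- sitting down / standing up: fixed random position (r in 0.5–2.0 m), a
  1.5–2.5 s linear intensity ramp between 1.0 and 0.55 (body cross-section
  seen from the ceiling), with a 0.3 m shift;
- falling: a 0.4–0.7 s transient at r in 0.3–1.8 m with 0.5–1.0 m radial
  displacement, intensity ramping to 1.4 and footprint radius doubling
  (body elongation on the ground).

Each subject carries intensity (U(0.85, 1.15)), speed (U(0.9, 1.1)) and
footprint (U(0.22, 0.28) m) factors.  Each recording has 1 s of stationary
lead-in/tail.  Every location, heading and duration is redrawn per repetition,
so normal activities are deliberately *not* location-locked.

What the simulator does not model: Fresnel-lens optics and pyroelectric element
physics, 3-D occlusion, multiple simultaneous targets, and any amplitude
calibration to real hardware (amplitudes are arbitrary units).  Passing tests
therefore demonstrate the pipeline's behavior on streams with realistic
spatio-temporal *structure*, not performance on real recordings.

## Segmentation

Short-time energy: channel-pooled sum of squares over 0.5 s windows with
0.25 s hop.  Runs of frames above threshold are merged across gaps below 0.5 s
and dropped below 0.6 s.  The default threshold is 5x the noise floor, with the
noise floor estimated as the median energy of the quietest quarter of frames —
robust even when active frames dominate a recording.  In the experiment
runner, each recording is known to contain exactly one emulated repetition, so
the single highest-energy segment is taken as that recording's sample (a
walking pass through the central occlusion disk can silence the node for over
half a second and would otherwise occasionally split one repetition in two).

## Sequence modeling and distances

Each activity sample (7 x T integer matrix) is modeled by a hidden Markov
model with diagonal-covariance Gaussian-mixture emissions, trained by
Baum–Welch.  Numerical choices: k-means initialization of state means with
seeded jitter, uniform-plus-jitter start/transition/weight distributions; all
discrete distributions floored at 1e-10 and renormalized (exact zeros make
later cross-scoring degenerate and the perturbation is orders below the EM
monotonicity slack); covariance floor as a constrained M-step, which preserves
monotonicity of the training log-likelihood; convergence on absolute
log-likelihood change.  The forward likelihood has two independent
implementations (scaled linear-domain and log-space) that agree to rounding
error; batch scoring pads sequences and runs the log-space recursion
vectorized.

In the pipeline the covariance floor is 1.0 squared ADC code units — the scale
of quantization plus sensor noise — rather than an arbitrarily small number:
a floor far below the intrinsic noise admits near-delta emission densities on
quiet channels, and the resulting likelihood explosions destroy the distance
geometry below.

The likelihood matrix has entries `l[i,j] = log P(Y_j; lambda_i) / T_j` over
per-sequence models.  **Per-sequence (embedding) models default to 3 states,
1 mixture** — much smaller than the 8-state/2-mixture profiling models.  This
is deliberate: the normalized likelihood columns (softmax over models,
computed with log-sum-exp) are only informative if models generalize across
sequences.  Per-sequence models as large as the profiling models memorize
their own segment, every column collapses to one-hot, all pairwise symmetrized
KL divergences saturate at the floor-determined ceiling `ln(1/1e-12) = 27.6`
nats, and the affinity graph degenerates to a structureless complete graph.
The pairwise distance is the symmetrized KL divergence between columns, with
both pdfs floored at 1e-12; the identity
`sym-KL(p,q) = 1/2 sum (p-q)(log p - log q)` makes the matrix exactly
symmetric and hollow.

## Self-tuning spectral clustering

Affinity `exp(-d_ij^2 / (sigma_i sigma_j))` with local scales `sigma_i` = the
distance to the 7th nearest neighbor (K = 7, the value used in the local-
scaling literature); symmetric normalized Laplacian; for each candidate count
c = 2..10 the top-c eigenvectors are rotated toward a cluster-indicator matrix
by minimizing the alignment cost `J = sum_ij Z_ij^2 / max_j Z_ij^2` over a
product of c(c-1)/2 Givens rotations.  Details that matter:

- every row contributes at least 1 to J (a row outside the span of the chosen
  eigenvectors counts exactly 1), so `N <= J <= N*c` holds even on exactly
  disconnected graphs; without this, unspanned rows bias selection toward
  small c;
- optimization is incremental gradient descent on the angles (analytic
  gradient with the per-row argmax held fixed), step 0.1 halved on cost
  increase, at most 200 sweeps, 1e-6 relative tolerance; each candidate c is
  warm-started both from the previous candidate's rotation and from a greedy
  initialization that orthonormalizes c mutually most-orthogonal rows of X
  (the better result is kept);
- eigenvalues are sorted descending and eigenvector signs canonicalized for
  reproducibility;
- the selected count is the *largest* candidate whose cost ties the minimum
  within 1e-6·N.  The tolerance only absorbs floating-point noise: above the
  true cluster count the cost curve is nearly flat (splitting a clean cluster
  across two indicator columns costs almost nothing), so any looser band
  drags the selection to c_max on well-separated data;
- c = 1 is never scored (the cost is degenerate there); single-cluster data
  returns 2.

## Anomaly detection

One 8-state/2-mixture HMM is fitted per discovered cluster (the setting
reported for profiling models), and every sample is mapped to the
C-dimensional vector of its raw forward log-likelihoods under the cluster
models.  Raw (not length-normalized) log-likelihoods are kept deliberately:
event duration is itself discriminative (falls are brief), and length-
normalized variants measurably weaken detection.

The normal profile is a one-class SVM in its support-vector-data-description
reading: the minimal sphere in RBF feature space containing most of the
training vectors, with nu = 0.01 bounding the outlier fraction.  Features are
standardized per component with training statistics; the kernel width follows
the median heuristic `gamma = 1 / (2 median ||x_i - x_j||^2)` (a local-scaling
variant and full whitening were both evaluated and degraded detection; an
optional log-magnitude compression of the features is available for heavy-
tailed likelihood scales but is off by default).  The dual problem — box bound
1/(nu·n), coefficients summing to one, which is the feasible standard
parameterization of the sphere dual — is solved by libsvm through
scikit-learn; the sphere radius is read off the boundary support vectors
(median, for robustness) and the continuous score `R^2 - ||phi(x) - a||^2`
(negative = abnormal) is retained for ROC sweeping.  The radius shifts scores
but never changes their ranking, so AUC is unaffected by its estimate.

The OneHMM baseline fits a single 8-state/2-mixture HMM to all normal
training samples and scores test samples by length-normalized log-likelihood.

## Evaluation

Abnormal (fall) is the positive class.  Detection rate TP/(TP+FN) and false
alarm rate FP/(FP+TN); ROC by full threshold sweep (ties grouped) and AUC by
trapezoid, equivalent to the tie-corrected Mann–Whitney statistic.  Scores are
oriented larger-is-more-normal at the interface and flipped internally.

## Experiment protocol and reproducibility

The default experiment generates 400 recordings, extracts one sample each,
removes all falls from the training pool, draws 240 normal samples for
training, and tests on the remaining 80 normals mixed with all 80 falls.
Training never sees activity labels; the runner itself enforces the
normals-only filter.  A single global seed fans out to per-stage seeds through
a fixed `SeedSequence((global_seed, stage_index))` rule, so every stage is
independently reproducible and two runs with equal (config, seed) produce
byte-identical result reports.  EM fits in the pipeline cap at 20 iterations
(tolerance 1e-3): segment-scale sequences converge within a handful of
iterations and the cap keeps the full experiment at roughly half a minute.

## Known limitations

- Because every repetition redraws its location and heading, normal activities
  are not compact in likelihood space (two walks along different chords excite
  nearly disjoint channel subsets).  The discovered clusters mix activity
  identity with coarse location, and held-out normals at unseen locations are
  the dominant false-alarm source; typical end-to-end AUC against the OneHMM
  baseline is roughly 0.75–0.9 vs 0.6–0.75 across seeds.  Location-locked
  activities (a fixed chair, habitual paths) would be easier and arguably more
  realistic for a single monitored room.
- The alignment-cost selection inherits the known flatness of J above the true
  cluster count; selection on heavily degenerate geometry is best-effort.
- The simulator's amplitude scale is arbitrary; nothing here calibrates to a
  physical sensor chain.
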