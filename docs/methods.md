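# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `connectoscan` — what each stage assumes, which knobs matter,
and what the synthetic test surfaces do and do not establish about real data.

## Diffusion tensor model and fit

Each voxel's diffusion-weighted signal is modelled by a single symmetric
positive-semidefinite tensor D (mm²/s):

    S_k = S0 · exp(−b_k · g_kᵀ D g_k)

The fit is ordinary least squares on the log-linearised system
−ln(S_k/S0) = b_k g_kᵀ D g_k over the six unique tensor elements, using the
pseudoinverse of the b-weighted design matrix.  With a full-rank single-shell
scheme (the default table has 15 approximately uniform hemisphere directions
at b = 800 s/mm² plus one b = 0 volume) this estimator is exact on noiseless
data and is the conventional choice for clinical acquisitions; weighted or
nonlinear estimators would matter only at low SNR and are out of scope.
Multiple b = 0 volumes are averaged before fitting.  Degenerate voxels
(any non-positive signal) are flagged invalid and carry a zero tensor;
negative eigenvalues are clamped to zero before FA/MD with a per-voxel flag,
which keeps FA in [0, 1].  All-zero eigenvalues define FA = 0 rather than
NaN so masks built from FA never propagate NaNs into tracking.

An independent cross-check in the test suite fits the same voxels by
nonlinear least squares on the exponential model (scipy) and agrees with
the log-linear fit to < 1e−6 on FA and MD.

## TEND tractography

Tracking is deterministic.  Seeds are all voxels with FA strictly above
0.3 (one seed at each voxel centre); each seed launches two half-tracks
along ±e₁.  The propagation rule is tensor deflection:

    v_out ∝ D · v_in   (sign aligned with v_in)

exposed in generalised form f·e₁ + (1−f)·((1−g)·v_in + g·D̂·v_in) with
defaults f = 0, g = 1 (pure deflection) since the weighting of the blended
variant is a free design choice.  A half-track terminates on: local FA
strictly below 0.2; a turn between successive step directions exceeding
60°; leaving the grid; or reaching `max_steps` (default 2000).  The stop
test is applied to the *candidate* next position before it is appended, so
streamline endpoints always lie in suprathreshold voxels — this makes
endpoint-to-region assignment well defined.  The junction between the two
half-tracks is exempt from the curvature test (they depart at 180° by
construction).

Tensor lookup is nearest-voxel: world coordinates map through the inverse
affine and round to the nearest integer index, i.e. half-open cells
[i−0.5, i+0.5) centred on voxel centres.  The same convention is used for
endpoint-to-label assignment, so tracking and network construction cannot
disagree about which voxel a point is in.  Trilinear interpolation is
deliberately not the default: the stop rules are phrased per voxel.

Step size defaults to half the smallest voxel dimension (sub-voxel
stepping); tracking runs in world millimetres so anisotropic voxels are
handled through the affine.

### Why the sharp-bend phantom uses a stick-like tensor

Pure deflection can turn by at most 90° − 2·atan(√(λ₂/λ₁)) in a single
step: the deflected direction of a unit vector at angle θ to the fibre axis
lies at atan((λ₂/λ₁)·tanθ), and the difference is maximised at
tanθ = √(λ₁/λ₂).  With the generic bundle eigenvalues (1.7, 0.3, 0.3)·10⁻³
that bound is ≈ 45°, so no single step can ever violate a 60° curvature
limit — the tracker would round any corner gradually or slide out of the
bundle.  The sharp-bend phantom therefore uses (1.7, 0.05, 0.05)·10⁻³
(bound ≈ 70°) and a 75° bend, which guarantees that a streamline crossing
from one leg into the other makes a single ≈ 69° turn and must stop with
reason `curvature`.  This is a property of the deflection rule itself, not
an artefact of the phantom.

## Parcellation

Probabilistic atlases are thresholded at 35% membership probability
(strict), and a voxel passing for several regions takes the argmax, ties to
the lowest region index — this yields deterministic, non-overlapping
regions.  Label volumes are resampled into native space by nearest-neighbour
through a supplied affine; points mapping outside the source grid become
background, and no new label value can ever be created.  Registration
*estimation* is out of scope: the affine is an input (identity for
phantoms).

## Network construction

For connection threshold m (default 1; 3 and 5 supported for sensitivity
analyses): n_ij counts streamlines whose two endpoints lie in regions i and
j (background or same-region endpoints contribute nothing); n_all is the
total number of streamlines launched, including unlabelled ones, because
fibre density is a fraction of the subject's whole-brain fibre count.
Density cd_ij = n_ij/n_all, so the upper-triangle density sum is ≤ 1 with
equality only if every fibre connects two distinct regions.  FA_ij and
MD_ij average over the deduplicated union of voxels visited by the edge's
streamlines — each voxel counted once, so a streamline lingering in one
voxel does not dominate the mean; whether the original formulation weights
by visit multiplicity is unknowable, and this choice is the stable one.
Edges failing the m-threshold are exact zeros in all attributes, giving
fixed-length feature vectors in which 0 means "no measured connection".
Raising m can only remove edges and never changes a surviving edge's value.

## Information-gain feature selection

Features are single edges of one attribute (cd, fa or md; attributes are
never mixed), vectorized in (i, j)-lexicographic upper-triangle order.
Information gain of a continuous feature is computed by supervised
discretization: sort by feature value, consider cuts between adjacent
distinct values, take the entropy-minimising binary cut, and recurse,
accepting deeper splits only under the Fayyad–Irani MDL criterion

    gain > [log₂(N−1) + log₂(3^k−2) − k·H(S) + k₁·H(S₁) + k₂·H(S₂)] / N.

IG is the class entropy minus the weighted entropy of the final bins
(base-2 logarithms, bits).  It depends on the feature only through its
ordering, hence is invariant to strictly monotone transforms, and is
bounded by H(labels).

Two variants are exposed because they serve different purposes:

* `information_gain(..., force_top_cut=True)` (default) always applies the
  best top-level cut when one exists and lets MDL gate only the recursion.
  This measures the best single split even on tiny samples (e.g. labels
  A,A,A,B with feature 0,0,1,1 give 0.8113 − 0.5 = 0.3113 bits).
* `select_features` uses `force_top_cut=False`: the MDL criterion gates
  *every* split, so a feature whose best cut does not pay its description
  length scores exactly 0 and is dropped.  This is what makes selection
  sparse on noise edges — on the synthetic planted cohorts roughly the
  planted set plus ~1 spurious edge survives per fold — and sparsity, not
  tiny-sample scoring, is the point of selection.

Default selection keeps all features with positive (MDL-gated) gain; a
`top_n` is available but note that on mostly-zero gain vectors it fills up
with tie-broken zero-gain features, which makes round-to-round selection
counts meaningless.  Selection-frequency reports count, per edge, the
validation rounds in which it was selected; edges with count strictly
greater than 5 are "highlighted" as stable discriminative connections.

## Classifiers

All three operate on the selected edge features and have fully
deterministic, documented tie rules.

* **Max-margin (SVM)** — linear soft-margin, primal ½‖ω‖² + C·Σε_k with
  C = 1 by default (the typical choice when nothing is known; n ≪ p makes
  regularisation mild).  Features are standardised by training-fold
  mean/sd (sd floor 1e−12).  The quadratic programme is solved by
  scikit-learn's SVC (libsvm, tol 1e−8).  Prediction is sign(ωᵀx + b)
  with 0 mapped to the positive class.  A linear kernel is the default
  because edge-feature dimensionality already exceeds subject counts.
* **Pearson k-NN** — similarity is the Pearson correlation between the
  subject's and each training subject's feature vector; k = 6.  Majority
  vote; vote ties break by larger summed similarity, then by the class of
  the single most similar neighbour.  Constant vectors correlate 0 with a
  warning.  Correlation makes predictions invariant to per-subject affine
  rescaling of the features.
* **Gaussian naive Bayes** — argmax_c log p(c) + Σ_i log N(x_i; μ_ci, σ²_ci),
  computed in log space; per-feature variances floored at 1e−9 of the
  pooled variance.  Exact posterior ties go to the larger prior, then the
  lower class index.

## Validation protocol

Folds are stratified by class and shuffled with the experiment seed;
10-fold is the default, leave-one-out available.  If the smaller class has
fewer members than folds, the fold count is reduced with a warning.  Within
each round, discretization, selection and training use only the training
subjects; each test subject is predicted exactly once; accuracy is pooled
correct/total across rounds.  Pooling (rather than averaging fold
accuracies) is deliberate: it makes every reported accuracy an integer
multiple of 1/n_subjects, which is also the granularity at which such
results are conventionally reported, and it is well defined for unequal
fold sizes.  An empty selection falls back to all features (logged) so the
classifiers always receive input.  The entire run is a pure function of
the cohort and the seed.

`type_one_check` runs the full protocol on cohorts generated with no group
effect and compares the mean pooled accuracy to the 95% binomial interval
around 0.5 (n = total pooled predictions).  This is a leakage alarm: any
use of test subjects during selection or training inflates null accuracy
far outside that interval.  Measured means with the default configuration
are ≈ 0.50 for all three classifiers over 50 repeats.

## Synthetic data: what it emulates, what it does not

**Bundle phantoms** place a tube (straight / arc / sharp bend / two
orthogonal crossing bundles) of anisotropic tensors (FA ≈ 0.80 inside,
≈ 0.08 outside — validated against the seed/stop thresholds at
construction) in a small grid, forward-simulate the 16-volume single-shell
acquisition exactly, and optionally add Rician noise as
|S + ε_re + i·ε_im| with per-channel sd = S0/snr — the standard MR
magnitude-noise model.  End-caps of each bundle are labelled as regions.
The phantoms establish correctness of fitting, tracking geometry, stop
rules and endpoint bookkeeping.  They do not emulate: crossing-fibre
partial volume beyond a hard overlap (the crossing phantom assigns the
first bundle's tensor in the overlap), susceptibility or eddy distortion,
realistic head geometry, or spatially varying SNR.  Passing them shows the
algorithms implement their definitions, not that tracking is anatomically
accurate in a brain.

**Network cohorts** draw two groups of symmetric R×R matrices (defaults:
R = 16, 20+20 subjects, 90% edge presence on a shared skeleton).  Each
attribute has a cohort-level per-edge baseline profile (heterogeneous edge
strengths, as real connectomes have) plus per-subject Gaussian noise
(FA 0.45 ± 0.05, MD 0.8 ± 0.08 ×10⁻³ mm²/s, densities normalised to sum
to 1 per subject).  A configurable number of edges (default 10) carries a
planted standardized shift (default d = 2) in group 2, signed in the
degenerative direction: density and FA down, MD up.  The planted-edge
identities are returned for recovery testing.  The cohorts establish that
the selection/classification protocol detects multivariate group structure
and stays at chance under the null; they do not emulate site effects,
age/sex confounds, non-Gaussian attribute distributions, or effects
correlated across edges.

## Known limitations

* **Pearson k-NN vs uniform effects.**  Per-vector centring makes Pearson
  similarity exactly blind to a shift that is uniform across the feature
  vector.  When selection is precise — which the MDL gating makes it — the
  selected features are almost exactly the planted set, whose shift *is*
  uniform by construction, so the k-NN cannot exceed ≈ 0.8 pooled accuracy
  on the planted cohorts no matter how large the effect, while SVM and NB
  sit at ≈ 0.99.  Enlarging the selected set dilutes this blindness but
  destroys the precision of the selection report.  On real data,
  connection-wise effect sizes are heterogeneous and the blindness is
  correspondingly partial; the synthetic uniform-shift cohort is the
  worst case for this classifier.
* Gaussian NB degrades when an attribute's distribution is made degenerate
  by clipping (e.g. densities clipped at zero under an extreme planted
  shift): the 1e−9 variance floor then produces near-singular likelihoods.
* The tensor model itself cannot represent crossing fibres within a voxel;
  in the crossing phantom the overlap region belongs to one bundle.
* Tracking accuracy in anisotropic-voxel grids depends on the nearest-voxel
  lookup; trilinear interpolation of tensors is not implemented.
* The pipeline consumes registration transforms; it never estimates them.
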