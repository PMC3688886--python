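# Methods

## Model

`likefusion` segments a target T1-weighted volume `I` over a voxel lattice
into `K` labeled structures plus generic tissue classes, given `N` atlases
(intensity volume + expert labels).  The generative model is the multi-atlas
random orbit model: each atlas chart (one labeled structure with its own
intensity mean and variance) is carried onto the target by an unknown
diffeomorphism, and the observed image is a conditionally Gaussian random
field given the deformed charts,

    I(x) | W(x)=k, A(x)=a  ~  Normal(mu_{a,k}, sigma^2_{a,k}),

where `W` is the latent segmentation field and `A(x)` the latent per-voxel
*atlas selector* saying which atlas generates voxel `x`.  Conditioned on the
labels, voxels are independent.  Each atlas also contributes an interpolated
label prior `pi_a(k|x)`: the one-hot indicator of its propagated labels in
chart interiors, linearly interpolated at boundaries.

Diffeomorphisms come from LDDMM: time-indexed velocity fields `v_t` with the
Sobolev norm induced by `L = (-alpha * laplacian + gamma)^p`, integrated via
`dphi/dt = v_t(phi_t)`.  Matching an atlas to the target minimizes

    E(v) = (1/T) * sum_t <L'L v_t, v_t>  +  (1/sigma^2) * || I_atlas o phi^-1 - I ||^2.

The integral over deformations in the likelihood is replaced by its mode
(one optimized `phi_a` per atlas, computed once and reused), and the selector
is marginalized by EM.  The E-step produces per-voxel convex weights
`q(x, a)` — conditional means of the selector indicators — from each atlas's
log-likelihood aggregated over a local window (chart-local evidence); the
M-step maximizes the fused score

    S(x, k) = sum_a q~(x, a) * [ log Normal(I(x); mu_{a,k}, sigma^2_{a,k}) + log pi_a(k|x) ],

the likelihood-fusion equation: a convex combination of per-atlas
log-likelihoods, not of per-atlas label decisions.

## EM surrogate and exact monotonicity

With window-aggregated evidence the EM free energy is

    F(q, W) = sum_x [ sum_a q(x,a) * b_a(x; W) + H(q(x, .)) ],
    b_a(x; W) = sum_{y in win(x)} l_a(y; W) + log pi(a) - lambda * E_geo(a),

where `l_a(y; W)` is atlas `a`'s per-voxel log score at the current labels.
The E-step softmax maximizes `F` over `q` exactly, after which
`F = sum_x logsumexp_a b_a(x)` — this is the recorded objective.  The exact
maximizer of `F` over `W` uses the *adjoint* of the window aggregation:
weights `q~ proportional to` the window-sum of `q` (the box window with zero
padding is self-adjoint).  Using `q~` in the M-step makes every recorded
objective increment provably non-negative; any decrease beyond 1e-6
(relative) raises a hard error rather than being tolerated.  All EM fields
are computed in float64 so rounding stays far below that tolerance.

## Pipeline

1. Register every atlas to the target by LDDMM (mode approximation).
2. Propagate hard labels; the cuboid ROI is their bounding box + margin.
3. Give every atlas background voxel a generic CSF/GM/WM chart (below),
   estimate per-chart means/variances, warp labels probabilistically.
4. Majority-vote initialization; outlier-atlas rejection against it.
5. Alternate E/M until the changed-voxel fraction drops below `epsilon`
   or 100 iterations.

## Parameters

Registration (`RegistrationConfig` / `KernelParams`):

- `alpha = 1, gamma = 1, p = 2` — operator `(-alpha*laplacian + gamma)^2`;
  the cascade overrides `gamma` per stage.
- `cascade_ratios = (1.0, 0.1, 0.01)` — gamma/alpha schedule, strictly
  decreasing for numerical stability; each stage warm-starts from the last.
- `timesteps T = 5`, `step_size = 0.2` with halving line search (<= 10
  halvings; accepted steps never increase the stage energy), `max_iters = 10`
  per stage, relative-change tolerance `1e-4`.
- `data_weight = 1/sigma^2` with `sigma` a MAD estimate of the target noise
  from first differences, floored at 1% of the robust intensity range so
  noise-free images do not produce an infinite weight.
- Fourier kernels use periodic boundaries with 4-voxel zero padding when
  smoothing force fields (wrap-around suppression).  The force-smoothing
  kernel is normalized to unit zero-frequency gain so gradient magnitudes
  stay comparable across cascade stages; the energy always uses the
  unnormalized operator.

Fusion (`FusionConfig`):

- `selector_radius = 2` voxels — the box window realizing chart-local
  evidence (support of the aggregated log-likelihood).
- `epsilon = 1e-4` — convergence threshold on the fraction of voxels that
  change label; `max_iters = 100`.
- `lambda_prior = 0` — the transformation prior `exp(-lambda * E_geo)`
  (metric distance in diffeomorphism space) is implemented and tested but
  off by default; no weighting constant is prescribed by the model.
- Log label priors are floored at `-30` nats so zero-probability labels keep
  scores finite.
- Outlier rule: atlases scoring below `mean - 1.5 * sd` in mean Dice against
  the initialization are dropped; at least `ceil(N/2)` atlases are retained.
- Atlas prior uniform over retained atlases.
- Variance floor per chart: `max(1e-6, 0.01 * global intensity variance)`.

## Generic tissue charts

ROI voxels outside the structures of interest must be explainable, or dark
CSF and bright WM get over-assigned to structures.  Each atlas's background
voxels are classified into CSF/GM/WM by a 3-class Gaussian mixture fitted to
that atlas's own background intensities (k-means initialized, deterministic
given the seed, components sorted by ascending mean = CSF, GM, WM).  These
tissue charts then participate in fusion exactly like structure charts.  The
same mixture machinery labels any ROI voxel the fusion leaves unlabeled when
tissue charts are disabled, so every ROI voxel ends with a structure or
tissue label.  A full tissue segmentation algorithm is out of scope; the
3-class mixture is the minimal model with the needed behavior.

## Synthetic study conditions

The generator emulates a subcortical T1 scene at desk scale, and its
defaults are the package's study conditions:

- 48^3 lattice at 0.9375 x 0.9375 x 1.2 mm (clinical MPRAGE-like spacing).
- Five ellipsoidal structures (hippocampus, amygdala, caudate, putamen, and
  a CSF-dark lateral ventricle) inside a white-matter ellipsoid with a
  gray-matter shell and CSF exterior; an unlabeled CSF pocket abuts the
  ventricle and hippocampus, reproducing the ambiguous inferior-horn
  boundary that intensity alone cannot resolve.
- Tissue means 30/70/100 (CSF/GM/WM) with sd 7, structure noise sd 7:
  subcortical gray is nearly isointense with cortical gray, and the
  structure-to-WM contrast-to-noise is moderate, as in clinical T1.
- Atlas populations: random diffeomorphisms from smoothed white-noise
  stationary velocities, max displacement 4 voxels, smoothness 6 voxels,
  intensity jitter sd 3 — inter-subject-scale shape variation under which a
  single atlas is clearly imperfect (single-atlas MAP Dice roughly
  0.8-0.95 per structure) so the value of fusing atlases is measurable.

Ellipsoids (closed-form membership) were chosen over meshes so generator
claims can be checked by exhaustive voxel scans.  The generator uses
stationary velocities (invertibility is what matters there); the
registration module integrates the full time-indexed flow.

What the phantom does *not* model: cortical folding, partial-volume
gradients beyond linear interpolation, bias fields, multi-compartment
structure intensities, and multi-modal channels.  Passing tests therefore
demonstrate the correctness and the qualitative behavior of the algorithm
(fusion >= single atlas, tissue charts help at CSF boundaries, outliers are
rejected), not clinical-grade accuracy on real MRI.

## Numerical choices

- Boxes are half-open `[lower, upper)`, voxel indexing 0-based.
- Tie-breaks: segmentation argmax ties go to the label with larger summed
  prior mass, then the lowest label id; tissue classification ties go to the
  lower (darker) tissue id; majority-vote ties go to the lowest label id.
  All deterministic, so atlas order never changes the result.
- The geodesic term along the line search is evaluated by its exact
  quadratic expansion in the step length (the energy is quadratic in `v`),
  avoiding redundant transforms.
- The inverse map is built by composing inverted Euler steps in reverse
  (backward integration of `-v`); fixed-point inversion exists only as a
  test oracle.
- Maps are interpolated via their displacement so translations are exact and
  edge clamping does not distort the identity part.
- `random_diffeomorphism` halves its amplitude (<= 3 retries) until the
  interior Jacobian determinant is positive everywhere.
- Registration and map algebra run in float32; EM fields, chart statistics
  and all reported energies/objectives accumulate in float64.

## Open design points, resolved

- Whether selector weights are per-voxel, per-chart, or global is left open
  by the model statement; this implementation uses per-voxel weights with
  local window aggregation (radius configurable), which subsumes the global
  case as the window grows.
- The outlier statistic and cut constant are not prescribed; mean Dice
  against the initialization with a `mean - 1.5 sd` cut and half-retention
  floor is the declared rule, chosen to be robust at small N.
- Re-optimizing the deformations inside the EM loop is supported by the
  model but disabled: one registration per atlas keeps the run deterministic
  and desk-scale, and the propagated priors change little per EM iteration.
- The transformation prior enters the selector only, not the fused scores.
- The randomization test uses the Welch t-statistic (safe for the unequal
  group sizes it is applied to) and two-sided comparison on |t|; Monte Carlo
  p-values carry add-one smoothing, exhaustive enumeration reports the exact
  fraction.
- Atlases are assumed pre-resampled to the target grid (a nearest/linear
  resampler is provided); the mapping direction is atlas -> target grid.

## Problem sizes

The shipped test suite and the acceptance script run entirely on the 48^3
standard fixture (5 structures, 5 atlases; 10 random replicates for the EM
monotonicity check, 5 for the fusion-benefit and tissue-ablation checks, 6
atlases for the outlier experiment) plus 32^3 or smaller grids for unit
oracles.  With the default configuration one atlas registration takes a few
seconds and the EM a few more, so a full multi-atlas run is well under a
minute on one CPU.

## Known limitations

- Single Gaussian per chart; no multi-compartment mixtures per structure.
- Surface/mesh matching and whole-brain segmentation are out of scope, as
  are STAPLE-style label-fusion baselines (external segmentations can be
  evaluated with the same Dice/permutation tooling).
- The greedy time-discretized descent is not a geodesic shooting method; the
  returned velocity is not guaranteed to be the exact metric geodesic.
- Affine pre-alignment is not implemented beyond the assumption of a shared
  grid; grossly translated inputs should be pre-aligned upstream.
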