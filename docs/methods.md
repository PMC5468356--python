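# Methods

## Pixel model and seed-point detection

Pixel colors I_Q ∈ [0,255]³ are modeled as a mixture of multivariate
Gaussians grouped into three classes — immunopositive (DAB-brown)
nuclei, immunonegative (hematoxylin-blue) nuclei, and background. The
density family sits behind a small interface (`DensityFamily`) so a
per-channel Gamma variant could be slotted in; the implemented family is
the full-covariance Gaussian, which is the density the energy equations
below assume. (Some descriptions of this detection approach say "Gamma
mixture" while writing Gaussian densities; the Gaussian form is what the
mathematics supports, and that is what is implemented.)

**EM fitting.** `fit_gmm_em` maximizes the mixture likelihood by
expectation–maximization and records the per-iteration mean
log-likelihood; the trace is non-decreasing up to the covariance-floor
regularization (a constant `covariance_floor`, default 1.0 intensity²,
added to every covariance diagonal in each M step — it keeps components
positive-definite and bounds collapse on degenerate input).
Convergence: relative log-likelihood change below `em_tol` (default
1e-5) or `em_max_iter` (default 200) iterations.

**Initialization.** The three-class image model starts EM at the
reference class colors — brown ≈ (150, 100, 60), blue ≈ (70, 80, 150),
background ≈ (235, 230, 240), all configurable — replicated with small
deterministic offsets when `components_per_class` > 1. Plain k-means
initialization was rejected after it let the dominant background mode
absorb a nucleus color mode on background-heavy fields; anchoring the
start at the stain colors removes that failure and keeps the fit fully
deterministic. Generic mixture fits (no class structure) fall back to
k-means with a fixed seed. Fitting uses a pixel subsample (default cap
100 000) for speed; labeling always uses every pixel.

**Class grouping.** Fitted components are assigned to the class whose
reference color is nearest (Euclidean RGB) to the component mean; a
class left without components adopts a broad Gaussian at its reference
color so labeling stays defined.

**MAP labeling.** The per-pixel unary energy is −ln(class prior ×
class-conditional mixture density). With Potts coupling β = 0 (the
default) each pixel independently takes the minimum-energy class —
pure maximum-likelihood labeling. With β > 0 a Potts pairwise prior on
the 4-neighbourhood (the simplest Gibbs prior consistent with a
unary + pairwise energy decomposition) is optimized by iterated
conditional modes from the unary initialization, sweeping until no
pixel changes or `icm_max_iter` (default 10) sweeps. ICM never
increases the objective, so the result is at least as good as its
initialization and is a single-flip local minimum at convergence; it
need not be the global optimum. Ties break toward the lowest label
index. The likelihood energy itself,
Σ_Q [½ (I_Q−μ)ᵀ Σ⁻¹ (I_Q−μ) + ½ ln|Σ|], is exposed as
`likelihood_energy` and is evaluated with the dominant (heaviest)
Gaussian of each class, the single-Gaussian reading under which the
closed forms hold.

**Seed extraction.** Nucleus-class pixels are grouped into 8-connected
components; components smaller than `min_component_area` (default 30 px
at the synthetic scale — about a quarter of the smallest nucleus area,
large enough to reject noise specks) are dropped, and each survivor
contributes one seed at its rounded centroid. Ordering is deterministic:
class, then row, then col. Touching nuclei merge into one component —
watershed splitting is out of scope — so detected counts are a lower
bound on true counts in dense fields.

## Patch extraction and splits

Patches are 71 × 71 × 3 crops centered on seed centroids; 71 is odd, so
the centroid sits exactly on the center pixel (35, 35). Near borders
the default policy reflects image content (mirror without edge
duplication), which preserves patch count without introducing
constant-color regions that would bias a color-driven classifier;
`constant` and `skip` policies are available. Splits and folds are
stratified by class (scikit-learn); grouped variants keep all patches of
one source image together to avoid leakage. Grouped splitting cannot
simultaneously guarantee exact fold sizes, so the ungrouped stratified
split is the default and the grouped mode is a flag.

## Classifier

Architecture (input 71×71×3; all convolutions valid, stride 1; pooling
2×2 non-overlapping with floor on odd sides):

| layer | maps | output | filter |
|---|---|---|---|
| conv-1 | 90 | 70×70 | 2×2 |
| pool-1 | 90 | 35×35 | 2×2 |
| conv-2 | 180 | 32×32 | 4×4 |
| pool-2 | 180 | 16×16 | 2×2 |
| conv-3 | 360 | 14×14 | 3×3 |
| pool-3 | 360 | 7×7 | 2×2 |
| conv-4 | 720 | 6×6 | 2×2 |
| pool-4 | 720 | 3×3 | 2×2 |
| conv-5 | 1440 | 2×2 | 2×2 |
| decision layer | — | 720 | — |
| fc-1 | — | 100 | — |
| fc-2 | — | 2 | — |

ReLU follows every convolution and fc-1; dropout (ratio 0.5) sits after
fc-1 and is active only in training.

**Decision layer.** Each of z trees is a full binary tree of depth D.
Decision node d holds an affine functional f_r on the flattened conv-5
output (affine is the minimal differentiable choice of "real-valued
function") and routes left with probability f_d = σ(f_r(x)). Leaf-reach
probabilities are path products, summing to 1 per tree by construction.
The layer runs in *embedding* mode inside the network: the concatenated
μ vectors of all trees form a z·2^D-wide feature vector for the FC
head; z = 45, D = 4 gives the 720-wide decision layer. Only this
reading is consistent with a 720-wide layer feeding fc-1; the
alternative *probability* mode (per-tree class posteriors Σ_p π_p μ_p,
with leaf distributions π parameterized by softmax) is exposed for
standalone forest use. In embedding mode π is unused and the decision
functionals train by the same backpropagation as every other layer; the
closed-form alternating π update from the decision-forest literature is
not implemented.

**Implementation.** All layers are NumPy float64 with hand-written
backward passes (im2col convolution; pooling backward routes gradient
to the first maximum on ties; routing backward runs the path-product
recursion in reverse). Float64 makes finite-difference gradient checks
meaningful; the suite checks every layer kind against central
differences at relative error < 1e-4. Weight initialization is
uniform(−√(6/fan_in), +√(6/fan_in)) with a fixed seed.

**Training.** Mini-batch SGD with momentum, classic L2 weight decay
(biases undecayed), softmax cross-entropy (the natural 2-class choice,
left open by the layer composition itself). Operating point: learning
rate 0.01, momentum 0.85, weight decay 0.005, batch 128, test interval
5000, maximum 450 000 iterations. Updates are clipped to a global
gradient norm of 5.0: a confident network meeting a hard patch can emit
a cross-entropy gradient spike large enough to kill the entire ReLU
stack (observed as an abrupt collapse to constant output, loss ≡ ln 2);
clipping bounds the step without changing its direction and removes the
failure. All randomness (init, batch order, dropout) derives from one
seed; identical configs reproduce identical losses bit-for-bit.

**Scale profiles.** The full architecture trains in reasonable time only
on GPU-class hardware. CPU runs use `NetworkConfig.small()` — the same
topology with maps (8, 16, 32, 64, 128), an 8-tree depth-3 forest
(64-wide embedding) and a 32-wide fc-1 — and
`TrainConfig.desk_scale()` (400 iterations, batch 32 by default). On
high-contrast synthetic scenes this profile reaches validation accuracy
1.0 within ~200 iterations; the test suite and the acceptance script use
it with ~2000 patches, 400 iterations. The full configuration remains
expressible and is what `NetworkConfig.full()` builds.

## Metrics and proliferation scoring

Precision = TP/(TP+FP), recall = TP/(TP+FN), F = harmonic mean of the
unrounded pair, positive class = immunopositive. Printed forms of these
formulas sometimes interchange the two denominators; only the standard
reading reproduces the reference worked example (matrix 17028 / 2277 /
1287 / 15840 → 0.93 / 0.88 / 0.91), so the standard definitions are the
default and `convention="swapped"` exposes the variant for audits.
Zero-denominator metrics are reported as undefined (None), never as 0.

APS = 100·TIP/(TIP+TIN); the reference category ranges (< 15, 16–30,
> 31) leave [15,16) and (30,31] unassigned, so the implemented cover is
low < 15 ≤ average ≤ 30 < high — exhaustive and order-preserving.
`category_error` is the absolute difference between the mean of manual
scores and the automated score, at two decimals. `count_regression`
fits automated counts on manual counts by OLS; R² is undefined (None)
when manual counts have zero variance and 0 when automated counts do.

## Synthetic scenes: what they do and do not show

The generator renders rotated ellipses (radii uniform in a range) with
per-nucleus color jitter (Gaussian SD per channel around the class
mean) and additive truncated-Gaussian pixel noise clipped to [0,255],
on a uniform pale background; overlap is controlled by the admissible
intersection fraction during rejection placement (0 = disjoint masks).
Default scene: 256×256, radii 6–12 px, jitter SD 8, noise SD 5,
class colors as above — chosen to echo DAB/hematoxylin appearance at
the package's working scale. Capacity failures (canvas too small for
the requested count) raise an error naming the limiting parameters.

The scenes emulate exactly what the pipeline consumes: two color
populations, size/intensity variation, optional overlap, known
centroids and ratios. They do **not** contain chromatin texture,
stromal/cytoplasmic background structure, stain gradients, scanner
artifacts or out-of-focus regions. Passing tests therefore demonstrate
the correctness of the machinery (energies, routing, gradients, counts,
determinism) and its behavior under the modeled variations — not
clinical performance on real slides, which would require annotated
tissue images.

## Degenerate inputs and numerical choices

- EM on fewer distinct pixels than components: warns, floors
  covariances, proceeds.
- Empty pixel set, empty patch list, zero detected nuclei, zero-count
  APS: explicit errors or None-flagged results, never silent zeros.
- Posteriors are computed in log space throughout (log-sum-exp); ties
  in MAP labeling break to the lowest label index; pooling ties route
  gradient to the first maximum.
- All stage seeds derive from one master seed via stable per-stage
  hashing (`ki67score._rng`), so any stage can be re-run independently
  and bit-identically.

## Known limitations

- Touching nuclei merge into single components (no watershed split);
  dense fields undercount both classes roughly proportionally, which
  perturbs APS only mildly.
- ICM at β > 0 is a local optimizer; graph cuts would find lower-energy
  labelings on hard fields.
- The NumPy network trains the reduced profile only; the full 720-map
  architecture is forward-practical but not desk-trainable.
- Background is modeled as a single pale Gaussian mode; heavily
  textured stroma would need more components per class
  (`components_per_class` > 1) or a richer background model.
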