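# Methods

`lensbench` benchmarks eight classical feature-extraction + classification
schemas for binary screening of pediatric cataract in rectangular slit-lamp
lens crops ("ROIs"). The clinical dataset this task comes from (476
cataract-positive, 410 control crops) is private, so the package ships a
synthetic generator that emulates its statistical structure; every pipeline
stage is exercised end to end on generated data.

## The eight schemas

| id | features | classifier |
|----|----------|------------|
| 1 | color moments + co-occurrence texture (38) | extreme learning machine, 80 hidden units |
| 2 | same 38 | SVM, linear kernel |
| 3 | same 38, GA-selected subset | SVM, linear kernel |
| 4 | same 38 | kNN, k ∈ {5, 10, 20} |
| 5 | all two-level DWT coefficients (haar/db1/sym4, 15×30) | SVM, linear or polynomial |
| 6 | windowed uniform-LBP histograms (9×9 windows, 20×30) | SVM, linear or polynomial |
| 7 | raw 5×10 gray pixels | sparse-representation classifier, DE-solved L1 |
| 8 | same 38 | sparse-representation classifier, DE-solved L1 |

Every schema is evaluated with seeded, stratified 4-fold cross validation;
reported numbers are across-fold mean ± sample standard deviation (ddof=1)
of accuracy = (TP+TN)/(P+N), sensitivity = TP/P, specificity = TN/N, and
the trapezoidal AUC of the ROC traced by sweeping the classifier's
continuous score. Scores are: SVM decision value, ELM output-unit margin,
kNN positive-neighbor fraction, SRC residual difference r_neg − r_pos.
Undefined metrics (a fold without one class) raise instead of yielding NaN.

## Feature definitions (frozen conventions)

**Color moments (9).** Per RGB channel: mean, √(second central moment),
signed ∛(third central moment).

**Gray-tone co-occurrence (14).** The image is converted to gray (BT.601
luma), quantized to 16 levels (v → ⌊v·16/256⌋), and pair counts at
displacement d=1 are accumulated for θ ∈ {0°, 45°, 90°, 135°} with
symmetric counting (both orderings), summed over directions and normalized.
From the resulting p(i,j) the canonical fourteen statistics are computed:
angular second moment, contrast, correlation, sum-of-squares variance,
inverse difference moment, sum average, sum variance, sum entropy, entropy,
difference variance, difference entropy, the two information measures of
correlation, and the maximal correlation coefficient (√ of the second
largest eigenvalue of Q(i,j) = Σ_k p(i,k)p(j,k)/(p_x(i)p_y(k))). Natural
logarithms, 0·log 0 = 0; on degenerate (single-level) images every
correlation/entropy-type statistic is defined as 0, never NaN.

**Gray-gradient co-occurrence (15).** Sobel gradient magnitude (reflect
boundary) is linearly dispersed into L_g = 10 levels via
round(G/G_max·(L_g−1)); the joint histogram of (16-level gray, gradient
level) is normalized to p(i,j) with marginals p_g, p_s and yields: small-
and large-gradient dominance (Σ p_s(j)/(j+1)², Σ p_s(j)·j²), gray and
gradient distribution asymmetry (Σ p_g², Σ p_s²), energy, gray and gradient
means and variances, normalized correlation, gray/gradient/mixed entropies,
inertia Σ(i−j)²p, and inverse difference moment. Indices are 0-based.

**Wavelet descriptor.** Gray image resized (bilinear, no antialiasing) to
15×30, two-level separable DWT with periodization boundary handling; all
coefficients flattened in the fixed order LL2, LH2, HL2, HH2, LH1, HL1,
HH1. Periodization pads the odd extent 15 → 8, so the vector length is
deterministic at 488 (not equal to the pixel count); exact Parseval energy
conservation therefore holds only for even extents and is tested at 16×32.
haar and db1 are the same filter and produce identical vectors.

**Uniform LBP descriptor.** Gray image resized to 20×30, tiled by
non-overlapping 9×9 windows anchored top-left (partial edge windows
dropped → 2×3 windows). Within each window, each pixel whose full 3×3 ring
fits inside the window (7×7 = 49 pixels) gets an 8-bit code — bit i set iff
neighbor_i ≥ center, neighbors ordered east then counter-clockwise — mapped
to its set-bit count (0..8) if the circular bit-transition count U ≤ 2,
else to the pooled label 9. The 10-bin window histograms are concatenated
(60 features); each window's histogram sums to exactly 49. P=8 neighbors is
used throughout (a 256-code space requires it).

## Classifiers

All classifiers standardize features (zero mean/unit variance per feature,
fit on the training fold only): the blocks mix raw moments, probabilities
and counts spanning orders of magnitude. The SVM is libsvm (via
scikit-learn) with C=1; polynomial kernel means degree 3, γ=1/dim, coef0=0.
The ELM draws input weights and biases uniformly from [−1,1] (seeded),
applies a logistic sigmoid, and solves Hβ = T by minimum-norm least squares
(T one-hot). kNN uses euclidean distance by default (manhattan and canberra
available), stable index-ordered tie-breaking, and an even vote goes to the
negative class.

**GA wrapper selection (schema 3).** Generational GA, population 30,
single-point crossover at 0.7, per-bit flip mutation at 0.3/length,
tournament selection (size 2), elitism of one, 200 generations. Fitness is
3-fold stratified CV accuracy of a linear SVM on the selected columns,
computed inside the outer training fold only, so selection never sees the
outer test fold (a deliberate nesting; fitness evaluations are memoized on
the bit mask). All-zero masks are repaired by activating one random bit.

**Sparse-representation classification (schemas 7, 8).** The dictionary is
drawn per outer fold from the fold's training samples — 1 negative + 80
positive columns for schema 7 (resized 5×10 gray pixels) and 5 + 70 for
schema 8 (the 38-feature vectors, standardized on the fold's training
data) — then column-normalized to unit L2; queries are normalized the same
way so residuals do not reduce to image brightness. The coefficient vector
solves min ‖x‖₁ s.t. ‖Ax − y‖₂ ≤ ε with ε = 0.05·‖y‖₂ (configurable; the
single largest free parameter of this component). The solver is
DE/rand/1/bin — population 50, scale factor F=0.4 (the schema's "mutation
rate"), crossover rate 0.7, 500 generations — with Deb's feasibility rules
as the replacement criterion (feasible beats infeasible; two feasibles by
objective; two infeasibles by violation). The population is initialized in
the least-squares affine subspace (LS solution plus graded null-space
perturbations): rand/1 mutation is an affine combination, so mutants
inherit near-feasibility and selection can concentrate on descending the
objective; initialized uniformly instead, the search stalls at the LS
anchor. On 8×12 benchmark dictionaries the DE objective lands within 0–1.5%
of the exact optimum of the same constrained problem (independent convex
solve). Class assignment takes argmin over class-restricted reconstruction
residuals, ties to negative.

## The synthetic generator

Each sample is a 60×90 8-bit RGB rendering of an elliptical lens on a dark
background, with per-sample jitter of the lens axes, peak/edge brightness,
illumination ramp, and a specular highlight. The class signal enters
through physically motivated channels, all scaled by a per-sample opacity
`grade` = severity · max(0, N(1, 0.45·heterogeneity)):

* **slit-beam scattering** — a clear lens shows the beam as a narrow crisp
  vertical band; a turbid lens spreads it into a wide dim glow of roughly
  equal total energy;
* **nuclear core and veiling glare** — a dense bright central cloud plus a
  whole-pupil brightness lift;
* **clouding texture** — signed Gaussian blobs, band-limited zero-mean
  noise, and multiplicative speckle over the glowing lens;
* **loss of retroillumination detail** — radial iris/fundus striations are
  rendered inside the pupil with visibility (1 − grade), so clear lenses
  carry fine structured texture that opacity replaces rather than adds to.

The last two channels are what keeps the task from being trivially solved
by global statistics alone: striations and speckle have overlapping
fine-texture energy, so the discriminative information is partly in *where
and how* intensity is arranged, which the windowed/spatial descriptors
retain. `severity=0` zeroes `grade`, making the two class distributions
identical (classifiers sit at chance, a tested contract); schema-2 accuracy
is non-decreasing in severity.

What the generator does **not** emulate: hand-crop variability in framing
and scale, multiple anatomies (eyelids, lashes), illumination color
changes, JPEG artifacts, and the full clinical spectrum of cataract
morphologies. Passing benchmarks on this family therefore demonstrates the
pipeline's correctness and the relative behavior of the schemas under a
controlled texture-vs-statistics trade-off, not clinical performance.

## Evaluation conditions and known deviations

The shipped evaluation (tests and `scripts/acceptance.py`) uses 200 samples
per class at severity 1 — sizes chosen to exercise every schema in minutes
on one core; the generator's class-ratio default (476:410) mirrors the
emulated study. Under these conditions the windowed-LBP schema (polynomial
kernel, its best variant) matches the 38-statistic SVM schema within
sampling noise, the SVM consistently beats the ELM on shared features, and
raw-pixel SRC with the 1+80 dictionary sits at chance AUC. One known
deviation: the wavelet schema trails the 38-statistic schema by roughly 0.1
accuracy on this family — its linear decision function cannot read
texture-energy signals that live in detail-coefficient *magnitudes*
(a polynomial kernel with coef0=0 is odd-symmetric and cannot either), so
its strength depends on signed coarse-scale structure that the emulated
data only partly provides.

## Numerical conventions

Quantization is floor-based; gradient dispersal rounds to nearest level;
resizing is pure bilinear without antialiasing (deterministic across
backends, exact on constants, clamped to the input range); residual and
vote ties break toward the negative class; all stochastic components
(generator, folds, ELM weights, GA, DE, dictionary draws) are seeded, and
per-sample/per-query streams are derived by counter so results do not
depend on evaluation order.
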