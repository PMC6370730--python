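# Methods

This note records the model implemented by `skfuse`, the parameter choices
that matter, the numerical conventions, and what the synthetic benchmark
does and does not establish.

## Model and assumptions

The pipeline assumes that a latent patient subtype expresses itself as a
mean shift in some subset of features in every measured view, so that
within-subtype patients are closer to each other than to other patients in
the (z-scored) feature space of each view. The method is wholly
unsupervised: survival enters only afterwards, as an external criterion for
scoring a partition and selecting the number of clusters.

### Per-view kernels

Each feature is standardized to mean 0 and unit **population** standard
deviation across patients (``ddof=0``; a flag switches to the sample
convention). Per-feature scaling, rather than one global scalar, is what
puts heterogeneous features on a common scale; constant features carry no
information and are set to zero. Features missing in more than 20% of
patients are dropped at load time and remaining gaps are mean-imputed, so
kernels are always defined (threshold configurable).

Squared Euclidean distances D between patient profiles are converted to
similarities with a locally-scaled exponential kernel

    K_ij = exp( − D_ij / (mu · eps_ij) ),   eps_ij = (m_i + m_j + D_ij) / 3,

where m_i is the mean of D over patient i's k nearest neighbors. A design
point worth recording: **eps is kept on the squared-distance scale**, the
same scale as the numerator. If eps is instead assembled from linear
(root) distances, the exponent grows like −2·√D/mu, i.e. with the square
root of the number of features; for realistic view widths (hundreds to
tens of thousands of features) every off-diagonal entry then collapses
toward or below the smallest representable double and the kernel
degenerates to the identity. With the squared-scale eps the exponent is
dimensionless: it depends only on the ratio of a pairwise distance to its
local neighborhood scale and is invariant to feature count. This is also
the convention of the widely used similarity-network-fusion reference
implementation. `mu` (default 0.5, sensible range 0.3–0.8) sets the
bandwidth; the diagonal is exactly 1; coincident neighborhoods floor eps
at 1e−12.

### Fusion

Per view, the column-stochastic kernel P and the row-stochastic sparse
kernel S (support: k nearest neighbors plus self) feed the cross-diffusion
recurrence given in the README. Conventions chosen where the definition
leaves freedom:

- **Synchronous updates.** All views' t+1 states are computed from the
  full t state. This makes the result independent of view order.
- **Column re-normalization each sweep.** The update does not exactly
  preserve column sums; re-normalizing each P_l^{t+1} keeps the states on
  the stochastic-matrix manifold and prevents scale drift across
  iterations.
- **Stopping rule.** The iteration stops when the largest per-view
  relative Frobenius change falls below ``tol`` (default 1e−6) or after
  ``max_iters`` (default 20) sweeps. For α < 1 the anchor term makes the
  map a contraction toward a blend of the initial states, so convergence
  is fast; at α = 1 the iteration may still be drifting slowly when the
  cap is reached, which the result records (``converged=False``).
- **Neighborhood size.** k defaults to max(5, n/10), capped at n−1 — the
  usual kNN-graph heuristic for cohorts of a few hundred to a thousand
  patients.
- **Mask neighborhoods.** The mutual-kNN mask is recomputed on the
  combined kernel K_com with the same k: the masking should reflect the
  fused geometry, which is the object being denoised, not any single view.
- **Final symmetrization.** Column normalization and one-way neighbor
  relations leave K_com slightly asymmetric; K* is symmetrized because the
  spectral step requires a symmetric affinity.

A property that does **not** hold, although one might expect it: for
identical input views the fused kernel is not independent of α. With all
views equal the state evolves as P^{t+1} = α·S P^t Sᵀ + (1−α)·P⁰, whose
limit moves with α unless S P⁰ Sᵀ = P⁰ — true only for degenerate
(near-identity) kernels. What diffusion does guarantee is symmetry
*between* views: identical inputs produce identical per-view states at
every iteration, and at α = 0 the initial state is a one-step fixed point.
Both are asserted in the test suite.

### Spectral step

L⁺ = I − D^{−1/2} K* D^{−1/2} with D the degree matrix of K*. The
embedding returned by ``spectral_embed`` is the orthonormal matrix of the
C smallest eigenvectors — orthonormality is kept at this boundary so that
Trace(QᵀL⁺Q) equals the sum of the C smallest eigenvalues exactly, which
is what makes the step independently checkable. The Ng–Jordan–Weiss row
normalization is applied inside ``cluster_embedding`` immediately before
k-means (it improves the rounding of the relaxation but destroys
orthonormality, so it belongs with the rounding, not with the embedding).
Determinism conventions: eigenvector signs are fixed so each vector's
largest-magnitude entry is positive; k-means uses a fixed seed with 10
restarts; clusters are relabeled by descending size; kNN ties break toward
the smaller patient index.

### Survival evaluation

The C-sample log-rank test is implemented directly: at each distinct event
time the observed events per group are compared with their hypergeometric
expectation, tied events use the Mantel–Haenszel variance, and the
statistic dᵀV⁻d over C−1 groups is referred to χ²(C−1). This is the score
test of a Cox model with the subtype label as its only (categorical)
covariate, so it matches the usual "Cox p-value" reported for subtype
separations while needing no iterative fitting. The implementation is
cross-checked in the tests against an independent survival library on
random data with ties and censoring, to 9 significant digits.
Kaplan–Meier curves are delegated to `lifelines`.

Model selection (``scan_clusters``) clusters at every C in a range and
reports χ², p and −log10 p per C; the α sweep (``alpha_scan``) repeats
this over a grid of diffusion weights (default 0.0–1.0, step 0.1). The
minimum-p C is a noisy statistic of the cohort draw — merging the two
most similar survival groups occasionally beats the true structure on the
p scale — so conclusions about the "right" C should rest on the shape of
the whole curve, not a single argmin (the tests assert the modal argmin
across cohorts).

## Synthetic benchmark

The generator plants C clusters (default 3 × 30 patients) shared across
views. Per view, a fraction (default 0.2) of features are informative:
each elevates one random cluster's mean by ``separation`` (default 6)
times the noise sd (default 1). The remaining features are pure noise.
Default view widths are 150/100/60 features — wide enough that distance
concentration, the regime the kernel scaling must survive, is present.
Survival times are exponential with per-cluster hazards (default 0.02,
0.06, 0.18 per month — adjacent ratio 3, strong but not degenerate);
censoring is independent uniform follow-up with its upper bound solved
per cluster so the expected censoring fraction matches the requested rate
(default 0.2). Everything is bit-reproducible from one seed.

What passing on this benchmark shows: the pipeline recovers well-separated
Gaussian-mixture structure exactly, degrades gracefully as separation
shrinks, finds no structure when none is planted, and the survival scoring
is calibrated. What it does not show: robustness to the pathologies of
real cohorts — batch effects, heavy-tailed counts, cluster-size imbalance
beyond the generator's proportions, views that disagree about the true
partition, or informative censoring. Results on real data depend on those
factors and on k and mu, which should be sense-checked with the α and C
scans rather than trusted at defaults.

## Known limitations

- The α = 1 endpoint (pure diffusion) converges slowly and may hit the
  iteration cap; results there depend mildly on ``max_iters``.
- The mutual-kNN mask can disconnect the fused graph when k is small
  relative to cluster sizes; the Laplacian step reports zero-degree
  patients rather than guessing.
- p-values from the scan are not corrected for the multiplicity of C
  values tried; they are selection scores, not confirmatory tests.
- The log-rank χ² approximation is asymptotic; for very small groups or
  very few events an exact/permutation test would be preferable.
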