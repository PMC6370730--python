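# skfuse

Similarity kernel fusion for discovering patient subtypes from multiple
expression profiles.

Molecular subtypes of a cancer rarely show up cleanly in any single data
layer. A cohort profiled for gene expression, miRNA expression and isoform
expression gives three partial, noisy pictures of the same patients.
`skfuse` integrates any number (≥2) of such patient × feature matrices into
a single patient × patient similarity kernel, partitions the patients with
normalized-cut spectral clustering, and scores candidate subtype structures
by how strongly they separate survival.

## Method

For each view, features are z-scored and squared Euclidean distances
between patient profiles are converted to a locally-scaled exponential
similarity kernel *K*. Two operators are derived per view:

- **P** = *K* normalized so every column sums to 1 (a transition-like
  kernel), and
- **S** = *K* restricted to each patient's *k* nearest neighbors plus
  itself and row-normalized (a sparse diffusion operator that discards
  weak similarities).

The views are fused by cross-diffusion: for view *l* of *L*,

    P_l^{t+1} = α · S_l ( Σ_{r≠l} P_r^t / (L−1) ) S_lᵀ
              + (1−α) · Σ_{r≠l} P_r^0 / (L−1)

so each view's state repeatedly absorbs the other views' information
through its own neighborhood graph, while the (1−α) anchor keeps a share of
the original cross-view average (α ∈ [0,1]; α = 0 keeps only initial
information, α = 1 only diffused information). At convergence the per-view
states are averaged into K_com and masked by mutual-kNN weights
w ∈ {0, ½, 1} (1 for reciprocal neighbor pairs, ½ for one-way, 0 for
neither), giving the fused kernel K* = sym(w ∘ K_com).

Patients are then clustered with the symmetric normalized Laplacian
L⁺ = I − D^{−1/2} K* D^{−1/2} (eigenvector embedding, row normalization,
k-means), and each candidate cluster number C is scored by the C-sample
log-rank test — the Cox score test for a categorical subtype label — on the
cohort's survival table, reported as −log10(p).

A built-in generator produces multi-view cohorts with planted clusters and
cluster-linked exponential survival, so the whole pipeline is testable
without any external cohort.

## Worked example

Simulate a 3-view cohort of 90 patients in three planted subtypes whose
hazards differ, then run the pipeline:

```bash
skfuse simulate --outdir demo --n-patients 90 --n-clusters 3 --seed 11
skfuse run --config demo/config.yaml
```

```text
clustered 90 patients into 3 subtypes
log-rank chi2 = 42.11 (df=2), p = 7.167e-10, -log10(p) = 9.145
artifacts written to demo/results
```

The scan table (`demo/results/scan.tsv`) shows why C = 3 was chosen — the
survival separation peaks exactly at the planted number of subtypes:

```text
n_clusters  chi_square    p_value        neg_log10_p
2           2.510165495   0.1131140523   0.9464834387
3           42.11270221   7.167090798e-10  9.144657094
4           42.93418494   2.5414724e-09  8.594914602
5           43.49989529   8.14888442e-09   8.088901842
```

A chi-square of 42.1 on 2 degrees of freedom (p ≈ 7×10⁻¹⁰) means the three
recovered groups have very different survival profiles; comparing
`demo/results/assignments.tsv` against `demo/true_labels.tsv` shows the
planted subtypes were recovered exactly. `skfuse alpha-scan --config
demo/config.yaml` sweeps the diffusion weight α over 0.0–1.0 in steps of
0.1 and reports the best C per value (on this well-separated cohort all 11
rows agree on C = 3).

Every run writes the fused kernel, assignments, scan table, Kaplan–Meier
step functions and a manifest of all parameters, and is bit-reproducible
for a fixed config and seed.

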