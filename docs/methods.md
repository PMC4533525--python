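# Methods

## Model and procedure

Progeny clustering treats a good partition as one whose clusters are
*reconstructable*: if each cluster's feature-wise distribution is
resampled into new, synthetic observations ("progenies") and the pooled
progenies are clustered again, progenies should return to their cluster
of origin. The method assumes observations are exchangeable within a
cluster and — crucially — that features vary independently within a
cluster, since each progeny coordinate is drawn from its feature's
marginal. For data with strongly dependent features the estimator offers
z-scoring and a PCA pre-transform (both off by default) to move the
analysis into an approximately orthogonal feature space; applying the
method to raw, highly correlated features should be done with caution.

For a candidate K the pipeline is: cluster the N×M data once into K
groups; R times, draw n progenies per cluster (each feature
independently, uniformly with replacement from the cluster members),
pool the K·n progenies, re-cluster them into K groups with the same
backend, and record the binary co-occurrence matrix Q. The entrywise
mean of the R matrices is the co-occurrence probability matrix P.
Because progenies are ordered by source cluster, P has K diagonal
("true") n×n blocks and (K−1)·K off-diagonal ("false") blocks, and the
stability score is

    S = mean of true-block entries (diagonal excluded)
        ─────────────────────────────────────────────
        mean of false-block entries

Diagonal entries of P are identically 1 and carry no information, so
they are excluded from the numerator; using means rather than sums makes
S invariant to block size and hence comparable across K. Whether the
initial clustering is recomputed per repetition is an open choice; it is
computed once per K here — the repetition loop measures the
reproducibility of *that* partition, and this is the cheaper
convention.

## Reference correction and selection

Even structureless data yields S > 1 at some K (splitting any point
cloud into more pieces manufactures stronger cluster identities, and
empirically S grows roughly linearly in K on uniform noise). T reference
datasets are therefore drawn uniformly over each feature's observed
range — the bounding-box null, chosen for its simplicity; a
PCA-aligned-box null is a known alternative that is not implemented —
and scored identically. Selection uses either

* greatest score: argmax_K D_K with D_K = S_K − mean_t S^ref_{t,K}, or
* greatest gap: argmax_K (2·S_K − S_{K−1} − S_{K+1}) over interior K.

The gap is a discrete second difference, so the near-linear reference
trend cancels and the criterion runs reference-free by default (a
`gap_on_difference` flag applies it to D instead for users who want the
full correction; a `log_ratio` flag compares scores on the log scale).
The gap criterion cannot assess the endpoints K_min and K_max; the score
criterion can, but on weakly structured data its curve approaches the
linear reference shape and the argmax drifts to K_max — the estimator
attaches a warning when the greatest score lands on K_max, and a
stronger one when the score curve is additionally near-linear
(Pearson r > 0.99 against K). Ties in either argmax break toward the
smallest K, favouring parsimony.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| k_min, k_max | 2, 10 | candidate range; k_max ≤ N |
| n_progenies | 10 | progenies per cluster; minimum 2 (with n = 1 the true blocks are empty after diagonal exclusion); 5–20 give near-identical curves on the benchmarks |
| n_repeats (R) | 100 | co-occurrence repetitions; controls Monte-Carlo error of P |
| n_references (T) | 10 | reference datasets; only the score criterion needs them |
| method | "kmeans" | backend; "ward" ships as the second contract implementation |

## Numerical choices

* **ε-floor.** A perfectly block-diagonal P has false mean 0; the
  denominator is floored at ε = 1/(R·N_false), N_false = (K−1)·K·n² —
  one chance co-occurrence in R rounds, the smallest probability the
  simulation can resolve — keeping S finite and comparable.
* **k-means backend.** Lloyd's algorithm, squared-Euclidean distance,
  k-means++ seeding, best within-cluster sum of squares over 10
  restarts, max 300 iterations, relative tolerance 1e-4. The inner loop
  re-clusters thousands of tiny progeny sets, where per-call estimator
  overhead dominates, so all restarts run batched as stacked numpy
  operations; a test verifies the partition agrees with scikit-learn's
  KMeans on separated data and matches its WCSS on unstructured data.
* **Ward backend.** `sklearn.cluster.AgglomerativeClustering` with Ward
  linkage on Euclidean distance (the squared-distance Ward convention),
  cut at K groups; deterministic, and always returns exactly K non-empty
  clusters even with duplicated progeny rows.
* **Degenerate runs.** A backend returning an empty cluster is retried
  with a fresh initialisation up to 10 times, then raises. Constant
  columns produce constant reference columns (allowed, logged). Missing
  or non-finite values are rejected at load — progeny sampling has no
  semantics for gaps, so no imputation is attempted.
* **Randomness.** One master `SeedSequence` spawns, in fixed order,
  (1) the stream of the original-data curve and (2) the reference
  stream; within a curve each candidate K spawns separate children for
  the initial clustering and the repetition loop. Runs with the same
  seed are bitwise identical; per-K streams do not interact.

## Synthetic benchmarks

`make_gauss_2d` draws three clusters of 50 points around (−1, 2), (2, 0)
and (−1, −2) with identity covariance — well separated but touching.
`make_gauss_10d` draws four clusters of 50 around (±4, ±4) in the first
two dimensions and fills eight further dimensions with standard-normal
noise, probing robustness to uninformative features.
`add_feature_noise` overlays N(0, σ²) on every entry for sensitivity
sweeps (σ from 0.1 to 1.5 is the intended range). These generators
emulate compact, spherical, equally sized clusters; they do not emulate
unequal cluster sizes, non-Gaussian shapes, correlated features or
outliers, so passing the benchmark tests demonstrates correct recovery
under favourable geometry, not performance on messy real data — the
Iris test (overlapping species, score criterion selects 2) is the only
real-data check in the suite.

## Problem sizes used in tests

The test and acceptance runs use the default parameterisation
unreduced (K 2–10, n ∈ {5, 10, 20}, R = 100, T = 10) on the full-size
benchmarks (150×2, 200×10, Iris 150×4), ten regenerations for the
repeatability check, R = 500 with twelve replicates for the
random-label null, and T = 10 for the reference-linearity check.
Structural tests (API, I/O, determinism) use reduced configurations
since the properties they check do not depend on Monte-Carlo precision.

## Known limitations

* Feature independence within clusters is assumed by construction.
* The score compares partitions produced by the *same* backend; it does
  not rank different backends against each other.
* The gap criterion never selects K_min or K_max; the score criterion
  is unreliable when its curve is near-linear (see the warning logic).
* Reference generation ignores feature correlation (bounding-box null).
* No parallel execution; the batched k-means already saturates one core
  on the intended problem sizes.
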