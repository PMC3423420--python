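# Methods

## Overview

`temponet` infers a small directed network over *temporal templates* —
representative expression profiles of co-regulated transcript clusters —
from short time-course expression data.  The pipeline has three stages:

1. **Filtering and clustering.**  Replicates are averaged on the log2
   scale; transcripts whose profile range (max − min over time) is below a
   threshold (default 0.5 log2 units) are dropped.  Remaining profiles are
   grouped by k-means under the correlation distance inside a consensus
   resampling loop, and the cluster count K is chosen from the consensus
   CDF.
2. **Transition inference.**  The K template profiles (and N
   pseudo-replicate matrices sampled one member per cluster) are linked
   across consecutive time points by a time-varying linear model
   `v_{t+1} = W^(t) v_t`, fitted with a sliding-window weighted loss, a
   temporal-smoothness penalty (weight λ₁) and an entrywise L1 penalty
   (weight λ₂).
3. **Model selection.**  (λ₁, λ₂) are chosen on a grid by BIC.

## Assumptions

- Expression values are log2-scale and already normalized (RMA-style);
  replicate collapse is an arithmetic mean on that scale.
- The "fold change" filter is interpreted on the log2 scale: a transcript
  must span at least 0.5 log2 units across the collapsed time course.  A
  linear-scale cut would discard up- and down-regulated genes
  asymmetrically.
- One treatment arm per run; arms are compared by running the pipeline
  twice and comparing template counts and edge sets.
- Dynamics between templates are linear and homogeneous (no intercept):
  templates are standardized to zero mean and unit variance across time
  upstream, which removes the need for an offset and makes transition
  magnitudes comparable across templates.
- The network may rewire over time, but slowly: matrices at nearby
  transitions are penalized toward each other.
- Causality is meant weakly — a directed edge is a hypothesis that one
  template's level helps predict another's at the next time point, not a
  demonstrated mechanism.

## Clustering details

Profiles are row-standardized (population variance), after which
`1 − Pearson(x, c)` is a monotone function of the dot product with a
standardized centroid.  Lloyd iterations assign each profile to the
highest-correlation centroid and recompute centroids as member means
re-standardized each step (the MATLAB 'correlation' convention), for at
most 100 iterations; an emptied cluster is reseeded with the globally
worst-fit profile.  A zero-variance profile is an error naming the
transcript, because its correlation to anything is undefined.

Consensus clustering runs `n_runs` (default 1000) k-means fits per
candidate K, each on a random subsample of the transcripts (rate 0.8,
without replacement).  The consensus matrix entry (i, j) is the fraction
of runs containing both i and j in which they co-clustered; pairs never
co-sampled get consensus 0 with a logged warning.  Run r of candidate K
uses seed `base_seed + candidate_offset + r`, so any individual run can be
reproduced.  The area under the empirical CDF of the upper-triangle
consensus values is computed exactly for the step function; the cluster
count is the largest K whose relative area increase Δ(K) exceeds 0.1.
This automatic rule stands in for a visual-inspection choice; the CLI
therefore keeps a `--k` override.  A flat Δ curve falls back to the
smallest candidate with a warning.

Templates are cluster means (of the raw collapsed profiles) standardized
across time; the mean was chosen over a medoid as the conventional summary.
Pseudo-replicate matrices draw one member per cluster uniformly at random
(standardized profile); with cluster sizes m_k there are Π m_k distinct
matrices, and duplicates are allowed.

## Inference details

The loss for the block centred at transition `t̂` includes the transitions
`t̂ .. t̂+Δ` (forward window, clipped at the last valid transition) with
weight `ω(t, t̂) = exp(−(t−t̂)²/2σ²)`; defaults Δ=2, σ=1, ω=1 at the
centre.  The functional form of the decay is a package choice (Gaussian,
with an exponential alternative); only the qualitative shape — smoothly
decaying forward weights — is prescribed by the protocol.  Window
distances are measured in frame indices, not hours, so unevenly spaced
time points (1, 2, 4, 8 h) are treated as equally spaced frames.

The loss is *averaged* over the N pseudo-sample matrices rather than
summed, so λ₁ and λ₂ keep the same meaning regardless of N; both penalties
are applied once.  There are T−1 transition matrices — the only count
consistent with the model mapping t to t+1.  Diagonal entries are
penalized like all others.

All solver work runs on sufficient statistics
(`A_s = Σ_t ω mean_n v_t v_tᵀ`, `B_s = Σ_t ω mean_n v_{t+1} v_tᵀ`), so
fitting cost is independent of N once the statistics are formed.

**Block coordinate descent (production).**  Blocks are cycled in time
order; each block subproblem (a K²-variable L1-regularized quadratic,
other blocks fixed through the smoothness coupling) is solved by proximal
gradient with backtracking line search and soft-thresholding, inner
relative tolerance 1e-8 (max 5000 iterations), falling back to the
guaranteed-descent step 1/L with L the exact Lipschitz constant
`2(eig_max(A_s) + λ₁ Σ M(s,·))`.  The outer loop stops when the relative
total-objective change falls below 1e-6 (max 500 cycles); non-convergence
sets a flag, never raises.  The objective history is recorded per cycle
and is non-increasing.  With very strong smoothness coupling (λ₁ ≳ 1e4)
the consensus mode of the blocks moves O(1/λ₁) per cold-started cycle; λ₁
sweeps should therefore warm-start each fit from the previous solution
(`model.fit(start=...)`), the same pathwise strategy coordinate-descent
lasso solvers use.

**Joint reference solve (oracle).**  The fully vectorized problem — all
(T−1)K² coefficients at once — is reformulated with the standard
positive/negative split `w = p − q`, `p, q ≥ 0`, making the objective
smooth over bound constraints, and solved with L-BFGS-B at tight
tolerances, followed by an exact KKT polish on the detected support (kept
only when it passes the off-support subgradient check and lowers the
objective).  It is restricted to 2000 variables and exists to cross-check
the production solver; on random instances the two agree to relative
~1e-12.

`lambda_max` (the smallest λ₂ for which the all-zero series is optimal) is
computed from the subgradient condition at zero: `max_s 2·max|B_s|`.

**Degeneracies.**  With λ₂ = 0 and rank-deficient `A_s` the problem is
underdetermined; the solver still returns (the proximal path from the zero
start), but no minimum-norm property is asserted.  With any λ₂ > 0 the
unidentifiable coordinates are driven to zero, which is also why tiny λ₂
values are used for "unregularized-like" fits in validation.

## BIC selection

The selection criterion is the Gaussian-likelihood BIC with the lasso
degrees-of-freedom convention:

```
BIC = n_eff · ln(RSS / n_eff) + df · ln(n_eff)
n_eff = N · K · (T−1),   df = #{|w| > 1e-6}
```

where RSS is the unpenalized loss term at the solution.  The default grid
crosses λ₁, λ₂ ∈ {1e-3, 1e-2, 0.1, 1, 10}.  The minimizer is selected;
ties break toward the larger (λ₁, λ₂) pair (smoother/sparser), which also
makes the selection invariant to grid order.  A perfect fit (RSS = 0)
returns a −∞ sentinel with a warning.  Because the exact normalization of
a BIC is convention-dependent, downstream use relies only on the *ranking*
of candidates, never on absolute BIC values.

## Synthetic validation design

The generator builds K×K transition matrices with exactly
`round(density·K²)` nonzero entries uniform in [−1, +1] in the first
matrix; each later matrix copies its predecessor and resamples `n_perturb`
entry positions (fresh uniform value with probability `density`, else
zero, preserving expected density).  Defaults match the validation design
the protocol was demonstrated on: K=9, T=4, density 0.1, 10 perturbed
entries, 10% proportional noise.

Each observation is an **independent trajectory**: a fresh standard-normal
initial state propagated through the true matrices, plus entrywise
Gaussian noise with sd `noise_frac·|clean value|` (entries whose clean
value is exactly zero use `noise_frac` times the trajectory-wide RMS, so
"10% of the signal" remains meaningful there).  Independent initial states
are what make the noiseless regime determined once `n_samples ≥ K`; noisy
copies of a single trajectory would leave every block rank-deficient.
`n_samples` defaults to 20.

**Nonsingular backbone.**  A singular transition matrix collapses state
dimensions, making all later transitions partially unidentifiable even
from noiseless data.  When the nonzero budget allows (`nnz ≥ K`) the
sparsity pattern is therefore seeded with a random permutation backbone —
one nonzero per row and column, magnitude at least 0.1, never resampled by
the perturbation — so every truth matrix is invertible and the propagated
state keeps full rank.  The default 9-node design (nnz = 8 < K) is below
that budget and uses plain uniform placement; its trajectories *do* lose
rank, which is why support-recovery F1 rather than coefficient RMSE is the
metric there, and why even an ideal estimator cannot reach F1 = 1.

`planted_cluster_profiles` builds clustering test data: cluster centres
are regular-simplex vertices embedded in the zero-mean subspace of R^T and
z-scored (pairwise correlation exactly −1/(K−1), the most-separated
arrangement possible under the correlation distance), with Gaussian
perturbations (default sd 0.15, keeping within-cluster correlations
≈ 0.98).

What the synthetic data does **not** emulate: probe-level microarray noise,
RMA artifacts, correlated replicate structure, unequal cluster sizes and
partially overlapping temporal signatures of real transcriptome data.
Passing the synthetic benchmarks shows the estimator recovers the model
class it assumes; it does not certify edge-level accuracy on biological
data, where the linearity and smooth-rewiring assumptions are themselves
approximations.

## Numerical choices

- Row standardization uses population (ddof = 0) variance.
- Soft-threshold scale and the BIC df cutoff share zero_tol = 1e-6.
- Support threshold for recovery metrics and network export: 1e-3 in
  coefficient magnitude.
- Precision is defined as 1 when no edges are predicted; sign accuracy is
  computed over true positives (1 when there are none).
- Exact zero at λ₂ = λ_max is achieved because soft-thresholding maps ties
  to zero.
- Run manifests hash stage outputs written with 12-significant-digit
  floats, so re-runs with the same config and seeds reproduce outputs
  bit-for-bit.

## Problem sizes used in validation

The bundled validation scripts use the study-scale designs directly (9
nodes, 4 states, 50 samples; 40 profiles over 4 time points for
clustering) and small random instances (K ≤ 4, T ≤ 4) for solver
cross-checks; consensus runs use 100 resamples per candidate K in the
seeded replicate studies and the full 1000 in the CLI defaults.

## Known limitations

- The number of templates chosen at the clustering stage alters the
  topology of the downstream network; the Δ(K) = 0.1 rule is a reasonable
  automatic stand-in but no substitute for inspecting the consensus CDF.
- Edges carry no statistical significance; the method returns the sparse
  point estimate the penalties select.
- Frame-index windows ignore the actual spacing of time points.
- BCD without warm starts converges impractically slowly for λ₁ ≳ 1e4.
- For very large K the joint reference solver is unavailable (by design)
  and no low-rank approximation of the Hessian is provided.
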