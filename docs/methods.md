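# Methods

## Model and procedure

`fedharmony` integrates per-site single-cell embeddings by alternating
maximum-diversity soft clustering with a per-cluster linear
(mixture-of-experts) batch correction, executed so that institutes
exchange only cluster-level aggregates with a coordinating server.

Notation: d embedding dimensions, B sites/batches, N_b cells at site b,
N = Σ N_b, K clusters. Z(b) is site b's d×N_b embedding, R(b) its K×N_b
soft assignment matrix (columns sum to 1), Y the d×K centroid matrix,
O = Rφᵀ the K×B cluster/batch co-occurrence and E = rowsum(O)·Prᵀ its
independence expectation, with Pr_b = N_b/N.

One run proceeds as:

1. **Initialization.** Centroids by federated k-means: each site
   proposes local k-means centroids with occupancy counts; the server
   seeds K centroids by weighted k-means++ over the pooled candidates and
   refines them with aggregated Lloyd rounds (sites send per-centroid
   coordinate sums and counts). Sites then initialize R(b) with the
   penalty-free softmax of the cosine distance to the broadcast
   centroids, and the server assembles O from per-site row sums of R(b)
   and E from O.
2. **Clustering phase** (per outer round, up to `max_inner_iterations`
   passes): the server sums Z(b)R(b)ᵀ contributions into new centroids;
   sites are visited in ascending index order, each updating its R(b) in
   random within-site blocks. A block's mass is removed from O/E, its
   columns recomputed as
   R_ki ∝ ((E_kb+1)/(O_kb+1))^θ · exp(−2(1−Y_kᵀZ_i)/σ), and the new mass
   added back, so O = Rφᵀ holds at every hand-off. The objective is
   assembled from per-site scalar partial sums; the phase stops when its
   relative change falls below `tol`.
3. **Correction phase.** Each site sends the per-cluster moments of the
   *input* embedding (the correction is re-derived from the uncorrected
   embedding every round, so rounds do not compound); the server solves
   the per-cluster ridge system, zeroes the intercept row of every W_k
   before broadcasting (sites never see batch-independent terms), and
   each site subtracts its own batch's correction rows locally, then
   re-normalizes columns for the next clustering phase.
4. Outer rounds repeat until the clustering objective stabilizes
   (relative change < `tol`) or `max_rounds` is reached.

All clustering operates on column-L2-normalized embeddings, so the
squared distance is the cosine form 2(1 − Y_kᵀZ_i); corrections are
applied on the original scale.

The centralized reference (`centralized.run_harmony`) is the same loop
on pooled data, with pooled k-means++ initialization and blocks drawn
across all cells. Shared numerical kernels guarantee that wherever the
two paths are algebraically identical, they are computationally
identical too; with one site and matched initial centroids the two runs
coincide.

### Sign of the diversity penalty

The update uses ((E+1)/(O+1))^θ — cells are pushed *away* from clusters
in which their own batch is over-represented. This is the unique reading
consistent with the clustering objective (whose diversity term
σθ·R·log(O/E) is a penalty) and with the first-order error analysis of
the block update; it also matches the reference Harmony implementations.
The +1 smoothing is used in both the update and the reported objective
so that empty clusters are well-defined.

### Ridge convention

The ridge Λ penalizes only the batch rows of W_k; the intercept row is
unpenalized (configurable: `ridge_intercept=True` restores a literal
λI). A consequence worth knowing: with a single batch the batch row of
every W_k is exactly zero — the intercept absorbs the cluster means — so
B = 1 runs return the input embedding unchanged, which is the sensible
behaviour when there is nothing to correct.

## Federation exactness and the block-update error

The correction path is an exact algebraic identity: the normal equations
φ* diag(R_k) Zᵀ and φ* diag(R_k) φ*ᵀ decompose into per-site moments
T_k(b), S_k(b), so the aggregated solve equals the pooled solve to
numerical precision (asserted at 1e-10 in the tests). The same holds for
the centroid update and the O/E bookkeeping.

The only structural deviation from pooled integration is that update
blocks are drawn within sites. At a fixed state, a sequential within-site
pass differs from the ideal simultaneous update because each block sees
O/E with its own mass removed (and earlier blocks' updates applied). The
per-cell deviation is O(α) in the block fraction; across a pass its
cell-average shrinks as the dataset grows, because the leading
(cluster-independent) part of the perturbation cancels in the softmax
normalization and what remains is driven by sampling fluctuations of the
block composition. `measure_block_error` reports per-block and average
|δR| for a snapshot; `polish_to_ideal_fixed_point` first damps the state
to a fixed point of the simultaneous update (damping 0.3 — the undamped
R → O/E → R iteration oscillates; damping changes the trajectory, not
the fixed point), so the measurement isolates the block-removal effect
rather than residual convergence motion. On the reference scenario the
measured averages are ~1e-7 and behave as the analysis predicts:
nondecreasing in α over {0.02, 0.05, 0.1} and nonincreasing in N over
{500, 2000, 8000}.

A related caveat: the sequential block update minimizes a surrogate
(O/E with the block removed), so the clustering objective is not a
Lyapunov function of a single fixed-Y pass — repeated passes on
far-from-optimum states can raise it by ~1e-4 relative. The property
that holds, and is asserted, is phase-level descent: with centroid
updates interleaved, the objective trace is nonincreasing to within 1e-6
relative slack on all tested runs (exact descent for θ = 0).

## Messages, privacy and accounting

Every exchange is a typed `Message` routed through a `MessageBus` that
audits shapes and meters bytes. The audit fails any payload with an axis
equal to some site's cell count unless the shape is an allowed
(K, d, B, G)-derived shape for its tag; the degenerate collision
N_b = K passes with a warning (a size-based audit cannot distinguish
these) and is documented as a limitation. Soft assignments are never
transmitted: from Y(b) = Z(b)R(b)ᵀ and R(b) a server could reconstruct
Z(b).

Wire encodings are minimal sufficient statistics: the sequential O/E
hand-off carries only the site's own co-occurrence column, the global
row sums and the site's batch frequency (E = rowsum(O)·Prᵀ is exact at
every block boundary, so the server reconstructs the full matrices), and
correction moments travel as the compact pair (d×K weighted sums, K
masses) from which T_k(b)/S_k(b) are rebuilt. Byte accounting uses
float32; computation is float64. One communication round = one
gather/broadcast exchange (a Lloyd step, an inner clustering iteration,
a moments gather, a factor broadcast); at the largest supported default
geometry (K = 100, d = 30, B = 40) every round stays under 1 MB.

The aggregated-moment PCA is deliberately simple and exact: sites send
(Σx, Σxxᵀ, N_b), the server eigendecomposes the pooled (optionally
unit-variance-scaled) covariance and broadcasts loadings with a
deterministic sign convention. The G×G moment exchange is coarser than
per-cell data but richer than cluster aggregates; pipelines that cannot
accept it can supply externally computed embeddings. Feature spaces are
reconciled by sorted intersection, with an optional pooled-dispersion
ranking for selecting highly variable features (default 2,000; the
choice of ranking rule is a design decision — only the intersection step
is fixed by the method).

## Synthetic scenarios

The generator emulates B institutes measuring the same tissue: C cell
types are isotropic Gaussian clusters whose means are drawn once in a
10-dimensional latent space (sd `celltype_spread` = 5) and embedded into
G features through a random linear map — low-rank structure that PCA
recovers. Site b adds a single offset vector of norm `batch_shift_scale`
in feature space (linear, hence removable by a per-cluster linear
correction) plus i.i.d. Gaussian noise (`noise_sd`), and may lack cell
types via per-site proportion rows. An optional Poisson layer produces
count matrices for exercising log-normalization.

The reference evaluation scenario is 3 sites × 1,000 cells, 4 shared
cell types, G = 50 features, shift 5, noise 1, generator seed 7, with
d = 20 principal components — sized so a full federated + centralized
comparison runs in seconds on one CPU. Defaults for the integration:
σ = 0.1, θ = 2, λ = 1, α = 0.05, K = min(100, N/30), tol = 1e-4, at most
10 outer rounds of at most 20 inner iterations — mirroring common
Harmony practice; all configurable.

What the generator does *not* emulate: count overdispersion and dropout,
nested subtype structure, nonlinear batch distortions, spatial
coordinates, or differing modalities across sites. Two consequences for
interpreting results. First, passing tests show the federated path
reproduces the centralized path and removes linear batch offsets; they
do not certify behaviour under realistic scRNA-seq noise. Second,
because the synthetic cell types are featureless blobs, k-means
partitions finer than the true type count are unstable to tiny
perturbations; the federated-vs-centralized ARI comparison therefore
starts both runs from the same initial centroids (the federated k-means
result, computable without pooling), isolating the effect of federation
from initialization luck. `compare(..., matched_init=False)` gives the
fully independent comparison.

## Numerical choices

- Soft assignments via log-domain softmax with per-column max
  subtraction; 0·log 0 = 0 throughout.
- E's block subtraction uses the fixed global batch frequencies
  (E −= outer(s, Pr)), keeping E row-sums tied to O row-sums exactly.
- Empty clusters are allowed everywhere (the +1 smoothing keeps
  penalties finite; empty k-means clusters retain their previous
  centroid; an all-zero R_k yields W_k = 0).
- Singular correction systems (λ = 0 with an empty batch) raise with
  advice to set λ > 0 rather than silently pseudo-inverting.
- Site visit order is fixed ascending; block partitions are reseeded per
  (outer round, inner iteration, site) from the run seed, so runs are
  bit-reproducible given a seed and the pooled reference draws identical
  blocks for B = 1.
- iLISI uses perplexity 30 with 3×perplexity neighbors by default (the
  convention of the original LISI implementation), per-cell bandwidths
  tuned by bisection; values are clipped into [1, B] against rounding.

## Known limitations

- The privacy audit is structural (shapes), not information-theoretic;
  it cannot detect a leak encoded in allowed-shape aggregates, and very
  small clusters make centroid aggregates themselves more revealing.
  Secure aggregation and differential privacy are out of scope.
- Federation is simulated in-process, sequentially; the message layer is
  a narrow interface so a networked transport could replace it, but no
  transport, retry or dropout handling exists.
- A single categorical batch covariate only; no multi-covariate φ.
- TF-IDF/LSI preprocessing for chromatin accessibility data is not
  provided; the pipeline applies log-normalization + PCA to whatever
  counts it is given.
- The aggregated-moment PCA is quadratic in the number of features and
  refuses G > 4,096 (subset to shared highly variable features first).
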