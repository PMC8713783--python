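# Methods

## The local independence test

For a homogeneous group of N cells with expression X (genes × cells,
any nonnegative monotone scale), the method estimates a gene–gene
network *per cell*. For cell j and gene pair (x, y), one-dimensional
bins of cells are centred at cell j's expression values:

    B_x(j) = {i : |X_ix − X_jx| ≤ w_x},   n_x(j) = |B_x(j)|
    B_y(j) = {i : |X_iy − X_jy| ≤ w_y},   n_y(j) = |B_y(j)|
    B_xy(j) = B_x(j) ∩ B_y(j),            n_xy(j) = |B_xy(j)|

The statistic compares the local joint frequency with the product of
the local marginals,

    ρ_xy(j) = n_xy(j)/N − n_x(j)·n_y(j)/N²,

normalised by its asymptotic null standard deviation,

    σ²_xy(j) = n_x(j)·n_y(j)·(N − n_x(j))·(N − n_y(j)) / (N⁴(N − 1)),

giving z_xy(j) = ρ_xy(j)/σ_xy(j), asymptotically standard normal when
x and y are independent in the neighbourhood of cell j. The test is
nonparametric: it makes no linearity or monotonicity assumption, and it
is invariant to monotone rescaling of either gene up to the binning.

**Zero rule.** z_xy(j) is fixed to 0 whenever cell j itself has zero
expression in either gene. A technical zero (dropout) carries no
information about where the cell really sits on that axis, so its local
test is meaningless. Zeros in *other* cells still count as neighbours —
the bin definition has no zero exclusion, deliberately: excluding them
would distort the marginal counts that calibrate σ.

**Degenerate windows.** When n_x ∈ {0, N} or n_y ∈ {0, N}, σ = 0 and z
is defined as 0: a window covering none or all of the sample cannot
discriminate the joint from the product of marginals.

## Window-width iteration

Bandwidth drives the power of the test. Instead of a fixed quantile
range, widths adapt per cell by an iterative local-SD rule:

1. **Initialisation.** B_x(j)(0) contains the cells whose rank-quantile
   of gene x lies within ±q0/2 of cell j's rank-quantile (ties get
   average ranks); likewise B_y(j)(0). Default q0 = 0.1, i.e. a ±5%
   quantile range. Performance is insensitive to q0 over a broad range
   because the iteration quickly forgets the start; q0 is exposed as a
   parameter.
2. **Iteration.** For t = 1, 2, …:
   w_x(t) = SD{X_ix : i ∈ B_y(j)(t−1)} and
   w_y(t) = SD{X_iy : i ∈ B_x(j)(t−1)} — each width comes from the
   *opposite* gene's current bin, coupling the two axes — then both
   bins are rebuilt from the new widths. Boundary ties are inclusive
   (≤), exactly as the set definition reads.
3. **Convergence.** Both memberships identical between successive
   iterations (set identity — exact and scale-free). Default
   max_iter = 10; on non-convergence the iteration-1 bins B(1) are
   used.

Numerical choices:

* The SD is the sample SD (ddof = 1). A bin with a single member has no
  SD; if that happens at t ≥ 2 the cell is declared non-convergent and
  falls back to B(1). At t = 1 the fallback target does not exist yet,
  so the SD of a singleton bin is defined as 0 there (a zero width still
  admits exact ties, including the centre itself).
* The centre cell is always in its own bins (|X_jx − X_jx| = 0 ≤ w).
* The computation is deterministic, and per-cell results are
  independent of the order in which (cell, pair) statistics are
  evaluated; internally all centre cells of one pair are processed as
  one vectorised batch over the N×N difference matrix.

## Thresholding and averaging

Thresholding z at the upper-α standard normal quantile (default
α = 0.05, cutoff ≈ 1.645) gives a 0/1 adjacency per cell. Averaging
adjacencies over a group's cells yields, per gene pair, the fraction of
cells rejecting independence — a coexpression-intensity estimate in
[0, 1]. Thresholding is one-sided by default: the averaged network is a
nonnegative intensity and excess co-occurrence is the signal of
interest; a two-sided mode (|z| against the α/2 quantile) is available
behind a flag.

**Why within-type computation.** Pooling heterogeneous cell types
invites Simpson's paradox: two marker genes independent within a type
but jointly up-shifted in another type appear dependent in the pooled
sample. Networks are therefore computed within cell types (or within
pseudotime bins); the package's Simpson-mixture simulation demonstrates
the inflation directly (pooled rejection rate ~20× the within-type rate
at a 2-SD shift).

## Metacell pooling and pseudotime binning

Raw scRNA-seq profiles are often too sparse for a local test (the zero
rule silences most statistics). Pooling similar cells of one type into
metacells — disjoint groups whose expression is the member mean —
reduces sparsity while preserving within-type structure; metacells are
then treated as cells. Grouping is within-type agglomerative clustering
(Ward linkage, scikit-learn) in the expression space of the analysed
genes, cut at ⌈n/target_size⌉ clusters (default target ≈ 20 cells).
Only the output contract matters for downstream validity — label
purity, approximate size, exact mean expression — not the particular
partitioner; any partitioner meeting it can be substituted.
Pseudotime, when present, is averaged per metacell.

Pseudotime binning divides the (meta)cells of each type into
equal-count contiguous bins of the pseudotime order (sizes differ by at
most one; ties broken by original index, stable). Binning is performed
within cell type so that types with disjoint pseudotime ranges are each
resolved across their own range.

## Grid approximation

The per-cell statistic depends on the centre only through its (x, y)
values, so cells landing in the same cell of a 2-D grid over the
outcome space get near-identical statistics. For each pair, each axis
is cut into k equal-probability (quantile) bins of the positive values;
zeros form their own bin at 0 so the zero rule and the grid interact
predictably. The exact statistic is evaluated once per occupied grid
cell, at its lowest-index member (deterministic, and a real data
point), and broadcast to members; the per-cell zero rule is still
applied individually. When k reaches the number of distinct values on
an axis, each distinct value gets its own bin, so a sufficiently fine
grid reproduces the exact computation bit for bit (verified in tests).
At k = 15 on 300 cells the approximate and exact z vectors correlate
above 0.96.

## Differential-network tests

Given two groups of cells of the same cell type (e.g. case vs
control), per-cell networks are computed **on the pooled cells** and
then split by group membership. This matters: network construction is
conditional on cell type, never on the grouping being tested. If each
group's networks were computed within that group, every cell's
adjacency vector would depend on its group-mates, the vectors would not
be exchangeable under the null, and the permutation tests below would
be sharply anti-conservative (we measured observed p-values pinned at
1/(n_perm+1) in null data). Pooled construction presumes the two
groups share marginal expression distributions — the situation in
which a coexpression difference, not a mean difference, is the target.

**sLED.** With group summaries A₁, A₂ (averaged adjacency, or Pearson
correlation of expression), the statistic is the sparse leading
eigenvalue of s·(A₂ − A₁) maximised over the sign s ∈ {+1, −1}. The
sparse eigenpair is computed by power iteration on the
positive-shifted matrix with soft-thresholding of each update at a
fraction (the sparsity level) of its largest component, initialised at
the dense leading eigenvector; sparsity 0 reduces exactly to the dense
leading eigenpair (checked against `numpy.linalg.eigh` to 1e-8 in
tests). Per-gene leverage is the squared loading, normalised to sum
to 1; the DN (differential-network) genes are the minimal
leverage-sorted prefix with cumulative leverage ≥ 0.9, ties at the
boundary included. The permutation null reshuffles cell→group
assignments and re-summarises (re-averaging precomputed adjacencies for
CSN mode; recomputing correlations for Pearson mode).

When no sparsity level is given it is tuned over the grid
{0, 0.1, 0.2, 0.3} by maximising the observed statistic's standardised
exceedance (obs − mean)/SD over a *separate*, seeded batch of 50 tuning
permutations; the reported p-value then uses fresh permutations at the
chosen level, keeping selection and inference independent and the
p-value valid.

**DISTp.** The energy distance between the two samples of vectorised
per-cell adjacencies,

    E = 2/(nm)·ΣΣ d(u_i, v_j) − 1/n²·ΣΣ d(u_i, u_i′) − 1/m²·ΣΣ d(v_j, v_j′),

with d the Euclidean distance, combined with the same permutation
scheme. Adjacencies (not raw z) are compared: they are the network
objects of interest and bound the distances. All pairwise distances are
computed once; permutations only re-index.

Both tests report p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm) (never
zero, valid under exchangeability; default n_perm = 500). Bonferroni
adjustment (`adjust_pvalues`) handles testing across many cell types.

## Synthetic data

The generator produces the structures the method is evaluated on, via
a Gaussian copula: latent N(0, 1) variables with exchangeable
correlation ρ inside designated gene blocks, mapped through lognormal
marginals (mean `base_mean`, log-scale SD 0.5) so the target mean is
exact, then independent dropout with probability logistic-decreasing in
log mean (defaults give ~10% zeros at mean 2 — moderate sparsity, as
after metacell pooling; raw UMI data are far sparser). The two-group
design keeps marginals identical across groups so that any detected
difference is purely a coexpression difference. The Simpson mixture
shifts the latent means of one marker pair by a chosen number of SDs in
one of two otherwise-identical types; for a balanced mixture the pooled
latent correlation is (s²/4)/(s²/4 + 1), i.e. 0.5 at a 2-SD shift,
while within-type correlation is 0 by construction.

What the generator does **not** emulate: UMI count noise, batch
effects, trajectory-shaped (smoothly varying) correlation, gene-length
or capture biases, and empirically calibrated mean–variance
relationships. Passing tests therefore establish correctness of the
statistics and qualitative behaviour (calibration, power, paradox
avoidance, block recovery), not performance on any particular real
dataset.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use sizes at which
every property is measurable with comfortable margins while keeping the
whole run in minutes on one CPU: 100 random instances (N ≤ 50, G ≤ 6)
for the oracle check; N = 500, 20 replicates for per-cell test
calibration/power; 500 cells/type for the Simpson contrast; 200 cells,
30 genes for block recovery; 300 cells, k = 15 for grid accuracy; and
20 replicates × 200 permutations for the two-sample tests (calibration
at 100 cells/group with a shared 3-gene ρ = 0.5 block; power at 200
cells/group with a 10-gene ρ = 0.7 block in one group among 20 genes).

## Known limitations

* The local test needs moderate group sizes (N ≥ ~50 for useful power;
  N < 3 is rejected outright) and non-degenerate expression spread.
* The adaptive window makes per-pair cost O(N²) per iteration; the grid
  approximation or metacell pooling is recommended beyond a few
  thousand cells per group.
* Pooled-construction two-sample testing assumes equal marginals
  between the arms; strong differential expression between arms would
  reintroduce a Simpson-type artefact into the comparison.
* The sLED statistic uses the single leading sparse eigenvalue; diffuse
  differences spread over many weak directions favour DISTp instead.
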