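# Methods

## Model

A PPI network on N proteins is a symmetric binary adjacency matrix X with
zero diagonal (self-interactions are dropped on load: complexes are defined
by interactions *between* their members).  The factorization X ≈ AY places
every item (column) in exactly one of m clusters — one 1 per column of Y —
and every feature (row) likewise in A; for symmetric input A = Yᵀ, so the
model is a hard partition of the proteins and the Boolean reconstruction
(AY)_rt = 1 iff r and t share a cluster.

The generative story: item t joins cluster j with probability α_j (features
with β_j in the rectangular case); each modeled entry of X is an
independent Bernoulli flip of the reconstruction with a single symmetric
flip rate ε ∈ (0,1).  One rate for both error directions is the simplest
binary-noise likelihood that matches the motivation — interaction screens
produce both false positives and false negatives — and keeps the
likelihood a sum of entrywise log-Bernoullis.  In symmetric mode only
unordered pairs r < t are modeled; ordered pairs would count each
interaction twice and the diagonal is not an observation.  α and β carry
symmetric Dirichlet priors and ε a matching Beta-style smoothing, all
governed by one shared hyperparameter κ.

The harmony functional being maximized is

    H = Σ_t ln α_{c(t)} + Σ_r ln β_{g(r)} + D ln ε + (P − D) ln(1 − ε)
        + (κ − 1)(Σ_j ln α_j + Σ_j ln β_j)

with c, g the hard assignments, P the modeled-entry count (N(N−1)/2
symmetric, nN rectangular) and D the number of disagreements between X and
the reconstruction.  The prior term is the log-density of a symmetric
Dirichlet(κ) up to constants; at the default κ = 1 it vanishes.

## Fitting

Each iteration runs three steps.

**Yang-step (reassignment).**  The contribution of item t under candidate
cluster j reduces, up to item-wise constants, to
ln α_j + (k_j − 2 e_tj)(ln ε − ln(1 − ε)), where k_j is the opposite-side
size of cluster j (excluding t itself in symmetric mode) and e_tj the
number of t's interactions into cluster j.  Ties break to the lowest
cluster index.  Symmetric mode sweeps items sequentially in index order,
each move scored against the current state: because an item's score depends
on the other items' clusters, moving everyone simultaneously against the
stale state lets whole groups pile into the same cluster — in practice ε
then inflates and the factorization collapses to one cluster — whereas
one-at-a-time moves each weakly increase H at fixed parameters.
Rectangular mode updates all columns synchronously given the rows, then
all rows given the new columns; within a block the scores are mutually
independent, so the block update is exact coordinate ascent.  (Updating
both blocks at once against the stale state lets row and column labels
leapfrog and oscillate.)

**Ying-step (parameters).**  α_j = (n_j + κ)/(N + mκ), β analogous, and
ε = (D + κ)/(P + 2κ).  With κ > 0 everything stays strictly inside the
simplex/interval.  Because the estimates are κ-smoothed while H carries the
(κ−1) prior exponent, the Ying-step tracks rather than exactly maximizes H;
the discrepancy is O(m/N) and the fitter always retains the best-H state
seen.

**Model-Selection-Step (pruning).**  Clusters holding nothing are deleted
and α, β renormalized; the renormalized probabilities coincide exactly with
the smoothed estimates recomputed at the reduced m.  Symmetric mode prunes
item-empty clusters; rectangular mode prunes only clusters empty of both
rows and columns, since a cluster still holding rows shapes the
reconstruction.  This is the sole mechanism by which m falls from m_init:
an empty cluster only costs prior mass under H, so maximization starves
unnecessary clusters.

**Termination.**  Assignment fixed point, or |ΔH| < tol·P with
tol = 1e−9 per modeled entry (scale-aware), or max_iter = 200, or a repeat
of a previously seen assignment vector (cycle detector; the best-H state
seen is returned).  Because H is non-convex, `fit_multi` restarts from
seeds seed, seed+1, … and returns the harmony-best model along with every
restart, supporting both the best-restart ("opt") and metric-averaging
("avg") evaluation protocols.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `m_init` | 300 | starting/upper-bound cluster count; 300 suits catalogue-scale test graphs, 600 large real networks; anything comfortably above the expected complex count works |
| `kappa` | 1 | shared Dirichlet/Beta smoothing; κ = 1 removes the prior term from H while keeping estimates strictly positive |
| `restarts` | 1 (`fit_multi` callers typically use 10; exhaustive protocols use up to 10³) | random initializations |
| `tol` | 1e−9 per modeled entry | harmony convergence tolerance |
| `inflation` (MCL) | 1.8 | flow contraction; larger → finer clusters |
| `alpha_sc`, `beta_sc` (SC) | 10, 1 | eigenvector selection and connectivity-filter percentages |

MCL adds self-loops of weight 1 before column normalization (damps parity
oscillation), prunes flow entries below 1e−5 for tractability (0 = exact),
and reads clusters as the weakly connected components of the limit
matrix's nonzero structure — a partition by construction.  For SC the
number of leading eigenvectors defaults to the count of eigenvalues above
the mean degree; the selection count per eigenvector is
floor(n·alpha_sc/100).

## Synthetic data and what it does (not) show

`generate_planted_complexes` plants k complexes with sizes uniform on a
range (defaults 3–10, matching curated catalogue scale), an optional
fraction sharing one member with an earlier complex (references overlap in
real catalogues), and optional background proteins in no complex.
`complexes_to_graph` cliquifies each complex — the noise-free limit of a
co-complex network.  `perturb_graph` then adds round(a·|E|) uniformly
sampled non-edges of the original graph and deletes round(d·|E|) original
edges (round = half away from zero); sampling additions from non-edges and
deletions from edges makes the two draws collision-free and the output
edge count exact.  The benchmark grid a ∈ {0, .05, .1, .2, .4, .8, 1.0} ×
d ∈ {0, .05, .1, .2, .4, .8} with 10 replicate seeds per cell ships as the
default protocol.

The expression generator plants k non-overlapping constant biclusters on
the block diagonal (defaults 100 genes × 50 conditions, 10 blocks, signal
1.0) in N(0, noise_sd²) background noise; the default binarization
threshold is signal/2, the midpoint rule that reproduces the exact block
indicator in the zero-noise limit.

These generators produce clique-true complexes, uniform edge noise and
constant-signal biclusters.  Real networks have density gradients inside
complexes, degree-dependent error rates and shared subunits; passing the
planted-recovery and degradation tests therefore demonstrates the
correctness and noise-robustness of the machinery, not field performance
on any particular database snapshot.

## Evaluation

From the contingency table T_ij of shared proteins between reference
complex i (size N_i) and predicted cluster j:
Sn = Σ_i max_j T_ij / Σ_i N_i, PPV = Σ_j max_i T_ij / Σ_j T_.j,
Acc = √(Sn·PPV), and Sep = √(Sep_co·Sep_cl) with
sep_ij = (T_ij/T_i.)(T_ij/T_.j), Sep_co the sep-sum over n_ref and Sep_cl
over n_pred.  Division conventions: 0/0 terms count 0, a prediction set
with no reference overlap has PPV 0.  Predicted proteins outside the
reference universe inflate cluster sizes but contribute nothing to T;
reference complexes may overlap and are not deduplicated.  The
biclustering match score is the mean best Jaccard overlap of gene sets,
directional (relevance: found vs truth; recovery: truth vs found); only
fitted clusters holding at least one gene and one condition count as
biclusters.

## Numerical and design notes

- Node order is first appearance in the input stream; all generators and
  fits are pure functions of their arguments including seeds, so every
  pipeline is replayable byte-for-byte.
- Assignment ties (including the isolated-node case) resolve to the lowest
  cluster index; `np.argmax` first-maximum semantics implement this.
- ε is clipped to [1e−12, 1−1e−12] after estimation as a guard; with κ > 0
  the estimate cannot actually reach the boundary.
- Degenerate inputs: an all-zero matrix is globally best explained by a
  single cluster with ε ≈ 1 (everything is noise) — enumeration at N = 6
  confirms it — but coordinate ascent from a multi-cluster start settles
  at an even split, since isolated items always prefer the smallest
  cluster and no single move crosses the valley.  This is the known
  strict-local-optimum caveat of the alternation; multi-restart mitigates
  but does not remove it on structure-free inputs.
- Benchmark problem sizes in the tests (50-complex catalogues, m_init 100,
  3–10 restarts; 100 small instances for the enumeration oracle) are the
  package's desk-scale defaults for routine validation; the full grid with
  catalogue-scale settings runs through the same `BenchmarkSpec` surface.
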