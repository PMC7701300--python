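# Methods

## Problem and data model

The input is a bipartite association structure between `n_m` miRNAs and
`n_d` diseases, held as a binary matrix `Y` with miRNAs as rows. One
orientation convention is used across the whole package (readers, kernels,
factorization, reports) because curated exports and the surrounding
literature freely flip rows and columns. Names are trimmed and matched
case-insensitively but stored as first seen; duplicate edges collapse to a
single 1 with a logged count. Unknown pairs are 0: the model treats them as
weak negatives rather than missing values, so the observation mask in the
objective is identically 1. This matches how the interaction-profile
kernels consume `Y` and how the evaluation protocols define negatives.

## Disease semantic similarity

Each disease is located in a MeSH-style hierarchy by one or more
dot-delimited tree numbers; every dot-prefix of a tree number is an
ancestor heading. The disease's DAG is the union of those prefix chains,
with parent→child edges between consecutive prefixes; a disease with
several tree numbers has several "self" leaves, deduplicating shared
ancestors. The contribution of node `t` to disease `d` is

    D_d(t) = 1                                   if t is a position of d
    D_d(t) = max { Δ · D_d(t')  :  t' child of t }  otherwise

evaluated in reverse topological order, with decay `Δ ∈ (0, 1)`, default
0.5 (the conventional choice in this similarity family; larger Δ weights
deep shared ancestry more). Similarity of two diseases is the sum of
`D_i(t) + D_j(t)` over shared nodes divided by the total contribution mass
of both DAGs — 1 for identical DAGs, 0 for disjoint ones. Node identity is
the tree-number string, so two diseases share a node exactly when their
prefix sets overlap.

A disease is considered to "have" semantic similarity when it has at least
one tree number; this is a per-entity property, so a pair of annotated
diseases with disjoint DAGs legitimately gets semantic similarity 0 rather
than a kernel fallback.

## Interaction-profile kernels and integration

The Gaussian interaction-profile kernel on either axis is
`K(i,j) = exp(−γ ‖p_i − p_j‖²)` where `p_i` is the entity's binary profile
(row or column of `Y`) and `γ = γ′ / mean_i ‖p_i‖²`. The raw bandwidth `γ′`
defaults to 1, the convention of this kernel construction; the
normalization makes the kernel scale with network density. An all-zero `Y`
leaves γ undefined and is an error.

Integration is piecewise per entry: the curated value (semantic similarity
for diseases, a supplied functional-similarity matrix for miRNAs) is used
when *both* entities are covered by the curated source, the kernel value
otherwise; the diagonal is forced to 1 and a per-entry provenance mask is
kept. In cross-validation the kernels are recomputed from each fold's
training matrix, never the full matrix, so held-out positives cannot leak
through the profiles. The functional-similarity matrix is consumed as
input (its construction from disease-term overlaps is out of scope); the
synthetic generator fabricates one.

## Factorization

Objective (observation mask ≡ 1):

    J(W,H) = ‖Y − WHᵀ‖²_F + λ_l(‖W‖²_F + ‖H‖²_F)
           + λ_m Σ_{i<p} ‖w_i − w_p‖² S_m[i,p]
           + λ_d Σ_{j<q} ‖h_j − h_q‖² S_d[j,q]

The graph penalties are defined over unordered entity pairs, which equals
`λ tr(WᵀL W)` with `L = D − S`, `D = diag(rowsums(S))`. This convention is
deliberate: it is the one under which the multiplicative updates

    W ← W ∘ (YH + λ_m S_m W) / (WHᵀH + λ_l W + λ_m D_m W + ε)
    H ← H ∘ (YᵀW + λ_d S_d H) / (HWᵀW + λ_l H + λ_d D_d H + ε)

are exactly the KKT complementary-slackness rules of `J`, so the objective
trace is provably non-increasing and the stationarity residual `|W ∘ ∇J|`
is the right convergence diagnostic. (Defining the penalty over ordered
pairs instead doubles the effective λ and merely relabels the grid.)
Updates alternate — `H` uses the freshly updated `W` — since the
stationarity conditions are silent on order and alternation is the
standard descent scheme. Self-similarity diagonal entries contribute
nothing to the penalty (they cancel in `L`).

Numerical choices:

* **Initialization**: `W, H ~ Uniform(0.01, 1.01) · sqrt(mean(Y)/k)`,
  seeded. Strict positivity avoids lock-in at zero (a multiplicative
  update can never leave 0); the scale puts the initial `WHᵀ` at the data's
  magnitude.
* **ε = 1e-10** added to denominators guards 0/0 without measurably
  perturbing the fixed points.
* **Convergence**: relative objective change < `tol` (default 1e-6) or
  `max_iter` (default 500). The trace includes the initial objective, so a
  run that stops after one update has a trace of length 2.
* **Defaults**: `λ_m = λ_d = 0.2` (the best cell of the sensitivity grid
  this model family reports; performance decays slowly as they grow);
  `λ_l = 1.0` and `k = 50` are not pinned down by the source model family
  and are package choices — `k = 50` is customary for association matrices
  of a few hundred entities per side, and `λ_l = 1` keeps the factor norms
  bounded without dominating the fit. Both are configurable and worth
  sweeping on new data.

Scores are `Y* = WHᵀ`; per-disease candidate lists exclude already-known
miRNAs and break score ties by miRNA index (stable, documented, and
deterministic).

## Evaluation protocols

* **Global fivefold CV**: the known positives are partitioned uniformly at
  random (seeded; fold sizes differ by ≤ 1). Per fold: held-out positives
  are zeroed in the training matrix, similarities recomputed from it, the
  model refit, and the held-out positives scored against *all* pairs never
  labelled positive in the full dataset — the negative-set convention of
  the comparison literature. Both per-fold and pooled (concatenated
  scores) AUC/AUPR are reported; note the pooled negative scores appear
  once per fold, each scored by that fold's model.
* **Cold-start CV_d**: a disease's entire column is zeroed before
  refitting; only the disease-similarity graph can then inform its latent
  vector. Diseases with no positives (nothing to recover) or all-positive
  columns (no negatives to rank against) are skipped with a warning. The
  summary is the mean of per-disease AUCs.
* **Metrics**: ROC and PR curves by threshold sweep with tied scores
  grouped into one step; areas by trapezoid (the ROC trapezoid equals the
  pairwise Mann–Whitney statistic with ties counted ½). The PR curve
  carries the conventional zero-recall anchor at precision 1. Single-class
  inputs are an error, not a silent 0.5.
* **Null calibration**: the label-shuffled null permutes the labels of the
  pooled (score, label) pairs. Shuffling `Y` itself instead would leak
  degree structure into both scores and labels and sit above 0.5 — that
  would be a biased null, not a property of the model.

## Synthetic data

The generator plants exactly the structure the graph penalties assume:
entities are assigned to `k_true` groups (shuffled round-robin, so no group
is empty); factors load 1.0 on the own group plus Uniform(0, 0.2)
background; the ground-truth score matrix `P = W*H*ᵀ` is row-normalized;
the top `density` fraction of cells becomes the known positives. `noise`
relocates that fraction of planted positives to uniformly random unknown
cells (one 1→0 flip paired with one 0→1), perturbing the signal while
preserving density. The functional-similarity matrix is the cosine
similarity of the miRNA factors plus symmetric Gaussian noise (`fs_noise`),
clipped to [0, 1]; disease groups become subtrees of a synthetic MeSH-like
hierarchy (shared prefix chain of depth `dag_depth − 1`, unique leaf per
disease), and a `mesh_missing` fraction of diseases (default 10%) is
omitted from the table to exercise the kernel fallback.

The `small` preset (200 × 100, rank 10, density 0.05, noise 0.02) is the
package's standard benchmark: large enough that fivefold CV is meaningful,
small enough that the whole harness runs in seconds. `medium` approximates
the scale and ~2.9% density of a curated human catalogue. What the
generator does *not* emulate: the heavy-tailed degree distribution of real
association databases, correlated annotation biases, partial overlap
between the similarity sources, or disease terms appearing in several
distant MeSH branches. Passing the recovery tests therefore demonstrates
correctness of the machinery and the value of informative similarity
graphs, not expected performance on any real database — on real exports
the achievable AUC is set by data quality and must be measured, not
assumed.

## Known limitations

* Unknown pairs are weak negatives; there is no unobserved-entry masking
  or negative-sampling scheme, and no confidence weighting of positives.
* Multiplicative updates converge linearly and can stall near zero
  entries; for very large matrices an alternating least-squares variant
  would be faster, and none is provided.
* The similarity integration is a hard piecewise choice, not a weighted
  blend; entities missing from both curated sources rely entirely on the
  kernel, which is uninformative for a fully cold entity (all-zero
  profile).
* Per-disease AUC spread in CV_d is reported but no significance testing
  across models is attempted.
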