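# Methods

## Model

`wlmgs` treats gene subset selection as a graph-quality problem. For a
candidate subset *gs* of genes, the samples are embedded in the
corresponding subspace and joined into the **weighted sample graph**
(WSG): an undirected edge connects samples *i* and *j* whenever
*i ∈ kNN(j)* or *j ∈ kNN(i)* (the union rule), weighted
`A(i,j) = exp(−d(i,j))` with `d` the Euclidean distance in the subspace.
The class labels are taken as fixed communities — no community detection
is ever performed — and the subset is scored by how well the graph's
weight concentrates inside classes.

Three quality functions are implemented. With per-class aggregates
`w_k` (internal edge weight), `w_k_out` (boundary edge weight, counted
once per adjacent class), `W_k = w_k + w_k_out`, node strength sum
`s_k = 2·w_k + w_k_out`, and unweighted analogues `m_k, M_k, d_k`:

* `LM  = Σ_k [ m_k/M_k − (d_k/(2·M_k))² ]`
* `WLM = Σ_k [ w_k/W_k − (s_k/(2·W_k))² ]`
* `WLM^s = Σ_k w_k/W_k`  (the selection objective; each term ∈ [0,1], so
  `WLM^s ∈ [0, C]`, reaching `C` exactly when no between-class edge
  exists)

`M_k`/`W_k` count the internal and boundary edges of class *k* only, not
the internal edges of neighbouring communities; this keeps `LM`/`WLM`
structurally consistent with the explicit `W_k = w_k + w_k_out` of
`WLM^s`. Classes with `W_k = 0` contribute 0, so a degenerate fold with a
singleton class cannot produce NaN. `LM` and `WLM` are diagnostics only;
selection always optimizes `WLM^s`.

Because edge weights are `exp(−d)` with the raw (un-rescaled) distance,
weights shrink as genes accumulate and score increments naturally taper —
this is what makes the increment threshold a usable stopping rule. A
distance-normalized variant (dividing `d` by √|gs|) is available via
`build_wsg(..., distance_normalize=True)` but is not the default.

## Selection algorithm

Sequential forward greedy search:

1. Score every candidate gene alone; take the argmax (ties → smallest
   gene index).
2. Repeatedly evaluate every remaining candidate appended to the current
   subset, reusing the additive squared-distance state so each candidate
   costs `O(m²)` (a full sweep is `O(λ·n·m²)`); take the argmax.
3. Stop when (a) the best candidate's increment is `< θ` — that
   candidate is **rejected**, so the reported subset never ends on an
   uninformative gene; (b) the subset reaches `λ` genes; or (c) the pool
   is exhausted.

Negative increments are legal (the greedy argmax is unconstrained) and
trip the θ-rule for any `θ ≥ 0`. A `cap-only` mode disables the θ-rule
for fixed-length runs, e.g. accuracy-vs-size curves. The θ-rule is
applied online; an alternative reading adds the sub-threshold gene
before stopping, which this package deliberately does not do.

The argmax uses exact floating-point comparison with index tie-break —
no tolerance — so results are bit-reproducible for a fixed platform and
input order.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `k` | neighbours per sample in the WSG | 7 | useful range ≈ 5–11 for tens of samples; clamped to `m−1` with a warning |
| `λ` (`lambda_max`) | hard cap on subset size | 15 | selection usually stops earlier via θ |
| `θ` (`theta`) | minimum `WLM^s` increment to continue | 0.02 | on the score's scale (magnitude ≤ C) |
| SVM `C` | soft-margin penalty | 100 | RBF kernel, bandwidth `1/(n_genes·var)`, one-vs-one multiclass |
| CV folds | stratified folds | 10 | falls back to unstratified shuffled folds when a class is smaller than the fold count |

## Normalization and the evaluation protocol

Every gene is z-scored to mean 0, sample SD 1 (`m−1` denominator);
constant genes become all-zero and are reported rather than erroring.
Inside cross-validation the scaler is fitted on the training fold only
and applied to held-out samples with training statistics, so neither
normalization nor selection can leak test information (an explicit
perturbation test asserts this). A `global_normalize` escape hatch
z-scores once on the whole matrix for comparability experiments.

Per fold, selection runs on the training portion and 1NN / SVM accuracy
is measured on the held-out portion using only the selected genes. Genes
are then ranked by selection frequency across folds (ties by mean
selection rank, then index); the consensus subset keeps the top genes,
as many as the most common fold-subset size. Both the mean fold-subset
size and the consensus size are reported, since either can serve as "the"
subset size. Repeats rerun the whole split with shifted seeds and
accumulate folds.

## Synthetic data

The generator emulates class-structured continuous expression data at
the target scale (tens of samples, 10²–10⁴ genes, 2–5 classes):
informative genes are `N(class mean, 1)` with class centroids placed on
a simplex (equidistant, so no class pair is favoured) and scaled so each
informative gene carries an `effect_size` class-mean shift in
within-class-SD units; noise genes are class-independent `N(0,1)`;
redundant genes are informative copies plus `N(0, 0.1)` jitter (near-
duplicates without exact ties); optional outlier rows are `N(0,5)` with
true labels retained; optional within-class sub-clusters add zero-mean
shifts to exercise local cluster structure. Everything is reproducible
from a single seed.

What it does **not** model: intensity-dependent variance, batch effects,
heavy-tailed noise, gene–gene correlation beyond the redundant copies.
Passing tests therefore demonstrate correctness of the machinery and the
score's behaviour under idealized Gaussian class structure, not
performance on real microarray noise.

## Numerical choices and degenerate inputs

* Squared distances are maintained incrementally (additivity of squared
  L2); incremental states are immutable and verified against from-scratch
  recomputation to 1e−10.
* k-NN ties break by ascending sample index; 1NN prediction ties break
  by smallest training index.
* Self-loops are excluded from the WSG: `exp(0)=1` self-weights would
  inflate every `w_k` identically while adding no class information.
* Empty candidate pools, single-class training folds, constant genes and
  singleton classes all have defined non-crashing behaviour (errors,
  warnings or zero contributions as documented in the API).

## Problem sizes used in the checks

The test-suite and the reproduction script work at desk scale: 50 random
graphs (≤ 15 nodes) for the oracle equivalences, 20 simulated datasets of
60 samples × 100 genes for recovery and stopping behaviour, 200
single-gene subsets of a 60 × 200 dataset for the score-vs-k-means
direction check, and 10-fold CV on 60 × 100. The k-means direction check
uses a dataset in which per-gene informativeness actually varies (60
informative, 140 noise, effect 1.5): on a mostly-noise dataset both
`WLM^s` and the objective are flat across most genes and a rank
correlation is uninformative.

## Known limitations

* With two classes the score ceiling is `C = 2` and the first selected
  gene often realizes ~75% of it, so only a few increments can exceed
  θ = 0.02 before saturation; on strongly separable data the search
  legitimately stops at 3–5 genes even when more informative genes
  exist. Near saturation the best-candidate increment is a maximum over
  many noise genes and an occasional noise gene can win a step.
* Very small classes (fewer than `k+1` members) necessarily have
  boundary-crossing neighbourhoods, which weakens their `WLM^s` term and
  with it recovery on heavily imbalanced data.
* Exact k-NN is used throughout; approximate neighbour graphs for large
  `m` are out of scope.
* Cross-platform floating-point drift can, in principle, flip exact-tie
  argmax decisions; determinism is guaranteed per platform.
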