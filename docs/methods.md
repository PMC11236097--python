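# Methods

## Problem and model

`sfngrn` infers directed transcription-factor (TF) → target-gene
relationships from single-cell (and optionally spatially resolved)
transcriptomics by casting network inference as supervised binary
classification of gene pairs. Given a cells × genes expression matrix
X ∈ ℝ^{c×g}, a candidate pair (a, b) is represented by the (c × 2) block of
the two genes' expression across all cells. A classifier scores the pair;
ground-truth edge lists (e.g. ChIP-seq-derived TF→target sets or
ligand–receptor catalogues) supply the training labels.

Two tasks share the machinery:

* **interaction** — is (a, b) a real regulatory pair? Negatives are
  TF–non-target pairs sampled uniformly without replacement, one per
  positive, so classes are balanced 1:1 per TF.
* **causality** — which direction? Each true edge (a, x₁) labelled 1 is
  mirrored by (x₁, a) labelled 0, so the classifier must exploit the
  asymmetry of the input block, not co-expression alone.

## Cell graph: shared factor neighborhood (SFN)

1. PCA on X, keeping the smallest number of components whose cumulative
   explained variance reaches `variance_target` (default **0.90**). Scores
   are column-centred; each factor's sign is fixed so its largest-magnitude
   loading is positive, making runs backend-independent.
2. For every cell, its **K = 10** nearest neighbours in the factor space
   (Euclidean, self excluded, distance ties broken toward the lower cell
   index).
3. Each cell's *dominant factor* is the argmax of its signed factor scores
   (first index on ties; an |score| variant is available behind
   `dominant_on_abs`). The histogram FN(i) counts the dominant factors of
   cell i's K neighbours; rows always sum to K.
4. Pairwise Manhattan distances between histograms are mapped through
   S = 1/(1+E), and an edge is admitted when S **strictly** exceeds the
   threshold (default **0.5**, i.e. E < 1).

Histograms are divided by K before the distance (default
`normalize_by_k=True`). With raw integer counts every non-identical
histogram pair has E ≥ 1, so threshold 0.5 would only connect cells with
*identical* histograms and the graph would collapse into dominant-pattern
cliques; normalising puts E in [0, 2] and makes the printed default
threshold meaningful. The raw-count behaviour remains available for
fidelity experiments.

For spatial data, Euclidean distances between cell positions are divided by
the median nearest-neighbour spacing (`scale="median_knn"`) before the same
similarity transform — raw micrometre-scale units would otherwise drive
1/(1+d) ≈ 0 everywhere. The expression graph and the spatial graph are
fused by an elementwise logical OR, which can only add edges.

Alternative cell-graph strategies (Pearson-correlation, Euclidean,
Manhattan, cosine distances on the PCA embedding) are provided for the
graph-strategy ablation only.

## Classifier

Per pair, X⁰ is the (c × 2) block (column 0 regulator, column 1 target —
swapping columns is the causality-reversed input). Two branches:

* **NN branch**: two dense ReLU layers of 32 units applied per cell row,
  giving θ₂ ∈ ℝ^{c×32}. The network is deliberately shallow: training sets
  are small (hundreds of pairs) and deeper nets overfit.
* **GCN branch**: two graph-convolution layers
  X^{(l+1)} = ELU(N X^{(l)} W^{(l)} + b^{(l)}), giving θ₁ ∈ ℝ^{c×32}.
  N is the symmetric Kipf normalisation D̂^{-1/2}(A+I)D̂^{-1/2} of the
  self-loop-augmented adjacency: it is symmetric, has spectral radius ≤ 1,
  and keeps degrees positive for isolated cells (an edgeless graph reduces
  the branch to a per-cell dense network). The one-sided form
  D^{-1/2}AD^{1/2} without self-loops is retained behind
  `compat_literal_normalizer` for comparison; it is not symmetric and
  zero-degree cells annihilate, so it is never the default.

θ₁ and θ₂ are concatenated along the feature axis, flattened into one
vector of length c·64 and passed through a single dense unit with a sigmoid.
Because of the flatten, a trained model is tied to the cell set (and order)
of its training graph; `predict` enforces this. With
`use_nn_branch=False` the θ₂ block is dropped entirely (strictly fewer
parameters; the NN weights are never created), which is the
integrative-network ablation.

Training minimises binary cross-entropy (the public `bce_loss` uses the sum
convention over the T pairs with predictions clipped to [1e-7, 1−1e-7];
optimisation uses the per-batch mean). Optimiser: Adam, learning rate 1e-3,
batch size 32, Glorot-uniform initialisation, up to 100 epochs with early
stopping (patience 10) on a 10 % held-out slice of the training pairs
(split by pair, within the training TFs) and restoration of the best
weights. The forward and backward passes are explicit NumPy in float64 —
small, CPU-friendly, bit-reproducible under a fixed seed, and validated by
central finite-difference gradient checks at 1e-5 relative tolerance.

## Cross-validation and evaluation

TFs — not pairs — are shuffled and dealt round-robin into 3 folds, so fold
TF sets are disjoint and cover all TFs; every pair travels with its anchor
TF (`tf_group`), including each causality mirror pair, whose `tf_group` is
the original regulator. An assertion that the train/test TF sets are
disjoint runs on every fold of every cross-validation.

AUROC is the tie-corrected Mann–Whitney statistic and AUPRC the step-wise
precision–recall integral (no interpolation), computed per TF and
summarised by the median (and mean) across TFs; pooled scores over all test
pairs are also reported. TFs whose test pairs are single-class are excluded
from per-TF summaries with a logged count.

The null control permutes labels *within* each TF group, preserving the
per-TF 1:1 balance while destroying the pair–label association; its median
AUROC should sit near 0.5.

Harnesses: `downsample_run` resamples cells without replacement at given
fractions (indices sorted, so fraction 1.0 reproduces the full run
bit-exactly) and rebuilds the whole pipeline per subset; `ablation_run`
toggles exactly one component per variant (dense branch off, spatial fusion
off); `rank_candidates` scores all TF × gene pairs for TFs disjoint from
the training TFs (enforced — the leakage guard) and returns overall and
per-TF rankings.

## Synthetic data generator

The generator emulates the structure the method assumes, at desk scale:

* cells assigned uniformly to `n_clusters` = 3 populations;
* per cluster and gene, baseline log-means ~ N(1.0, 0.5) — Poisson means
  roughly 1–20, the sparse-counts regime of real single-cell data;
* TF log-expression = baseline + N(0, `noise_sd`);
  target log-expression = baseline + β·(TF log-expression) + N(0,
  `noise_sd`), with `noise_sd` = 0.5 and effect size β = 1.5 as the default
  study condition; each target depends on exactly one TF, keeping the
  planted signal identifiable at small n;
* counts = Poisson(exp(log-expression)) with Bernoulli dropout
  (default rate 0.1) emulating technical zero-inflation;
* in spatial mode, cluster centres lie uniformly on the unit square and
  cells scatter around their centre with sd 0.08, so expression clusters
  and spatial neighbourhoods coincide — the regime where OR-fusion is
  informative.

Named bundles (`tiny`: 20 cells; `small`: 200 cells, 60 genes, 6 TFs × 5
targets; `small-spatial`: same plus coordinates) are generated under fixed
seeds and are bit-reproducible.

What the generator does **not** emulate: negative-binomial over-dispersion
(Poisson is sufficient to exercise every code path), batch effects,
trajectories, combinatorial regulation, and realistic library-size
variation. Passing tests on these simulations therefore demonstrate
correctness of the machinery and recoverability of a planted monotone
TF→target dependency — not performance on real tissue atlases.

Because β > 0 both couples and inflates target expression, direction is
easy to detect in simulation (causality AUROC near 1); the causality task
is judged against its shuffled control rather than an absolute bar.

## Numerical and design choices

* Raw simulated counts are normalised by median-library-size scaling +
  log1p before graph building and classification; file readers leave
  pre-processed single-cell inputs untouched by default (`mode="none"`).
  The normalisation applied is recorded in run metadata.
* Gene matching is case-insensitive with case preserved on output (mouse
  vs human symbol conventions).
* Negative sampling excludes a TF's true targets and itself but not other
  TFs.
* Reciprocal edges (a→b and b→a) are dropped from causality truth — the
  mirror construction would label them inconsistently.
* All randomness flows from a master seed through named per-stage
  substreams (graph, negatives, folds, init, shuffle), so changing one
  stage's stochasticity never perturbs the others.
* Degenerate inputs: constant expression matrices are rejected by PCA;
  duplicate coordinates yield similarity-1 edges; zero-edge graphs warn but
  proceed (the GCN then acts per cell); zero-count cells make
  library-size normalisation fail loudly with the offending cell ids.
* Reduced problem sizes in the test and acceptance harnesses (100–200
  cells, 30–100 epochs) were chosen so the planted signal is comfortably
  recoverable while keeping each cross-validation in the seconds-to-minutes
  range; these sizes are recorded alongside every reported number.

## Known limitations

* The flatten head ties a trained model to its training cell set; applying
  a model to a new dataset requires retraining (per-fold models are always
  retrained inside cross-validation).
* Dense (c × c) adjacency and per-pair (c × 2) blocks keep the
  implementation simple but scale quadratically in cells; the method is
  intended for datasets up to a few thousand cells.
* Per-TF AUROC on 10 test pairs (the desk-scale fixture) is a coarse
  statistic; medians across TFs are the stable summary.
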