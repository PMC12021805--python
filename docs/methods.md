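# Methods

`r2snet` implements a three-part analysis for differential diagnosis of
parkinsonian syndromes (idiopathic Parkinson's disease, IPD; multiple
system atrophy, MSA; progressive supranuclear palsy, PSP) from regional
radiomic feature tables: (1) construction of per-subject metabolic
similarity networks, (2) a graph-transformer classifier, and (3)
gradient/attention attribution of its decisions to brain regions and
connections.  Because no public cohort of regional radiomic tables for
these diseases exists, the package ships a synthetic-cohort generator
with planted, exported ground truth; everything below is testable
end-to-end against that ground truth.

## 1. Regional radiomics similarity networks (R2SN)

Input: one table per subject of radiomic feature values over a fixed
96-region parcellation (80 bilateral AAL cortical labels + 16 PD25
subcortical labels; the ordering is bundled with the package and shared
by all artifacts).

1. **Collinearity pruning.**  Pairwise Pearson correlation of features is
   computed over all pooled (subject, region) observations of the
   *training* cohort.  Features are scanned in catalogue order; a feature
   is dropped iff |r| > 0.9 against an earlier retained feature.  The
   greedy order-stable scan makes the selection reproducible; the
   selection is frozen and applied unchanged to validation/test data.
   Zero-variance features are dropped outright and flagged.
2. **Per-subject min-max normalisation.**  Each retained feature is
   rescaled to [0, 1] across the 96 regions *within* the subject.  A
   constant column maps to 0 (flagged with a warning) rather than NaN.
3. **Network construction.**  r_ij is the Pearson correlation between
   region i's and region j's normalised feature profiles; the edge
   weight is the affine map w_ij = (r_ij + 1)/2 in [0, 1].  Among the
   candidate "standard transformed correlation" readings ((r+1)/2, |r|,
   Fisher-z rescaling) the affine map was chosen because it is monotone,
   subject-independent and keeps anti-correlation distinguishable from
   decorrelation; |r| is available via `build_r2sn(..., transform="abs")`.
   The diagonal is fixed at 1 so that the attention Hadamard mask never
   silences a node's self-attention.  A zero-variance region receives
   r = 0 (w = 0.5) against all others, with a warning.

## 2. Graph-transformer classifier

The model operates on G = (V, E, X, W): 96 nodes with d = 36 feature
vectors x_i and the symmetric edge-weight matrix W.  Three identical
layers are stacked; each layer computes, in order:

* **Gated structure fusion.**  A learnable structure token s in R^36 is
  blended into every node: g_i = sigmoid(W_g [x_i || s]),
  x~_i = g_i * x_i + (1 - g_i) * s, with W_g in R^{72x36}.  When a layer
  is mask-restricted, fusion applies only to nodes incident to at least
  one retained edge (in practice all nodes unless a node is isolated).
* **Adjacency-Hadamard multi-head attention** (4 heads,
  W_Q, W_K in R^{36x24}, W_V in R^{36x32} per head):
  alpha^h = softmax(Q^h K^h^T / sqrt(24)) with masked entries at -inf,
  then alpha~^h = alpha^h ⊙ W.  The Hadamard product deliberately
  attenuates attention by connectivity strength and is *not*
  renormalised (a config flag can renormalise rows; off by default).
  The four 32-dim head outputs are concatenated (128) and projected back
  to 36 dims by an output matrix W_O in R^{128x36}.  W_O is a necessary
  reconciliation: without it the printed per-head value dimension (32)
  cannot re-enter the 36-dim residual stream.
* **Position-wise FFN** W_2 GELU(W_1 x + b_1) + b_2 with
  W_1 in R^{36->144}, W_2 in R^{144->36}.  GELU is the exact
  Gaussian-CDF form (x Phi(x)), not the tanh approximation, so that
  numerical oracles are bit-stable.
* **Single post-LayerNorm** over the three-term sum,
  X^{l+1} = LayerNorm(X~ + Attention(X~) + FFN(X~)).  Standard
  transformers interleave two pre-norms; the single post-norm follows
  the model's defining layer-update equation.  The residual stream is
  the *fused* features X~, i.e. fusion is treated as producing the
  layer's working representation.

**Masking schedule.**  Layer 1 attends globally; layers 2–3 are
restricted to a TopK-sparsified subgraph (per node the k = 8
strongest-weight neighbours, ties to the lower index, mask symmetrised
by union, diagonal always kept).  This realises the global-then-local
attention design; the schedule is configurable (`attention_masking`:
"hybrid" | "global" | "topk").

**Readout and head.**  h_pool^l = element-wise max over the 96 nodes of
layer l's output; h_concat = h_pool^1 || h_pool^2 || h_pool^3 (108-dim);
the class head is Linear(108->128) -> GELU -> Linear(128->64) -> GELU ->
Linear(64->3) -> softmax, with LayerNorm and dropout (p = 0.3, off at
inference) before each linear map.

**Why numpy + hand-written reverse-mode autodiff.**  The model's
gradients are needed twice over — for training and for gradient-based
node attribution — and the arithmetic is small (96 nodes, 36 dims), so
the package implements its own compact tape-based autodiff
(`r2snet/_autodiff.py`, ~15 primitives, float64).  The hot attention
path (softmax -> dropout -> Hadamard -> matmul) is a single fused node
with a hand-derived backward.  Correctness is enforced by a
central-difference gradient check over every parameter group and the
input features (relative error <= 1e-4 on a 6-node toy).

## 3. Training protocol

Composite objective

    L = CE(y, p) + 1e-4 ||theta||_2^2 + 0.2 L_SupCon,

where L_SupCon is the canonical supervised contrastive loss at
temperature tau = 0.07 over unit-norm embeddings z_i produced by a
2-layer projection head (108 -> 64 -> 32, discarded at inference);
anchors without a same-class positive are skipped.  Optimisation: Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-8), batch size 32 with
class-stratified batch composition, global gradient-norm clipping at
3.0, linear warmup of the learning rate from 0 to 5e-4 over 5 epochs
followed by cosine decay to 1e-6 at epoch 200.  Stochastic
regularisation: 15% whole-row node-feature dropout (with 1/(1-p)
rescaling), 10% attention dropout inside each head, 40% dropout before
each head linear, and Gaussian noise (sigma = 0.05) on a random 10% of
off-diagonal edge pairs, clipped back to [0, 1] and re-symmetrised.
TopK masks are computed once per graph from the clean weights — the
mask encodes the graph's structure, while edge noise perturbs only the
Hadamard weights.

**Early stopping** monitors the *validation cross-entropy* with patience
10 and restores the best weights.  Three small-cohort safeguards shape
the monitor: (1) the monitored quantity is the classification loss
rather than the full composite — the L2 term is data-independent and
the contrastive term is a training-batch construct, and on small
validation splits the slowly-moving contrastive term masks genuine
classification progress; (2) monitoring starts only after the learning-
rate warmup completes — while lr ≈ 0 the model cannot improve, and a
lucky validation draw from a still-at-chance model would otherwise
become the benchmark that patience counts against (the same guard as
Keras EarlyStopping's `start_from_epoch`); (3) patience counts against
an exponentially smoothed series (weight 0.3 on the newest value),
because a ~20-subject validation split wobbles per epoch by more than
the true loss moves.  Best-weight snapshots always track the raw
minimum.  The validation split is a stratified 15% of the training
cohort, seed-controlled.  Warmup/decay "epochs" are interpreted
literally as epochs (not optimizer steps); both readings exist, and the
config exposes the epoch counts directly.

**Two-stage mode.**  `pretrain_finetune` first trains from scratch on a
pre-training cohort (emulating the clinically *possible* cases), then
continues from those weights on the definite-diagnosis cohort with a
fresh schedule.  An empty pre-training cohort degrades to plain
training.

## 4. Explainability

* **Node importance** I_node(i) = || d log p(y|G) / d x_i ||_2, the L2
  norm of the input-feature gradient of the target class log
  probability (target = predicted class by default; the true class is
  selectable).
* **Edge importance** averages the pre-Hadamard attention maps over
  heads and over the three layers, then symmetrises as (M + M^T)/2 —
  attention is directed while R2SN edges are not.
* **Edge retention** keeps the top 15% of the 4560 undirected
  off-diagonal pairs — exactly ceil(0.15 x 4560) = 684 edges — with
  lexicographic tie-breaking for reproducibility.
* **Group contrasts** use Jaccard similarity |A∩B| / |A∪B| between
  retained edge sets; two empty sets count as identical (J = 1).

## 5. Synthetic cohorts with planted ground truth

Each subject's 96 x 40 table is drawn from a latent-factor model:

    value(i, k) = scale_k * [ profile_ik + lambda_i . P_k
                              + delta_i 1[k in affected block]
                              + pair terms + noise_ik ] + offset_k

* `profile` — a *stable per-region fingerprint* (sd 1.0), identical
  across subjects.  Real regional radiomic profiles are dominated by
  anatomy; the fingerprint is also what allows a permutation-invariant
  graph model to recognise a region from its features at all.  Without
  it, region identity would exist only in row order, which the model
  never sees.
* `lambda_i . P_k` — shared latent factors (6) with region loadings
  built around a common direction (base correlation 0.6), giving every
  pair of regions correlated feature profiles — the raw material of the
  similarity network.
* **Node effects** — designated hypometabolic (delta = -2.5) or
  hypermetabolic (+2.5) regions receive the mean shift on a 12-feature
  "intensity-like" block (of 36 non-duplicate features).  The magnitude
  and block width were calibrated once so that the planted class effects
  put the classifier in the performance regime the method reports on
  real patients (per-class F1 in the high 80s to mid 90s) — weaker
  settings produce cohorts in which no variant of the model family
  generalises, which would not emulate the study's conditions.  In FDG
  radiomics terms the planted patterns are "marked"/"widespread"
  hypometabolism: both intensity and texture features track uptake.
* **Edge effects** — a disrupted pair (i, j) receives an anti-correlated
  pair-specific component (+kappa q to i, -kappa q to j, q fresh per
  subject, kappa = 0.9 x (1 - rho_factor)), lowering that pair's profile
  correlation; enhanced pairs receive the component with equal signs.
* **Planted redundancy** — 4 of the 40 columns are exact affine copies
  of earlier columns, so collinearity pruning has known targets
  (40 -> 36 retained).
* **Presets** — three stylised disease signatures named for the classes:
  IPD-like (putaminal/pallidal hypometabolism, posterior
  cingulate/precuneus hypermetabolism, basal-ganglia-thalamic edge
  disruption), MSA-like (posterior/occipital and thalamic stand-ins with
  motor-area hypermetabolism — the cerebellum and pons are not in the
  96-label atlas), PSP-like (red nucleus/subthalamic/dorsolateral
  prefrontal with midbrain-prefrontal disconnection).  A null preset
  (no effects) yields exchangeable classes for negative controls.

**What the generator does not emulate:** realistic marginal
distributions of individual radiomic features, scanner/site effects,
age/sex covariates, class imbalance, or any spatial smoothness between
neighbouring regions.  Passing recovery tests therefore demonstrates
that the pipeline recovers *this kind* of planted signal, not clinical
performance.

## 6. Problem sizes and numerical choices

Default experiment sizes (used by the acceptance script and the heavier
tests): cohorts of 50 subjects/class for training plus 15/class held
out, 5 seeds for multi-seed aggregation, 20 attribution runs for
explainer recovery, 30-subject cohorts for the capacity check.  These
sizes keep full pipeline runs in the minutes range on a single CPU
while leaving the statistical checks well-powered.

* All arithmetic is float64.
* Degenerate inputs (constant features, zero-variance regions, empty
  edge sets) are defined to produce finite flagged values, never NaN.
* Ties (TopK neighbours, retained edges, ROI ranking, max-pool argmax)
  break deterministically toward the lower index / lexicographic order.
* Pearson correlations use the n-convention (the n vs n-1 factor
  cancels).
* Checkpoints store every parameter tensor plus the model config and
  seed; loading restores bit-identical parameters.

## 7. Known limitations

* The printed per-head shapes require an output projection (W_O) that
  the defining equations do not name; it is declared plumbing.
* Whether W_Q/W_K are shared across heads, and which layers the TopK
  mask applies to, are open readings; both are config-exposed
  (per-head projections and the hybrid schedule are the defaults).
* With cohorts an order of magnitude smaller than the clinical study,
  early stopping on a small validation split is noisy; runs can
  truncate while validation loss is still falling.
* The synthetic task is easier than the clinical one in structure even
  when calibrated to a comparable accuracy regime; absolute metric
  values on synthetic cohorts are not clinical claims.
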