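# Methods

## Problem and model

The package predicts unobserved drug–microbe associations from a binary
association matrix `B` (N_d drugs × N_m microbes), a drug–drug similarity
matrix `K_drug` and a microbe–microbe similarity matrix `K_micr` (or a
microbe attribute matrix from which cosine similarities are computed as
`K_ij = (cos(x_i, x_j) + 1)/2`). Drugs and microbes form one heterogeneous
graph: within-type edges carry similarity values at or above a threshold
`beta` (kept as weights, not binarized — a `binarize_adjacency` switch
provides the 0/1 alternative), cross-type edges carry the known
associations. Because similarity diagonals are 1, every node has a
self-loop, so degrees are always positive and neighbor sets never empty.
Drugs occupy indices `0..N_d-1`; microbe `j` is global node `N_d + j`.

Four raw feature families describe each node:

* **similarity** — block-diagonal of the two unthresholded similarity
  matrices (thresholding applies only to graph edges, following the
  construction's notation literally);
* **multi-modal** — similarities plus the association profile,
  `[[K_drug, B], [B^T, K_micr]]`;
* **position** — the node's row of the weighted heterogeneous adjacency;
* **multi-scale topology** — return probabilities of 1..t step random
  walks on the column-normalized adjacency `A D^{-1}` (`D` = diagonal of
  column sums). With symmetric `A` the diagonal of `(A D^{-1})^s` equals
  that of `(D^{-1} A)^s`, so the normalization convention is unobservable
  in the features actually used.

The trainable network has four stages:

1. **Embedding enhancement (ES).** Node-type-specific autoencoders
   (encoder widths `in → 2·N_p → N_p`, mirrored decoder, ReLU throughout)
   compress the similarity and multi-modal rows; a linear classifier on
   each bottleneck predicts the node type through a log-softmax (the
   affine output alone is not a probability, so the cross-entropy is taken
   after softmax normalization). Losses: per-family mean squared
   reconstruction error and cross-entropy, summed into `gamma_proc`.
   Position/topology features stay raw. With `disable_es` the stage
   collapses to a single per-type linear projection with zero ES loss.
2. **Neighbor feature fusion (NFF).** A stack of heterogeneous
   graph-attention layers updates similarity, position and topology
   channels in parallel. Per target i and neighbor j: a semantic score
   `s = softmax(W_p W_φ(i) h_i) · L2norm(W_φ(j) h_j)` (softmax over the
   feature dimension, so |s| ≤ 1; a zero key vector scores 0), a
   structural importance `c = [τ·cos(posi) + (1−τ)·cos(topo) + 1]/2`
   (zero-norm vectors contribute cosine 0), and a learned scalar `r` per
   relation type (drug←drug, microbe←drug, drug←microbe,
   microbe←microbe; initialized to 1, one scalar per relation per layer,
   shared across heads and channels). Attention is the softmax of
   `r·s·c` over the neighbor set; each head aggregates with the target
   type's transform plus a per-head residual, heads are averaged, ReLU
   applied. Channels compute their own `s` but share `c` and `r`; a
   `share_channel_attention` switch instead reuses the similarity
   channel's attention everywhere.
3. **Graph feature fusion (GFF).** A relation-aware transformer with
   dense attention over all node pairs on the enhanced multi-modal
   embedding. Queries/keys/values project the node representation
   concatenated with a learned 4-row relation-type embedding (one table,
   shared across layers); projection weights are per node type and head.
   Since the relation type depends only on the (target type, source type)
   pair, projections are computed blockwise (4 type combinations) rather
   than per pair. Scaled dot-product attention, head concatenation, then
   `LayerNorm(W1 m + h)` and `LayerNorm(ReLU(W2 n) W3 + n)` with
   per-row normalization (ε = 1e-5) and learned affine rescale.
4. **Pair head.** Each node's final vector concatenates its original
   similarity row, all NFF layer outputs (layer 0 included), its original
   multi-modal row and all GFF layer outputs. A pair is scored by
   ReLU-affine on the concatenated (drug, microbe) vector followed by an
   affine map to two logits and a softmax. The pair affine is evaluated in
   split form (`h_d W_top + h_m W_bot`), algebraically identical to the
   concatenated product. Total loss:
   `gamma = ε·gamma_proc + (1−ε)·gamma_pred` with `gamma_pred` the mean
   two-class cross-entropy over training pairs.

Everything trains jointly (one computation graph, no pre-training) with
Adam at learning rate 1e-3, full batch over the sampled training pairs.
The engine is a compact reverse-mode automatic-differentiation tape over
dense float64 numpy arrays (`ngmda.autodiff`), entirely adequate at the
graph sizes this package targets; weights use seeded Glorot-uniform
initialization.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `beta` | 0.9 | similarity threshold for within-type edges (inclusive) |
| `walk_steps` | 2 | random-walk steps t (topology feature width) |
| `tau` | 0.4 | position-vs-topology weight in the structural importance |
| `epsilon` | 0.2 | ES-vs-prediction loss balance |
| `nff_layers`, `gff_layers` | 2, 2 | attention stack depths |
| `nff_heads`, `gff_heads` | 4, 4 | attention heads (head count is an engineering choice) |
| `embed_dim` | 64 | bottleneck/attention width N_p |
| `head_dim` | 64 | pair-head hidden width |
| `lr`, `epochs` | 1e-3, 80 | Adam schedule, full-batch |

`beta`, `walk_steps`, layer counts, `tau` and `epsilon` follow the
method's published operating point. Width and schedule are desk-scale
choices: on the synthetic fixture, quality is indistinguishable between
`embed_dim` 64 and 128 and between 80 and 120+ epochs, while the smaller
setting halves runtime; both remain configurable. Ablation switches
(`disable_es/nff/gff/topo/posi/rel`) reproduce the structural ablations:
`disable_topo` forces τ=1, `disable_posi` τ=0, `disable_rel` pins r≡1,
`disable_nff`/`disable_gff` bypass the module so the corresponding
channel passes through unchanged.

## Evaluation protocol

Known associations are shuffled and split into five near-equal folds.
Per fold, training uses the fold's positives plus an equal number of
negatives sampled uniformly without replacement from the unobserved
pairs; **all** remaining unobserved pairs are test negatives, preserving
the extreme class imbalance of a real screen. Test positives are masked
out of the training graph (adjacency, multi-modal, position and topology
features) to prevent label leakage; whether the original study masked
them is not stated, so its printed real-data numbers are not directly
comparable. Metrics are per drug over that drug's held-out candidates
only — AUC with mean-rank tie handling, step-wise average precision,
top-k recall with deterministic (−score, index) tie-breaking — averaged
over drugs with at least one test positive (the skipped count is
reported), and fold means are averaged into the final figure. The paired
Wilcoxon signed-rank comparison of two per-drug metric vectors drops zero
differences, uses an exact null distribution (dynamic-programming
convolution over doubled mean ranks) for n ≤ 25 and a normal
approximation with continuity correction above; all-zero differences
give the degenerate p = 1.

## Synthetic data

The generator encodes the method's working premise — similar drugs
interact with similar microbes — as planted low-rank structure. Every
drug and microbe receives a non-negative loading vector: a *direction*
(one dominant factor of weight ~1 plus 0.2·uniform background across
`latent_rank` factors) times a lognormal(0, 1.5) *activity* magnitude.
Association probabilities are proportional to loading inner products,
calibrated by bisection (cap 0.98) so the expected density equals
`assoc_density`, and drawn independently. The activity term mimics the
hub structure of curated microbe–drug databases (a few broad-spectrum
drugs and well-studied microbes carry most associations) and is what
makes held-out pairs rankable: the Bayes-optimal per-drug AUC of ranking
by the true probabilities is ≈0.9 under the default fixture. Drug
similarities are the [0,1]-rescaled cosines of the directions (activity
cancels in the cosine) plus truncated symmetric Gaussian noise; microbe
attributes are the noisy directions, so the package's own cosine map
reproduces a correlated microbe similarity. `sim_noise = inf` yields the
null dataset — independent Bernoulli associations and structureless
similarities — used for the leakage control.

What the generator does **not** emulate: real marginal distributions of
MDAD-scale data (1373×173), chemical-structure or Gaussian-kernel drug
similarities, sequence-level microbe features, or any correlation
between similarity noise and association noise. Passing tests therefore
demonstrate that the implementation recovers plantable low-rank signal
through the full pipeline without leakage — not that it attains any
particular performance on real curated data.

The default fixture (60 drugs × 30 microbes, rank 4, density 0.08,
noise 0.1, seed 7) keeps a full 5-fold, 3-seed run within a few minutes
on one CPU; these sizes are the package's reference study conditions.

## Numerical choices and degenerate inputs

* Softmax/log-softmax are max-shifted; neighbor softmax uses −inf
  masking and rejects empty neighbor sets (unreachable with self-loops).
* L2 normalization and cosines map zero vectors to zero contributions.
* Non-finite layer outputs or losses abort the fold with a divergence
  error rather than propagating NaNs.
* All randomness derives from one integer seed via
  `numpy.random.SeedSequence([seed, fold_id])`; with a single BLAS
  thread, reruns are bit-identical.
* `AssociationMatrix` requires strictly 0/1 entries and unique
  identifiers; `SimilarityMatrix` enforces symmetry (1e-8), unit
  diagonal and [0,1] range.

## Known limitations

* Dense (N_d+N_m)² attention and feature matrices limit the
  implementation to desk-scale graphs (hundreds of nodes); no sparse
  scatter path is provided.
* The pair head consumes very wide concatenated vectors; with few
  training pairs the network can overfit the classification objective
  while ranking quality plateaus — ranking metrics, not losses, are the
  quantities to monitor.
* Exact Wilcoxon p-values are computed only up to n = 25 non-zero
  differences; beyond that the normal approximation is used.
* Probabilities from the pair head are not calibrated; only their
  ranking is meaningful.
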