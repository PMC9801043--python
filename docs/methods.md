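# Methods

## Model

A gene is an ordered list of polyadenylation sites (PASs), proximal to
distal in transcription order, each represented by a fixed-width DNA
window centered on its cleavage position (stored 5′→3′ on the
transcribed strand, so "upstream" is always to the left). The model
predicts the usage distribution over the gene's sites jointly:

1. **Base network** (parameters shared across all sites of a gene) maps
   one window to a feature vector:
   * `feature_net` — occurrence counts of named regulatory motifs
     (IUPAC patterns restricted to regions around the cleavage site)
     plus 1–4-mer counts, z-scored with training-split statistics, then
     fully connected layers;
   * `single_conv` — one convolution block (1-D convolution → ReLU →
     local max pooling) over the one-hot window, then fully connected
     layers;
   * `multi_conv` — two convolution blocks, then fully connected layers.
2. **Interaction layer** over the ordered site vectors:
   * `bilstm` — a bidirectional LSTM whose time steps are the sites (one
     direction proximal→distal, the other distal→proximal); the two
     hidden states per site are concatenated and a linear head yields a
     scalar logit;
   * `dense_only` — the same per-site head without recurrence (ablation:
     joint normalization but no cross-site communication);
   * `none_pairwise` — raw per-site scores with no softmax, trained by
     pairwise comparison (ablation of the joint treatment altogether).
3. **Joint softmax** (with max subtraction) turns the logits into
   usages summing to one — for any number of sites. Genes are never
   padded; minibatches are bucketed by site count.

Training minimizes the mean per-gene cross entropy −Σ t·ln p (logistic
pairwise loss −ln σ(s_hi − s_lo) over site pairs with usage difference
> 0.05 for `none_pairwise`) with Adam. The assumption doing the work is
that usage is a competition decided by local sequence strength plus
inter-site context; the BiLSTM is what lets a site's predicted usage
depend on its competitors and on its position in the order.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `W` | 455 nt | window width, odd = symmetric 227/1/227 around the cleavage site; an even `W` (e.g. 448) is read as `W/2` bases up to and including the site plus `W/2` downstream. An odd default is used because an even window cannot be centered. |
| `conv1_filters × conv1_width` | 40 × 12 | layer-1 filters; 12 nt comfortably spans the 6-nt signal hexamer plus context |
| `pool_width/stride` | 3/3 | local max pooling; pooling is local, not global, so positional information survives for mutation maps |
| `conv2_filters × conv2_width` | 40 × 10 | layer-2 filters; receptive field (conv2_width−1)·pool_stride + pool_width + conv1_width − 1 = 41 nt |
| `base_out_dim`, `lstm_hidden`, `fc_sizes` | 64, 64, (64,) | kept small; desk-scale data does not support wider layers |
| `dropout_p` | 0.2 | applied to the BiLSTM outputs only |
| `weight_decay` | 1e-3 | L2 on convolution and fully-connected weight matrices; biases and LSTM matrices exempt |
| `lr` | 3e-3 | Adam step size; `fine_tune_lr_divisor=100` gives the transfer-learning rate |
| `patience` | 5 epochs | early stopping on validation MAE ("stop as soon as it does not improve", with a small tolerance for epoch-to-epoch jitter) |
| `val_fraction` | 0.1 | gene-level validation split carved from the training genes, seeded |
| pair threshold / top margin | 0.05 / 0.15 | metric eligibility rules: strictly >5-point pair differences; ≥15-point top-1 margins |

The optimizer defaults (lr 3e-3, weight decay 1e-3) were selected from a
small convergence grid on simulated data: smaller rates left layer-1
convolution filters close to their random initialization (diffuse PFMs)
even when aggregate accuracy looked fine, while the chosen setting
improved usage MAE, pairwise accuracy, and filter interpretability
together.

## Synthetic data: what it emulates, what it does not

The generator draws genes with 2–8 sites. A site's latent strength is

```
s_k = hexamer(window_k) + β·(n−k) + Σ aux(window_k) + ε_k
```

with hexamer strengths AATAAA 1.0 > ATTAAA 0.7 > TTTAAA 0.4 > none 0
(the known affinity ordering; planted with probabilities
0.45/0.25/0.15/0.15 at a uniform offset 15–30 nt upstream of the
cleavage site), proximal positional advantage β = 0.25 per index step, a
UGUA-like upstream enhancer (+0.15 per occurrence, −100..−40) and a
U-rich downstream silencer (−0.15 per occurrence, +10..+80) each planted
with probability 0.3, and Gaussian noise ε with SD 0.15 standing in for
trans effects the sequence cannot explain. True usage is softmax(s);
observed counts are multinomial at depth 2000; background sequence is
uniform ACGT (GC content adjustable); half the genes are written on the
minus strand to exercise strand handling. The sequence-dependent part of
`s` is recomputed from the *realized* window, so edits (allelic
substitutions, saturation mutagenesis) have exact ground-truth effects,
and allele pairs share their noise realization — as in an F1 hybrid,
where both alleles see the same trans environment and usage differences
isolate cis effects.

Passing tests on these data show the machinery works: the architecture
can represent and recover a competitive softmax over sequence-derived
strengths, the metrics implement their definitions, and the
interpretation tools localize the true causal elements. They do not show
real-data performance: real PAS windows have correlated composition,
many interacting elements, measurement artifacts, and inter-site
distances that the generator deliberately omits.

## Numerical choices

* Softmax and log-softmax use max subtraction; cross entropy clamps
  ln at 1e-12.
* The network runs on a reverse-mode autodiff engine over float64 numpy
  arrays (matmul against 2-D weights, elementwise ops, 1-D max pooling,
  slicing/concat, log-softmax), gradient-checked against central finite
  differences; convolution is im2col + matmul.
* Max pooling and PFM accumulation break ties toward the lowest
  position; layer-2 PFM subsequences whose receptive field overhangs the
  window (or contains N) are skipped with that filter's sequence count
  decremented, keeping each PFM's row sums exact.
* One-hot N rows are all-zero (padded flanks contribute nothing to
  convolutions); z-scored features with zero training SD map to 0.
* Metric edge rules: ties in predicted scores count as incorrect in the
  pairwise task (conservative, configurable); per-gene Spearman uses
  average ranks and excludes genes with a constant rank vector; a gene
  whose read counts are all zero is excluded at load time, as are genes
  below a configurable total-read floor (default 10).
* Degenerate inputs: single-PAS genes are kept in the data model (their
  usage is trivially 1.0) but excluded from training and metrics;
  indel-edited reporter windows are re-extracted at fixed width centered
  on the (possibly shifted) cleavage site, with unknown shifted-in bases
  set to N.
* Seeded determinism end to end: fold assignment, initialization,
  shuffling, dropout, and the generator all derive from explicit seeds;
  two runs with the same configuration and seed reproduce each other.

## Problem sizes used by the test suite

The recovery study trains on 400 simulated genes and evaluates on 100
held-out genes at `W = 201` — a window that still contains the full
signal region (−30..−15) and both auxiliary-motif regions; the package's
choice for routine desk-scale experiments, with `W = 455` remaining the
default for real data. The normalization sweep uses 10,000 random
model/gene draws at `W = 21`; the chance-level computation uses 500
genes and 100 score redraws.

## Known limitations

* Inter-site distances, transcription kinetics and RNA structure are
  outside the model; the order index is the only positional signal.
* The comparison-trained ablation produces scores, not usages; MAE is
  undefined for it and reported as N/A.
* The feature-network motif list is a default, not a claim: users with a
  curated motif set should supply their own table.
* Fine-tuning assumes the same architecture and window length as the
  pretrained model.
* Training is CPU-bound pure numpy; it is sized for thousands, not
  millions, of genes.
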