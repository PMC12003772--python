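# Methods

## Model

The encoder is a bidirectional pre-norm transformer: residual blocks apply
LayerNorm before exact multi-head attention softmax(QKᵀ/√d_k)V and before a
GELU feed-forward block with a 4× hidden widening; a final LayerNorm closes
the stack. Stochastic depth drops whole residual branches per sample with
probability 0.02·(layer index) during training only; evaluation-mode forward
passes are deterministic functions of (weights, input). No attention
approximation is used — the contract, enforced by tests, is that any
optimized attention path equals the naive per-head computation within 1e-4.
Per-layer Q/K tensors can be cached during a forward pass for network
extraction; caching is purely observational.

Input tokens sum three streams per gene: a frozen identity embedding
(random unit-scale Gaussian stand-ins by default, or any externally computed
per-gene vector table, e.g. protein-language-model embeddings), an
expression MLP on log₂(x+1), and a sinusoidal positional encoding of the
genome-location bin (genes on the same chromosome less than 10,000 bp apart
share a bin; chromosome boundaries always open a new bin, since different
chromosomes share no regulatory neighborhood; coordinate ties are broken by
gene ID for determinism). The expression/total-count MLPs are two layers of
Dropout(ReLU(LayerNorm(Linear(·)))), dims 1→d→d, dropout 0.1. Their weights
and biases use uniform fan-in initialization with nonzero biases: with
zero biases, LayerNorm(x·w) is invariant to the scale of a scalar input, so
every positive count would collapse to a single token and expression
magnitude would be unreadable — a degenerate initialization we explicitly
avoid.

The cell-token block is ordered (total-count, default, one per class) and
serialized with the model, because decoders index positions. The
total-count position carries the encoded total directly rather than a
learned placeholder; at inference this token is the knob that requests a
reconstruction at an arbitrary sequencing depth.

During pretraining a context of `context_size` genes is sampled uniformly
from the expressed genes of the (corrupted) profile and padded with
unexpressed genes at value 0. The padding is load-bearing: predicting true
counts at positions observed as zero is the only training signal that
teaches the model to distinguish dropout from biological absence, so the
context must be large enough that padding actually occurs. The full-scale
design uses 2200 genes for this reason (covering all expressed genes of
most cells); the desk-scale runs here use a 50-gene vocabulary with a
50-gene context, preserving the same property. Any context length ≥ 1 is
accepted at inference.

## Expression decoder

A [d, d, 3] MLP maps each gene's output embedding to raw (a, b, c), with
μ = exp(a), θ = exp(b) (both raw values clamped to [−15, 15] first, since
the NB likelihood overflows easily) and the zero-inflation logit ρ = c, so
π = σ(ρ). The ZINB negative log-likelihood is computed in log space:
log L(0) = logaddexp(ρ, log NB(0)) − softplus(ρ) and
log L(x>0) = log NB(x) − softplus(ρ). This is derived directly from the
mixture definition π δ₀ + (1−π) NB; the test suite pins it against a
numerically normalized PMF oracle on a 1000-point grid (1e-6) and against
its NB (ρ→−∞) and Poisson (θ→∞) limits. NB-only and MSE reconstruction
modes are selectable in the config; MSE reads the log-mean channel as a
single decoded value.

The class decoders are [d, d, d_A] MLPs over ontology leaf labels with the
final layer initialized as weights ~ N(1, 0.02), bias −0.12. The
classification loss is softmax cross-entropy on the raw logits; for a coarse
(internal-node) label the descendant-leaf block is collapsed into one
log-sum-exp logit, which makes the loss algebraically equal to
LSE(all) − LSE(descendants) and therefore invariant to any redistribution
of descendant logits preserving their LSE. Unknown labels contribute zero
loss. Hierarchical ontologies apply where available; classes without one
fall back to a flat label list.

## Pretraining

One step performs a single corrupted encoder pass whose outputs feed all
four objectives (the bottleneck decoder reuses the encoder's placeholder
embeddings; the true total count rides along on the total-count token so the
reconstruction depth is well-defined). Corruption is zero-inflated Poisson
downsampling with dropout fraction r (default 0.6) scaled by s = 0.55;
analytically the retained-count fraction is bracketed by
[(1 − rs)², 1 − rs], which the tests assert instead of the looser prose
figure of "about r dropped". The four losses are summed unweighted.

The contrastive term averages (1 − cos) over all ordered pairs (self-pairs
included) of each cell's disentangled embedding set (default + per-class
placeholders), then over cells. Minimizing (1 − cos) aligns embeddings
rather than repelling them; because the stated intent (disentanglement) and
the stated formula disagree, both signs are implemented behind
`contrastive_sign` ("as-printed" default, "repel" for 1 + cos).

Optimization is decoupled-weight-decay Adam (lr 1e-4, wd 0.01) with linear
warmup (500 steps), global gradient-norm clipping at 100, plateau LR decay
(factor 0.6, patience 1), early stopping after 3 consecutive
validation-loss increases, a 98/2 train/validation split, and sampling with
replacement weighted by 50/(c + 50) over joint-label groups. Stochastic
weight averaging over the second half of training at its own learning rate
(0.03) is implemented but off by default: at desk scale that rate is two
orders of magnitude above the base LR and destabilizes small models.
`TrainConfig.toy()` (lr 3e-3, warmup 100, batch 4) is the preset used for
the few-thousand-step runs in the test suite; the larger defaults above are
kept for realistic-scale training.

## Synthetic data

The generator is a one-step linear structural-equation mechanism: per-group
latent activities (plus per-cell jitter) are propagated once through the
planted directed network, softplus-rectified into rates, normalized into
proportions, scaled by a log-normal library size (σ = 0.3,
E[library] = mean_depth exactly, so analytic gene means are available),
NB-sampled with configurable inverse-dispersion, and thinned by Bernoulli
dropout with probability σ(dropout_logit). Groups are imbalanced
(geometric proportions by default) and hierarchically labeled via a random
rooted ontology; a fraction of cells receive a coarse (parent) label to
exercise the hierarchical loss. Mild multiplicative batch effects
(log-normal, σ = 0.1 per gene per batch) are applied before rate
normalization.

What this emulates: ZINB marginals, library-size variation,
network-structured gene-gene covariance, label imbalance, coarse labels,
batch structure. What it does not: dynamics/trajectories, indirect cascade
effects beyond one propagation step, realistic dropout–depth coupling, and
real biological gene programs — so passing tests demonstrate mechanism
correctness and learnability of planted structure, not performance on real
tissue.

QC follows the standard filter: cells expressing fewer than 200 genes are
dropped; a dataset is rejected (a typed outcome, not an exception) below
100 surviving cells, below 10,000 genes, or when more than 95% of cells
were removed. All thresholds are overridable, and toy fixtures use smaller
ones.

## Networks and benchmarking

Meta-cell attention averages Q and K over the cell set before the softmax;
a singleton set reduces exactly to single-cell attention. Placeholder
rows/columns are dropped before network assembly. Orientation: rows are
targets, columns regulators (the softmax normalizes each target's incoming
mass); `orient()` transposes for ground truths built the other way.
Head selection fits Ridge(α=1, positive coefficients, no intercept) on ±1
edge labels over per-head attention features, using half the ground-truth
edges and non-edges subsampled to ≤10× positives; selected heads (positive
coefficient) are averaged unweighted. Genome-wide assembly averages
block-wise attention by pair co-occurrence count, keeping never-co-sampled
pairs as NaN (absent, not zero).

EPR is the diagnostic odds ratio at the top-K cutoff with ties at the K-th
rank broken by a seeded shuffle so exactly K predictions are made; FP = 0 or
FN = 0 maps to +∞. The conventional precision@K/prevalence form is
available behind a flag. AUPRC integrates (precision − prevalence) clipped
at 0 over achieved recall with the trapezoid rule, thresholds entering at
distinct-score boundaries, with no extrapolation past the last achieved
recall; candidate pairs are all ordered non-self pairs over the common
universe, excluding NaN entries. Prerank enrichment ranks genes by row-sum
(target hubs), column-sum (regulator hubs) or networkx eigenvector
centrality, scores sets with the weighted-KS running sum (weight exponent
1), and draws its null from gene-label permutations (sign-conditioned
nominal p; Benjamini–Hochberg q over the permutation p-values).

## Desk-scale study conditions

The training-smoke protocol used by the acceptance tests: 5000 cells over a
50-gene vocabulary with a 25-gene planted network (edge probability 0.1),
mean depth 500, 8 hierarchically labeled groups; a 2-layer, 2-head, d = 64
model with a 50-gene context trained 2000 steps with `TrainConfig.toy`;
100 held-out cells corrupted at r = 0.7 and denoised at their true totals;
success is a decreasing total loss plus a positive mean Spearman delta,
judged by seed majority. Problem sizes were chosen as the smallest at which
every mechanism (including unexpressed-gene padding) is actually exercised.

## Known limitations

- The numpy/autograd stack is single-threaded and eager; it is built for
  inspectability and desk-scale experiments, not for atlas-scale training.
- Random identity embeddings carry no cross-gene structure, so transfer to
  unseen genes — a motivation for protein-derived embeddings — cannot be
  demonstrated on the synthetic fixtures.
- Inhibitory (signed) regulation is not modeled; attention scores are
  nonnegative.
- The genome-wide assembly's absent-pair handling assumes downstream
  consumers treat NaN as missing, not zero.
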