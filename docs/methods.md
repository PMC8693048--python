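# Methods

`phenocomb` implements a phenotype-driven virtual-screening workflow for
drug combinations: a conditional scaffold generator links transcriptional
phenotypes to chemical substructure, a symmetric synergy regressor scores
candidate drug pairs, and a screening layer composes the two over a
compound library.  This note records the models, their assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Phenotype representation

A phenotype is a 978-entry vector over a fixed landmark-gene panel with
entries in {-1, 0, +1}: the discretized log2 fold change between two cell
states (treated vs control, knockout vs wild type, tumour vs normal).  The
threshold is strict (`|log2FC| > 1`; an exact value of 1 maps to 0) and is
configurable (`deg_vector(threshold=...)`).  Expression profiles used as
cell-line features are min-max scaled per gene to [0, 1]; genes constant
across samples map to 0 ("unexpressed by convention", configurable).
Replicates are collapsed by median for synergy tables and by mean for
expression profiles, both exposed in `collapse_replicates(how=...)`.
The package ships synthetic landmark identifiers (`G0001..G0978`); any
fixed 978-identifier list is accepted interchangeably.

## Chemistry layer

SMILES handling is restricted to a 29-token alphabet: 25 chemistry
characters (C, H, O, N, F, S, Cl, Br, c, n, o, s, +, -, 1-6, =, #, [, ],
(, )), `*` for scaffold attachment points, and `<` / `>` as sequence
start/stop markers.  Tokenization is greedy longest-match so `Cl`/`Br`
never split.  Cleaning keeps the largest organic component, strips salts
and stereochemistry, canonicalizes, and rejects structures that exceed 100
tokens or leave the alphabet; duplicates collapse on canonical SMILES.

Scaffolds are RECAP fragments (RDKit's implementation of the 11
retrosynthetic bond classes) carrying `*` at each cleaved bond.  The
scaffold filter keeps fragments that (1) satisfy fragment-likeness
("rule-of-three") bounds — MW ≤ 300, cLogP ≤ 3, ≤ 3 H-bond donors,
≤ 3 acceptors, ≤ 3 rotatable bonds — (2) contain at least one ring, and
(3), when they have exactly one ring and one attachment point, are complex
enough: more than 10 heavy atoms or more than 2 heteroatoms.  The
heteroatom bound is read strictly ("more than") to parallel the heavy-atom
bound; `ScaffoldFilter(hetero_inclusive=True)` selects the inclusive
reading, and all bounds are configurable.  In substructure screening a
`*` matches any atom, each attachment point must be satisfied by a real
substituent, and additional substitution elsewhere on the core is allowed:
a scaffold is a core to be decorated, not an exact structure.  Similarity
is Tanimoto over 2048-bit radius-2 Morgan fingerprints.

## Neural-network substrate

Both models run on a small reverse-mode automatic-differentiation engine
over NumPy (`phenocomb.nn`): tensors record their producing operations on
a tape and gradients flow back through elementwise arithmetic with
broadcasting, matmul, tanh/sigmoid/relu, softmax, concatenation, slicing,
embedding lookup and a fused softmax-cross-entropy.  All gradients are
verified against central finite differences in the test suite, and
weight initialization is Glorot-uniform from explicit seeded generators,
so every training run is reproducible bit for bit at fixed thread count.

## Gene-scaffold generator (GSG)

A sequence-to-sequence model with attention:

* **Encoder.** The phenotype vector is pooled into non-overlapping windows
  of `enc_window` genes (default 6; window 1 recovers a per-gene
  sequence), processed by a two-layer LSTM, and the final-layer outputs at
  `n_c` evenly spaced positions are projected (tanh) into the context
  matrix `c ∈ R^{n_c × n_H}`.
* **Attention.** At each step a single-layer network scores the context
  positions from `concat(e_D, h)` (token embedding and previous hidden
  state); softmax weights `w` pool the rows into `F = w·c`.  The weights
  are on the simplex by construction and the pooled feature is a convex
  combination of context rows.
* **Stack-augmented LSTM decoder.** The LSTM input is
  `concat(e_D, F, stack_top)`.  After each step, two single-layer networks
  produce a candidate top `s_stack = tanh(D_stack(h))` and a control
  distribution `s_ctrl = softmax(D_ctrl(h))` over (no-op, push, pop); the
  differentiable stack (n_s rows of width n_H) updates as a convex mixture
  of the three literal operations, with zeros filling the bottom row on
  pop.  The stack gives the decoder an explicit memory for nested SMILES
  syntax (ring closures, branch parentheses) and measurably raises the
  fraction of chemically valid samples.
* **Conditioning path.** Besides attention, the decoder's initial hidden
  and cell states are seeded from the mean context row
  (`h_0 = tanh(W_h · mean(c))`).  Attention-only conditioning proved
  fragile at desk scale — the decoder can ignore a weak pooled feature and
  still fit the training set — while state initialization makes the
  phenotype signal load-bearing from the first token.  With a zero context
  (pretraining, unconditional sampling) this reduces to a learned constant
  start state.

Training is teacher-forced in two stages with RMSprop (default learning
rate 1e-4, batch 128): *pretrain* fits the decoder alone with a zero
context so it learns SMILES grammar from scaffolds; *finetune* trains
encoder and decoder jointly on (phenotype, scaffold) pairs.  The loss is
token-level categorical cross-entropy over the vocabulary; a per-token
one-hot binary-cross-entropy variant is available (`loss="bce"`) but a
29-way token choice is naturally a categorical problem, so cross-entropy
is the default.  Sampling draws multinomially at a configurable
temperature (default 1.0, greedy mode available), starts from `<`, and
stops at `>` or after 100 tokens.  Architecture defaults (`n_c` 16, `n_H`
256, `n_s` 10, embedding 128, 2 encoder layers) are config values; no
canonical sizes exist for this architecture.

## Symmetric synergy predictor (SDSP / DSP)

Inputs are two drug SMILES (10-100 tokens) and a cell line's scaled basal
expression.  One *shared* drug encoder — embedding, two-layer
bidirectional LSTM, masked mean pooling over valid positions, linear
projection — produces `z_A` and `z_B`; sharing is required for the
drug-order swap to be meaningful and halves the parameters.  A two-layer
feed-forward encoder produces the cell embedding `z_G`.  Two separate
three-layer heads (default widths 512/256/1) score the two concatenation
orders:

    ss_AB = head1(concat(z_G, z_A, z_B)),   ss_BA = head2(concat(z_G, z_B, z_A))

and the final prediction is their mean.  The loss is

    L = MSE(ss, (ss_AB + ss_BA)/2) + α · MAE(ss_AB, ss_BA),   α = 1

whose second term penalizes order-dependence directly.  Training uses Adam
(learning rate 1e-4 default, batch 256, gradient update every 10 batches)
and re-draws a randomized SMILES rendering of every drug each epoch, which
teaches the encoder that different renderings of one molecule are the same
drug.  The DSP variant replaces the sequence encoder with a feed-forward
network over Morgan fingerprints and keeps every other contract.

Evaluation reports Pearson and Spearman correlation, AUROC/AUPRC
(positives are samples with |true score| > 5, ranked by |prediction|), and
the AB-BA Pearson correlation between predictions on each sample and its
drug-order-reversed twin.  Encoding stability is quantified by the full
width at half maximum (FWHM) of the prediction distribution across k×k
randomized re-encodings of a fixed pair, estimated from a histogram (span
of bins reaching half the peak count); constant predictions give 0.

## Bin-wise score augmentation

Observed Bliss scores concentrate near zero (empirically close to
N(-0.55, 5.45²)), starving a regressor of synergistic and antagonistic
examples.  The training table is flattened toward a wider target
N(-0.55, 8.25²): 300,000 points are drawn from the target, both
distributions are histogrammed on 101 unit-width bins spanning
[-50.5, 50.5] (scores outside the range clamp into the terminal bins,
half-open bins except the last), and each bin where the target count
exceeds the source count is topped up by resampling that bin with
replacement.  Oversampling applies only where the target exceeds the
source: adding samples where the source already exceeds the target would
sharpen, not flatten, the distribution; `strict_abs_diff=True` reproduces
the literal absolute-difference reading.  Resampled copies get fresh
randomized SMILES and Gaussian score jitter (sd 0.1 — "minimal" noise is
not otherwise quantified), and finally every row is mirrored
(A,B) ↔ (B,A), making the pair distribution exchangeable.  Original rows
are never removed and the mean is preserved up to sampling error because
source and target share their mean.

## Screening and candidate selection

The *partner screen* takes a known drug plus the phenotype of the desired
partner: sample `n` scaffolds (default 100) from the generator, keep the
chemically valid ones, deduplicate on canonical fragment SMILES, apply the
scaffold filter, collect library molecules containing any surviving
scaffold, score each hit in combination with the known drug, and rank by
predicted score with ties broken by canonical SMILES.  The *de novo
screen* pairs hits of *different* scaffolds (a pair must realise two
distinct scaffolds; with one scaffold per family this is the cross-family
product, and the count for disjoint hit groups is exactly
Σ_{i<j} h_i·h_j), deduplicates unordered pairs, and scores them; a
`same_scaffold` flag (default off) admits within-scaffold pairs.
Candidate selection keeps |score| ≥ 5 (inclusive boundary), with a
synergistic-only mode keeping score ≥ 5.  Multi-cell screens are
independent runs per cell line; no cross-cell aggregation is defined.

## Mechanism typing

From curated or predicted target sets: overlap type `a` if the common
target ratio |tA∩tB|/|tX| is below 10% for both drugs, `c` if above 80%
for both, else `b` (strict boundaries).  Specificity: a drug with at most
10 targets is molecularly targeted, more than 50 wide-spectrum; pairs are
`d` (two targeted), `e` (two wide), `f` (mixed).  Both conventions for
e/f appear in the literature, so `figure_mapping=True` swaps them; drugs
with 11-50 targets return an explicit `unclassified` rather than a silent
bin.  The drug-target-interaction predictor is a protocol (SMILES +
protein → probability); a lookup-table implementation ships for tests and
curated data, and any external compound-protein model can be plugged in.

## Synthetic benchmark

The generators in `phenocomb.synthetic` define the study conditions for
all tests; they emulate the *shape* of the real data, not its biology:

* **Phenotype classes.** K = 3 classes by default, each owning a disjoint
  block of 60 informative genes with fixed random signs; vectors get a 2%
  per-gene random flip.  Class k pairs with variants of one scaffold
  family (200 pairs per class).
* **Scaffold families.** Eight hand-picked ring systems (benzene, indole,
  pyridine, piperidine, quinoline, morpholine, naphthalene, pyrimidine
  cores with 1-2 attachment points), all passing the scaffold filter,
  mutually distinct under Morgan/Tanimoto.  Variants substitute ring CH
  positions; library members additionally fill every attachment point with
  small substituents.  Decoys are random acyclic branched skeletons —
  acyclic molecules cannot contain any ring family, and every decoy is
  re-verified against all families before inclusion.
* **Cell panel.** One profile per class: uniform baseline in [0, 0.4]
  with the class's gene block raised to [0.8, 1].  The panel is a fixed
  property of the spec (not of the table draw seed) so training tables,
  test tables and screens share cell identities, as real cell lines would.
* **Synergy ground truth.** Score = N(-0.55, 5.45²) background + a
  deterministic +12 bonus when (family_A, family_B, cell class) matches a
  planted rule ((k, k+1) synergistic and (k, k+2) antagonistic in cell k),
  -12 for antagonism, + unit observation noise.  Rules are symmetric in
  drug order.  Half of the samples are drawn from planted rules so both
  signal classes are well represented.
* The +-12 effect against the 5.45 background bounds the achievable
  held-out correlation near r ≈ 0.85; passing the r ≥ 0.7 check therefore
  demonstrates genuine recovery, not memorization of a noise-free rule.

What passing these tests does *not* show: performance on real synergy
assays (batch effects, dose-response surfaces, assay heterogeneity),
real L1000 noise structure, or chemistry beyond the 29-token alphabet.

## Desk-scale problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline with
reduced model sizes, chosen once as the package's benchmark configuration:
generator with n_c 8, n_H 64, n_s 6, embedding 32, encoder window 12,
RMSprop lr 5e-3, batch 32 (20 pretraining epochs on 500 scaffolds, 25
finetuning epochs on 600 pairs); synergy model with n_H 32, embedding 32,
heads 64/32/1, Adam lr 2e-3, batch 128, no gradient accumulation
(16 epochs on 5,000 samples; accumulation over 10 batches is designed for
hundred-thousand-sample tables where the effective batch of 2,560 is a
small fraction of an epoch, and would leave a 5,000-sample epoch with two
updates).  Screens use a 250-compound library with the planted-rule
families rarer than the neutral family, which mirrors the realistic
situation that true partners are a small fraction of a library.

## Numerical choices and degenerate inputs

Forget-gate bias starts at +1; gradients are clipped to norm 5; softmax
and cross-entropy are computed in the log-sum-exp stabilized form;
sampling excludes the padding token.  Constant genes normalize to 0;
correlation on constant vectors is flagged `nan` rather than raised;
FWHM of all-equal predictions is 0; empty screens return explicit status
values (`no-scaffolds`, `no-hits`, `insufficient-families`) instead of
empty silence.  Candidate ranking breaks score ties lexicographically on
canonical SMILES so output tables are byte-reproducible.

## Known limitations

* The autodiff engine is single-threaded NumPy; it is sized for
  desk-scale experiments, not for hundred-thousand-sample training runs.
* RECAP fragmentation and the scaffold filter inherit RDKit's ring
  perception and descriptor definitions; other toolkits may disagree at
  the margins (e.g. logP models).
* The drug-target-interaction step is an interface with a lookup
  implementation; mechanism typing of novel compounds is only as good as
  the plugged-in predictor.
* Generated scaffolds are sampled, not searched: rare families may need
  more draws, and generation fidelity depends on how separable the
  phenotype classes are.
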