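# Methods

## The prediction problem

MHC class I molecules present short endogenous peptides (8–11 residues)
on the cell surface; which peptides a given allele binds and presents is
the central question of epitope discovery. `degenmhc` implements a
pan-specific predictor: a single model covers many alleles by
conditioning on a structural summary of each allele — the *pseudo
sequence*, the ordered set of MHC α-chain residues observed within 4.0 Å
(any atom pair) of a bound peptide in crystal structures. Two tasks are
supported: antigen presentation (AP; binary, the label type produced by
mass-spectrometry immunopeptidomics) and binding affinity (BA;
continuous IC50 values mapped to `log50k(IC50) = 1 − log IC50 / log 50000`,
clipped to [0, 1], so 1 nM → 1 and 50 μM → 0; the conventional binder
call is IC50 < 500 nM, with the boundary itself a non-binder).

## Degenerate encoding (the ILA)

Each peptide–allele pair becomes a 20 × 9 × 21 image-like array:

* rows: the 20 amino-acid types (fixed alphabetical order
  `ACDEFGHIKLMNPQRSTVWY`; the order is a convention — any fixed order is
  equivalent under consistent use);
* columns: 9 core positions. 9-mers map by identity; an 8-mer gets a
  placeholder at slot 5; 10/11-mers delete the middle residue(s)
  (peptide positions 5, resp. 5–6) — a deterministic middle
  insertion/deletion rule that preserves the anchor-bearing termini;
* channel 0 (*contact channel*): entry (h, j) = 1 iff the allele's
  pseudo sequence contains a residue of type h that structurally
  contacts core position j, under the consensus position → core map;
* channels 1–20 (*peptide channels*): channel c carries 0.90 in column j
  when the core residue at j is amino acid c, 0.05 everywhere else,
  broadcast over the row axis; placeholder columns are all 0.05.

Broadcasting the peptide channels over all rows (rather than restricting
the 0.90 to rows where the contact channel is set) keeps the peptide
fully decodable from the array for any allele, including alleles with
sparse contact maps; the contact × peptide interaction is then exposed
to the network explicitly (see the interaction stem below). The hit/miss
constants are config-exposed. Flat baseline encodings (one-hot and
BLOSUM62 rows, 21 numbers per residue over pseudo-sequence plus core
residues, zero vectors at placeholders) are provided for ablations.

Two published preset position lists ship with the package: the
34-residue peptide-contacting list used by NetMHCpan-style encoders
(positions 7, 9, 24, 45, …, 171 in mature-chain numbering) and the
37-residue variant used by MHCflurry-style encoders (the same 34 plus
91, 102, 199). New specs can be derived from PDB structures: the peptide
chain is the unique polymer chain of length 8–11 (ties broken by chain
identifier), the MHC chain is the longest remaining chain, only 9-mer
complexes contribute, residues are renumbered sequentially from the
first observed residue (mature-chain convention, ignoring author
numbering), all atoms count (no atom-type filtering), and a position
enters the spec when it contacts any core position in at least
`min_support` structures (default 1; the threshold is exposed because
published derivations do not state it).

## Network

The model is implemented in numpy with hand-written backpropagation;
single precision throughout. Input batches are (N, 20, 9, 21),
channels last.

1. **Attention block.** Each amino-acid row h gets one single-filter 1-D
   convolution (width 3 by default, zero-initialized) along the core
   axis of its 9 × 21 slice; the output is mean-reduced, shifted by a
   per-row bias, and squashed by a logistic into a score a_h ∈ (0, 1)
   that rescales row h. The biases are initialized from min–max-scaled
   amino-acid frequencies of the training peptides (uniform fallback →
   all weights 1), so with zero filter weights a_h = logistic(init_h).
   This is the only part of the architecture with row-specific
   parameters, i.e. the only mechanism that can weight amino-acid types
   individually; it therefore trains with an 8× learning-rate multiplier
   — its 20 biases otherwise receive weak, heavily shared gradients
   relative to the convolutional stack.
2. **Interaction stem.** The contact channel is multiplied elementwise
   with each peptide channel and the 20 product channels are appended
   (41 channels total). These products are exactly the pairwise
   contact × peptide co-occurrences the encoding interlocks; computing
   them explicitly spares the convolutional stages from having to
   synthesize multiplications out of their nonlinearities.
3. **Backbone.** A pointwise projection to the first stage width, layer
   normalization, then ConvNeXt-style stages (defaults: two stages,
   widths 16/32, depth 1 each): depthwise convolution with same padding
   (default kernel 3 × 7 — wide along the core axis, narrow along the
   type axis, where alphabetical adjacency carries no meaning), layer
   normalization over channels, pointwise 4× expansion with GELU
   (tanh approximation), pointwise contraction, residual connection.
4. **Readout.** Global average pooling of the final stage, concatenated
   with the stem's product channels pooled over core positions only — a
   20 × 20 MHC-type × peptide-type interaction profile read directly by
   the head. A single linear unit produces the output; AP reads it
   through a logistic (probability), BA reads the same bounded (0, 1)
   value as the log50k target and converts to IC50 via the inverse
   transform.

Training uses Adam (base rate 2 × 10⁻³, halved every 8 epochs), batch
size 64, up to 24 epochs, early stopping on a held-out validation split
(default 10–15%) with patience 6 and restoration of the best state. All
randomness (initialization, shuffling, dropout) derives from one
recorded seed; two runs with the same seed and data are bitwise
identical. Non-finite losses abort with a diagnostic. The same code
path serves transfer learning: an affinity model can be warm-started
from a fitted presentation model's backbone (all non-head parameters
copied, head reinitialized, source state hash recorded), mirroring the
pretrain-on-MS / finetune-on-affinity workflow.

The depthwise/pointwise primitives are also exposed functionally
(`degenmhc.nn.depthwise_conv`, `pointwise_stack`, valid positions only)
and are cross-checked in the tests against a quadruple-loop brute-force
oracle and against `scipy.signal.correlate` at 10⁻⁶ absolute tolerance.

## Semi-supervised augmentation and decoys

MS presentation records convert to pseudo-labelled affinity records by
anchoring positives at 100 nM and negatives at 10,000 nM (config-exposed;
the anchors must fall on the correct sides of the 500 nM boundary, which
is validated). Random decoy peptides are sampled i.i.d. per position
from a configurable composition (uniform default) with lengths drawn
from {8, 9, 10, 11}; decoys colliding with observed positives are
resampled. Decoys are retained as negatives only when every supplied
affinity model predicts them weak — predicted IC50 above 1000 nM —
using this package's own BA models as the predictors. Train/test overlap
removal drops any (allele, peptide) pair present in the test set.

## Synthetic world

The generator builds a ground-truth universe for parameter-recovery
testing. A world draws a factorized residue compatibility table
`compat = u vᵀ` with u ≥ 0 half-normal (pocket interaction strength per
MHC residue type) and v standard normal (peptide-residue favorability) —
a deliberate first-order model in which the two sides multiply. Each
allele receives random pseudo residues on a shared position list
(default 12 positions), a random subset of 5 of the 9 core positions it
contacts, and a random position → core assignment within that subset.
The preference of allele a for amino acid aa at core j is the mean
compatibility of aa with the residues contacting j; a peptide's binding
score is the mean preference over the allele's contacted cores, so
uncontacted cores are pure noise for the label. Scores map to log50k
targets through a logistic link (any monotone link suffices) with
additive Gaussian noise σ = 0.1; presentation labels threshold the
target at a quantile, fixing the positive rate exactly. Defaults:
4 alleles, lengths drawn as 8/9/10/11 with weights 0.1/0.7/0.1/0.1
(9-mer-dominated, as real immunopeptidomes are).

What this world does *not* emulate: real anchor-position motif
structure, allele frequency imbalance, peptide source-protein biases,
measurement-specific noise of MS versus competition assays, and any
higher-order (non-multiplicative) residue interaction. Passing the
recovery tests therefore shows that the encoding, network and training
machinery can extract a planted contact-driven binding rule at realistic
noise — not that the defaults would reach any particular accuracy on
real immunopeptidome data.

The world also writes toy PDB fixtures realizing a chosen contact
assignment: contacting atom pairs are placed at 3.5 Å and every other
inter-chain pair at ≥ 8 Å, so recovery through the structural pipeline
at the 4.0 Å criterion is exact by construction.

## Evaluation and the encoding ablation

Classification reports accuracy, F1 and MCC (0 by convention when a
confusion-matrix marginal is empty, following the usual treatment of
degenerate folds); regression reports Pearson r and MSE on the log50k
scale; test sets are additionally stratified by peptide length
(8/9/10/11), the regime where encodings differ most. Cross-validation
uses stratified k-fold splits (k = 5 default) that are deterministic per
seed; the fold hash is recorded and asserted identical across the arms
of an ablation.

The ablation harness trains one *identical* compact CNN per encoding —
two 3 × 3 convolutions (widths 8/16), ReLU, global pooling, linear head;
inputs carrying the ILA's 21 channels additionally get the same
interaction stem and row-resolved product readout as the full model,
applied identically to every such encoding — on bitwise-identical folds
with identical seeds, then reports per-fold accuracies, mean, standard
deviation, a Shapiro–Wilk normality p-value per encoding and a t-test of
each encoding against the degenerate reference. The t-test is Welch's
two-sample form (a paired variant is config-selectable; which form the
published table used is not stated, and with five folds the two rarely
disagree in direction). Comparing an encoding against itself reports
p = 1 by convention. The headline contrast is the degenerate encoding
with the *true* contact maps versus the same encoding with per-allele
core-shuffled maps: because the synthetic labels are generated through
the true assignment, the shuffled arm mispairs contact information with
peptide positions, and the accuracy gap measures how much of the
learnable signal the contact channel itself carries.

## Problem sizes and numerical choices

The shipped study conditions are desk-scale by design: parameter
recovery trains on 5,000 presentation records (σ = 0.1, positive
fraction 0.3) and evaluates on 1,500 held-out records, with a median
over three training seeds; the ablation uses 2,000 records, 5 folds and
three world seeds. Oracle equivalence for the convolution primitives is
asserted at 10⁻⁶ absolute; transform round-trips at 10⁻⁹; encoding and
structure round-trips are exact. Degenerate inputs are errors, not
silent fallbacks: empty record sets, zero-variance regressions,
non-positive IC50s, unknown residues, and classes too small to stratify
all raise with a message naming the offender.

## Known limitations

* The backbone is a compact stand-in for a full-scale ConvNeXt; widths,
  depths and the attention reduction (mean over conv outputs, then
  logistic) are this package's design choices where published details
  end.
* The contact channel is binary (an allele either presents a contacting
  residue type at a core position or not); contact frequencies across
  structures are aggregated only through the `min_support` threshold.
* Non-9-mer core alignment is a fixed middle insertion/deletion rule;
  no alignment search is performed.
* The numpy implementation is single-threaded BLAS-bound; it is sized
  for datasets up to ~10⁴ records, not for million-record training.
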