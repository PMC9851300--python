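# Methods

`ltrnet` builds reference libraries of intact LTR-retrotransposons
(LTR-RTs) from plant genome assemblies.  The method is a hybrid of neural
prediction and structure-based candidate finding; this note records the
model, its assumptions, the numerical choices, and what the synthetic
data used for training and testing does and does not emulate.

## Pipeline

1. **Sanitising.**  Sequences are uppercased and every character outside
   {A, C, G, T, N} is *replaced* by N.  Replacement (not deletion)
   preserves the 1:1 coordinate mapping between the cleaned sequence and
   the assembly; a strict-deletion utility exists separately for library
   post-processing.
2. **Windowing.**  Each sequence is tiled into non-overlapping 50 kb
   windows.  With `C` analysis cycles (1–5), cycle `c` shifts the tiling
   by `floor(50000·c/C)` bases, so an element split by one cycle's window
   boundary lies inside a window of another cycle.  The final sub-window
   fragment is kept and N-padded to full width (no terminal sequence is
   discarded); padding never enters candidate coordinates.
3. **One-hot encoding.**  A window becomes a 5×n binary matrix with fixed
   row order (A, C, T, G, N), one 1 per column.  Filter banks and all
   networks depend on this constant.
4. **Detection.**  A CNN scores each window for containing an LTR-RT;
   windows below the threshold (default 0.5) are dropped before the more
   expensive structural stage.
5. **Structural candidates.**  Inside each retained window a
   seed-and-extend direct-repeat finder locates paired LTRs: exact 20-mer
   seed matches at a compatible spacing are grouped by diagonal, each
   cluster is extended outward from its longest run of consecutive seeds
   (a block that is exact by construction), and boundaries are snapped to
   TG…CA termini.  Filters: element length within [2000, 28000] bp
   (flags -m/-M), TG…CA termini on both LTRs (-i), and a 4–6 bp
   target-site duplication (TSD) abutting the element (-d).  An adapter
   ingests external candidate tables (TSV, 1-based inclusive) so any
   third-party structural detector can stand in for the built-in finder.
6. **Features.**  Each candidate's occurrence counts of all k-mers,
   1 ≤ k ≤ 6 (5460 dimensions, lexicographic order with A<C<G<T), are
   computed by a fixed-weight convolution: the filter of k-mer *m* is the
   5×k one-hot matrix of *m* (zero weight on the N row) with bias 1−k; a
   matching position scores k, the bias brings it to 1, any mismatch or
   N-overlap falls to ≤ 0 and is clamped by rectification, and the sum
   over positions is the exact count.  Counts are then PCA-reduced and
   standardised.
7. **Curation and classification.**  An FNN assigns an intactness
   probability (class 0 = intact); with curation on, elements below 0.5
   are dropped.  A second FNN with 13 softmax outputs assigns the
   lineage; exact ties resolve to the lowest class index.
8. **Non-maximal suppression.**  A prediction's score is the mean of its
   three network probabilities.  Predictions pooled over all cycles are
   reduced greedily in descending score (ties: longer element, then
   smaller start): a prediction is kept iff its interval IOU with every
   kept prediction on the same sequence is ≤ 0.6, where
   IOU = max(0, min(Y1,X1) − max(Y0,X0)) / (max(Y1,X1) − min(Y0,X0)).
   IOU is never evaluated across different source sequences, and
   suppression is applied once, globally, to the pooled set.

Outputs: a FASTA library with RepeatMasker-style headers
(`{id}_{start}_{end}#LTR/{lineage}`, 1-based inclusive) and a TSV
predictions table (`ltrnet_predictions.tab`) with the three
probabilities and their mean per element.  Internally all coordinates
are 0-based half-open.

## Networks

All three networks run on a small numpy engine written for this package
(`ltrnet/_nn.py`: 1-D convolution, max pooling, dense, batch
normalisation, dropout; SGD-with-momentum and Adam; seeded
initialisation, shuffling and dropout masks), since no deep-learning
framework is part of the package's dependency set.  Training is
single-threaded-deterministic: identical seed, data and config reproduce
identical weights.

* **Detector** — three conv layers (32, 64, 128 filters, kernel width
  10), each followed by max pooling (width 10), then dense layers of
  1000 and 500 units, all ReLU, sigmoid output; SGD (momentum 0.9,
  gradient-norm clipping at 5) on binary cross-entropy; 100 epochs,
  batch 64.  Conv filter counts/kernels and pool widths are
  configurable; the published recipe fixes the layer counts, dense
  sizes, optimiser, loss, epochs and batch size.  Pool widths may be
  given per layer, and a width of 0 pools each channel over its whole
  feature map.  The bundle trained for the end-to-end tests uses
  (16, 32, 64) filters and pools (10, 10, global): with a global final
  pool the dense head sees position-invariant features, which is what
  lets a ~100-window corpus generalise at full 50 kb width — with a
  flatten head the same corpus is memorised (train loss → 0, held-out
  accuracy ≈ chance) because the head can key on *where* the element
  happened to sit in the training windows.
* **Intactness filter** — three hidden layers of 200 units, each with
  batch normalisation (momentum 0.99), ReLU and dropout 0.5; l1 penalty
  1e-4 on kernels, l2 penalty 0.01 on biases; 2-class softmax; Adam on
  categorical cross-entropy; 200 epochs, batch 128.  Label convention:
  0 = intact, 1 = non-intact.
* **Lineage classifier** — identical recipe with 13 softmax outputs.
  The 13 default labels are common Copia/Gypsy plant lineages
  (RLC_Ale … RLG_Retand); the bundle carries the list, and retraining
  with any 13-entry label set is supported.

**Feature preprocessing.**  PCA defaults to 64 components via randomised
SVD (a float in (0,1) switches to a full-SVD variance target; the
variance-target default was rejected because a full SVD of an n×5460
matrix costs minutes at the corpus sizes used here), followed by
standard scaling.  The fitted transform is stored as plain arrays in the
bundle.

**Training protocol.**  Every `train_*` entry point takes an explicit
seed, refuses single-class inputs, performs its own stratified 80/20
train/validation split and reports held-out accuracy in the returned
history.  Learning rate for the detector defaults to 0.005: 0.01 shows
loss spikes, and without gradient clipping a single oversized early step
leaves the ReLU stack permanently dead (loss pinned at ln 2).

## Synthetic data

The generators provide seeded, coordinate-exact stand-ins for the
training corpora the production tool would be trained on:

* **Lineage models** — 13 order-2 Markov chains over {A,C,G,T}, each
  with a distinct stationary composition (random row-stochastic tables
  biased toward a per-lineage base composition; fixed internal seed, so
  the default models are package constants).  Each lineage has a narrow
  element-length envelope (centres 3000–9000 bp ± 200, inside the
  global [2000, 28000] envelope) and an LTR-length range (roughly
  300–1100 bp).  Narrow envelopes make length-given-composition
  informative for the intactness filter.
* **Elements** — LTR + internal + LTR from the lineage model; both LTRs
  start TG and end CA; the 3′ copy carries 2% substitutions (termini
  protected).
* **Implantation** — a 4–6 bp TSD is copied from the host flank to the
  element's right flank, exactly as insertion would leave it.
* **Background** — a separate near-uniform order-2 model ("other
  genomic features").  This is an explicit stand-in: it has no genes,
  GC landscape, tandem repeats or degraded element copies, so passing
  detector tests show separability of implanted composition from this
  background, not performance on real assemblies.
* **Non-intact decoys** (filter training, label 1), uniform over three
  kinds: (a) an element of another lineage nested inside an element;
  (b) length violations — truncation to 60% or extension to 150% of the
  true length, decisively outside the ±20% tolerance applied to the
  lineage envelope; (c) a Class II-like cassette (20 bp terminal
  inverted repeats, own composition model, ~0.5–2 kb) inserted into the
  element.
* **Genomes** — implants are placed in equal slots with ≥ 1 kb spacing;
  on request one implant is centred on a 50 kb multiple so that
  single-cycle windowing must split it (the multi-cycle test case).

## Problem sizes and tolerances

Corpus sizes used by the test suite and the acceptance script (chosen as
CPU-scale study conditions): detector 200 windows at 5 kb width (30
epochs); filter 1000+1000 elements; classifier 13×200 elements (60
epochs each, PCA 64); end-to-end bundle 200 windows at 50 kb (40
epochs, slim detector as above), 1000+1000 filter elements and 13×40
classifier elements (100 epochs; at 400+400 the filter's ~8% intact
false-negative rate makes curation drop genuine elements); evaluation
genome 500 kb with 10 implants.  K-mer
counts are exact integers and all three counting routes (convolutional,
rolling-code, naive oracle) must agree exactly; scores are small
integers, exact in float32.  Degenerate inputs: sequences shorter than k
count 0 for that k; empty candidate lists, empty libraries and
background-only genomes are valid outputs; a genome in which no
sequence spans one window is an error.

## Known limitations

* The direct-repeat finder assumes substitution-only divergence between
  LTR copies (no indels): seeds and extension operate on a single
  diagonal.  Young, intact elements fit this; degraded copies are the
  filter network's job, not the finder's.
* Reverse-strand logic is unnecessary (direct repeats are
  strand-symmetric) and PBS/PPT/internal-domain evidence is not used.
* The background model understates real-genome confounders (solo LTRs,
  segmental duplications, satellite arrays); false-positive rates
  measured here do not transfer to real assemblies.
* No pre-trained weights ship with the package: training on synthetic
  data is part of the test suite, and retraining on user libraries is
  the supported path for real use.
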