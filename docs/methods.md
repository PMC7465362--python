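# Methods

## Problem setting and model

The classifier decides whether the cytosine at the center of a 41-nt DNA
window is N4-methylated. Windows are strings over {A,C,G,T,N}; the central
base (index 20, 0-based) is required to be C, a constraint the I/O layer
enforces and that can be relaxed for non-standard inputs. Labels travel
outside the FASTA records — one file of positives, one of negatives — which
is how 4mC benchmark sets are normally distributed.

The model is a small 1-D CNN applied to an encoded (positions × channels)
representation of the window. Each of the two convolution blocks is
Conv1D → ELU → group normalization → max pooling → dropout; the head is
flatten → dense(ELU) → dense(1, sigmoid). The network is implemented
directly in NumPy with hand-derived backward passes for every layer. This
keeps the dependency surface to the scientific Python stack and gives exact
input gradients for the saliency analysis; both parameter and input
gradients are validated against central finite differences in the test
suite (relative tolerance 1e−4 and 1e−3).

Assumptions worth making explicit: windows are independent samples (no
genomic context is shared between records), classes are learned from local
sequence composition only, and N is an uninformative fifth symbol (all
encodings map it to zeros or treat it as its own token).

## Encodings

All six encoders are pure functions; shapes for L = 41 are frozen and
property-tested:

* **BE** — per-base one-hot over channels (A,C,G,T,N); N encodes to the
  zero vector, so "unknown" carries no signal.
* **DNC/TNC** — each overlapping k-mer (k = 2, 3) is one-hot over the 5^k
  k-mer alphabet, giving positional matrices of 40×25 and 39×125. The
  positional (rather than global composition) reading is required for the
  convolution to see where a k-mer occurs and for the saliency map to
  resolve per-position dinucleotide importance. The channel order is
  lexicographic over the alphabetical symbol order A,C,G,N,T and is part of
  the stable interface.
* **NCP** — ring structure x (purines A,G), hydrogen-bond strength y (weak
  pairs A,T), amino group z (A,C); N maps to the origin (0,0,0).
* **NCPNF** — NCP plus the cumulative nucleotide density
  dᵢ = (occurrences of sᵢ in positions 0..i)/(i+1), which injects
  coarse positional/compositional information; d₀ = 1 and dᵢ ∈ (0,1].
  The matrix has 4 informative channels; an option zero-pads to 5 channels
  for strict shape parity with BE, since no fifth feature is defined.
* **MMI** — a global 55-vector: 5 mononucleotide frequencies, 15 pairwise
  mutual-information terms over the unordered adjacent-pair set, and 35
  triple terms over the complete unordered 3-tuple multiset (C(7,3) = 35;
  5 + 15 + 35 = 55). Pair and triple frequencies count unordered adjacent
  windows (L−1 and L−2 of them). Every term whose logarithm would touch a
  zero frequency is defined as 0, which is the correct limit of x·ln x and
  keeps the features finite. MMI is reshaped to (55, 1) so the same model
  applies; being non-positional it supports mutagenesis but not saliency.

## Training protocol and numerical choices

Defaults: 2 blocks, 32 filters of width 5, stride 1, 4 normalization
groups, pooling 4/2, dropout 0.25, 32 dense units, L2 10⁻⁴ applied to the
weights *and biases* of the convolutions and the hidden dense layer
(the output unit is unregularized). Optimization is SGD with momentum 0.95
and learning rate 0.005 on binary cross-entropy, batch size 32, at most
100 epochs.

Choices the reference configuration leaves open, fixed here:

* **Padding** — convolutions and pooling both use "same"-style padding
  (output length ⌈L/stride⌉, pooling pads with −∞). This keeps the
  two-block chain valid for every in-scope input, including the shortest
  (39 positions for TNC, 55×1 for MMI), and makes the positional maps easy
  to align with the sequence. Frozen and documented.
* **Early stopping** monitors the regularized validation loss; training
  halts after 30 epochs without a new minimum and the best-epoch weights
  are restored (checkpointing). A vanishing validation-loss improvement
  therefore counts as "no improvement".
* **Weight initialization** is Glorot-uniform from an explicit
  `numpy.random.Generator`; the same generator drives shuffling and
  dropout masks, so a fit is bit-reproducible for a fixed seed on a fixed
  NumPy build. Cross-platform bit identity is not promised; statistical
  claims in the tests use bands, not exact values.
* **Loss stability** — BCE is computed from logits via softplus; a
  non-finite training loss aborts with a diagnostic rather than silently
  continuing.
* **Grid search** enumerates the Cartesian product of the standard tuning
  ranges (conv layers 1–5; filters 8–128; kernel 2–14; pool size/stride
  2 or 4; dropout 0.2–0.4; 8000 points), scores each by k-fold
  cross-validation, and selects by mean validation MCC (ties: first in
  iteration order). Combinations whose pooling chain shrinks the input
  below the kernel width are skipped and logged, not fatal.

## Evaluation

`make_folds` stratifies, shuffles with a seed, and cuts k near-equal folds
(scikit-learn's StratifiedKFold supplies the partition); rotation j tests
on fold j, validates on fold (j+1) mod k, and trains on the rest — the
8/1/1 role split at k = 10. The validation-fold assignment rule (cyclic
successor) is this package's construction; only the role split itself is
standard. Metrics are computed per rotation and aggregated as the mean
over folds (not pooled predictions). MCC is defined as 0 whenever a
marginal of the confusion matrix is zero. The classification threshold is
fixed at 0.5. ROC is swept over unique scores and AUC computed by the
trapezoidal rule, which equals the tie-aware normalized Mann–Whitney
statistic; the implementation is cross-checked in tests against both an
O(n²) concordant-pair oracle and scikit-learn.

## Interpretation maps

*Mutagenesis*: for every record, position i and symbol a ∈ {A,C,G,T,N},
substitute, re-encode, re-predict and record |p_mut − p_orig|; the map is
the element-wise mean over records, so substituting a record's own symbol
contributes exactly 0. Substitution to N is included because the alphabet
treats it as a first-class symbol.

*Saliency*: the gradient of the **pre-sigmoid logit** (not the
probability, which saturates on confidently classified windows) with
respect to the encoded input, multiplied element-wise by the encoding and
summed over channels per position. Per-position importances are folded
into dinucleotide cells: the score of the 2-mer starting at position i is
importance(i) + importance(i+1), accumulated into the cell of the
dinucleotide observed there and averaged over records. For DNC the input
positions already index 2-mers and are used directly; for TNC each
window's importance is first spread over its three member bases; MMI has
no positional gradient path and is rejected with an explanatory error.
Whether to attribute over all records or positives only is a flag; the
default uses all records.

## Synthetic data generator

`SyntheticSpec` defines the study conditions: balanced classes of 41-nt
windows, i.i.d. background uniform over A,C,G,T with a 1% N admixture
(so every encoder's N path is exercised), central C enforced, and a motif
(default "CC" starting on the central C) written at a fixed site with
probability p_pos in positives and p_neg in negatives (defaults 0.9/0.1).
When the motif is *not* planted the site is redrawn until it does not
spell the motif, so site presence is exactly Bernoulli(p) per class:
p = 1 vs 0 yields classes separable by a single substring test, and
p_pos = p_neg yields an exact no-signal null. Motif occurrences elsewhere
in the window remain possible, as in real sequence. A motif overlapping
the center must carry C at the central position.

What the generator does **not** emulate: realistic nucleotide composition,
CpG/strand structure, positional heterogeneity, correlated motif variants,
or label noise. Passing tests on this data therefore demonstrate that the
pipeline can recover a localized, position-fixed signal — not that it
matches published benchmark performance, which depends on the original
species datasets.

## Problem sizes

The end-to-end checks run 10-fold cross-validation on 300 windows per
class (separable and null conditions) with the default architecture and
schedule, and train one binary-encoded model on 150 windows per class for
the interpretation maps, attributing over every second record for
mutagenesis (41 × 5 re-predictions per record). These sizes give stable
statistics for the qualitative claims being tested while keeping a full
run to a few minutes on one CPU.

## Known limitations

* The redundancy filter is a deliberately naive greedy identity scan; it
  is plumbing for small experiments and does not replicate CD-HIT-EST
  clustering.
* Published benchmark tables for the Rosaceae datasets are not reproduced
  here; they require the original FASTA benchmarks. Given those files, the
  `cv` command emits the same metric set for direct comparison.
* Training is CPU-only NumPy; it is comfortable at benchmark scale
  (thousands of windows) but not intended for genome-scale scans.
* The heat-map rendering is qualitative; no attempt is made to match any
  particular published color scaling.
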