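# Methods

## The model

`plinet` predicts protein–ligand interactions from sequence alone. A
protein is represented as a one-hot matrix over the 20 standard amino
acids, padded or N-terminally truncated to a fixed length (default
20 × 1200); a ligand SMILES string is tokenized over a pinned 64-symbol
vocabulary and encoded as 64 × 200. Two parallel convolutional extractors
process the matrices: block 1 is VGG-style (two width-3 convolutions +
width-2/stride-2 max pooling), blocks 2–3 are inception-style (parallel
width-1/3/5 convolutions and a width-3 same-length max-pool branch,
channel-concatenated), each followed by the same pooling. Convolutions are
1-D along the sequence axis with vocabulary rows as input channels — the
1×1/3×3/5×5 notation of image inception blocks maps to kernel widths here.
The flattened feature map of each molecule is projected by a dense layer to
a fixed embedding (default 1024), the two embeddings are concatenated, and
shared dense layers (512 then 64 units, ReLU, each followed by a
multi-dropout layer) feed two task-specific heads:

* **classification** — sigmoid output, binding probability, trained with
  mean binary cross-entropy
  `L1 = -(1/N) Σ [y log f(x) + (1-y) log(1-f(x))]`;
* **regression** — linear output, binding affinity on the pK scale
  (pK = −log10 of a dissociation/inhibition constant in molar units),
  trained with `L2 = (1/M) Σ (g(x) − value)² + λ‖w‖²`.

The L2-regularized weight set `w` is the regression head's dense weights
(biases excluded); λ defaults to 1e-4. The scope of `w` is a design choice:
the penalty is attached to the regression objective, so only that head's
weights enter it.

**Multi-dropout.** Each dropout layer holds 5 units whose rates are drawn
once at model construction, uniformly from a configurable range; each unit
applies an independent inverted-scaling mask and the layer output is the
(uniformly) weighted mean of the unit outputs, which is unbiased in
expectation and the identity at inference. Whether such units should be
*learned* is left open deliberately; the rates and weights are fixed,
documented configuration.

**Ensemble head.** Each head emits 5 values in its last dense layer,
combined by an unweighted mean — the variance-reducing default for an
otherwise unspecified combination rule.

The network is implemented directly in NumPy (im2col convolutions,
hand-coded backward passes). The backward pass is verified against central
finite differences in the test suite, end to end through both task losses.

## Training

Weights use Glorot uniform initialization (uniform on
±√(6/(fan_in+fan_out)), biases zero; conv fans include the kernel width).
The optimizer is Adam with lr 1e-4, β = (0.9, 0.999), ε = 1e-8 and batch
size 128 by default. Early stopping monitors the plain validation loss
(BCE / MSE without the regularizer, dropout disabled) and the returned
parameters are the best-epoch snapshot.

Multi-task training alternates one batch per task — classification first,
an arbitrary but fixed order for reproducibility. A step updates the shared
layers plus only the active task's head: gradients exist only for
parameters the backward pass reached, and Adam keeps per-parameter step
counters so untouched parameters (moments included) are bit-identical
before and after the step. When the two streams have unequal sizes, an
epoch ends when the larger stream is exhausted and the smaller recycles,
reshuffled. Each task records its own best validation epoch and parameter
snapshot, so the final classification and regression models may come from
different epochs.

## Dataset unification and leakage-safe splitting

Interaction manifests (protein id, ligand id, dataset, task, label) unify
classification and regression records. Affinities binarize at pK > 6
(IC50 = 1 µM; the tie at exactly 6 is negative — a documented strictness
choice); transformed kinase-bioactivity scores take their own threshold
(e.g. 12.1). A floor-value filter removes regression records piled at an
assay floor. Class balance is enforced by downsampling negatives only,
never touching positives, per dataset, seeded.

Targets are clustered by Needleman–Wunsch global identity (match +1,
mismatch 0, linear gap −1 by default; the substitution scheme is
configurable because no canonical one is imposed). Identity is
matches / alignment length (gaps included) — the most conservative
denominator for leakage control. DP ties break diagonal > up > left so the
reported identity is deterministic. Pairs with identity strictly above the
threshold (80% default; "greater than" is taken literally, so an exact tie
is no edge) join single-linkage clusters, and whole clusters are assigned
to folds greedily by interaction weight. No protein can appear in two
folds; a degenerate corollary is that a pair with exactly 0% identity
never merges at threshold 0.

## Occlusion

For a sample with real binding value `v`, unmasked prediction `p` and
prediction `p_j` after zeroing a window of 15 residues (stride 1) from the
protein matrix, the importance of window `j` is

    K_j = |p_j − v| / (|p − v| + ε),       ε = 1e-6.

K > 1 flags a region whose removal hurts the prediction, K ≈ 1 an inert
region, K < 1 candidate noise. The mask value is the all-zero column —
identical to padding and to the unknown-token policy, the canonical
occlusion choice. Window K values aggregate to a per-residue track either
by window center (default) or by the mean over covering windows; CNN
pooling gives local translation invariance, so the signal can shift by a
few residues, and the evaluation offers an optional truth-interval dilation
to tolerate ±window/2 shifts. Site calls threshold the track at the Kr-th
percentile of its own values (Kr ∈ [0, 100]; the percentile reading of the
Kr → K_threshold mapping is an interpretation, stated as such), and
maximal runs become 0-based half-open intervals. Evaluation is
residue-level precision/recall averaged over samples, against a
random-guess baseline equal to the truth-residue fraction; the per-track
area under the precision-recall curve (AUPRC) summarizes ranking quality.

All intervals — truth files, predicted sites, reports — use the BED
convention: 0-based, half-open.

## The synthetic world

The simulator emulates the *structure* of heterogeneous interaction data,
not its chemistry or homology:

* proteins: i.i.d. uniform amino-acid strings (default 80 proteins,
  100–160 residues) with 1–3 of three 8-residue motifs planted at recorded
  non-overlapping positions;
* ligands: random strings over a background subset of the SMILES
  vocabulary (default 120 ligands, 20–50 tokens), each of three designated
  pharmacophore tokens inserted independently with probability 2/3. They
  are vocabulary-valid token strings, not chemically valid molecules — the
  learning machinery needs token statistics, not chemistry;
* affinity: `pK = 4 + 1.5 × (matched motif–pharmacophore pairs) + N(0, 0.5)`.
  The bonus of 1.5 pK units (3 noise SDs) with base 4 yields both classes
  under the pK > 6 threshold with realistic overlap;
* recipes: a near-normal regression set (skewness ≈ 0.1 at n = 5000), a
  skewed regression set floor-censored at pK 5 (mimicking the assay-floor
  pile-up of kinase panels), and classification sets at 1:1 and 3:1
  negative:positive ratios filled by stratified pair sampling so the ratio
  is exact up to rounding.

Everything derives from a single integer seed through NumPy's Generator;
two runs with the same seed are identical.

What passing tests on this world do **not** show: performance on real
benchmark data. Real datasets have homologous target families, correlated
chemistry, label noise structure and scale (hundreds of thousands of
interactions) that the simulator does not emulate. The synthetic study
validates the *machinery* — that the pipeline is leakage-free, the
optimization works, the occlusion statistic recovers genuinely causal
subsequences — not benchmark-level accuracy.

## The desk-scale study

`plinet.pipeline.planted_motif_study` runs the whole method at sizes chosen
to finish in minutes on one CPU: the default world above (~9,000
interactions), a narrow model of the same architectural shape
(12/16/16 channels, 64-dim embeddings, 64/32 dense units, dropout rates
drawn from [0.05, 0.25]), lr 1e-3, batch 128, ≤ 20 epochs with patience 5.
Three target-clustered folds are built; two train, one is held out, and
validation proteins are carved out of the training folds so early stopping
never sees test targets. Occlusion runs on up to 20 held-out proteins, each
paired with a ligand that actually matches at least one of its planted
motifs, and the K track is scored against the intervals of the *matched*
motifs (an unmatched motif is not a binding site for that ligand). The
smaller learning-rate/width choices relative to the full-scale defaults
reflect the narrow model, and the gentler dropout range reflects its much
smaller capacity.

## Numerical choices

* BCE probabilities clamp at ε = 1e-7.
* Classification gradients use the combined sigmoid-plus-BCE form
  `(p − y)/N` for stability.
* Pearson's R uses the standard symmetric formula; the regression SD is the
  residual SD of the least-squares fit of true values on predictions
  (CASF convention) with an N−1 denominator, so an affine shift of the
  predictions gives SD = 0.
* AUC is computed by tie-aware midranks, which equals the trapezoidal area
  over score-ranked thresholds exactly; metrics with empty denominators
  (single-class AUC, zero-variance R, empty-margin MCC/precision) are NaN
  with a warning, never an exception.
* The decision threshold for confusion-based metrics is 0.5 (strictly
  above), configurable.
* Balanced accuracy is (recall + specificity)/2, a reconstruction.
* Checkpoints are JSON with full-precision floats plus SHA-256 hashes of
  the vocabularies, so loading against a different vocabulary fails loudly.

## Known limitations

* The 64-token SMILES vocabulary is a pinned reconstruction (organic-subset
  atoms, aromatic forms, two-character halogens, digits, branch/ring/bond
  and bracket symbols, spare letters for bracket-atom contents); no
  canonical inventory exists for the 64-symbol convention.
* Unknown tokens map to all-zero columns, preserving matrix shapes but
  conflating them with padding and with occlusion masks.
* The NumPy engine is single-threaded and desk-scale; it is not a path to
  training on hundreds of thousands of interactions.
* Occlusion is protein-side only; a ligand-side analog is future work.
* The simulator's affinity rule is additive and noise is homoscedastic;
  negative transfer between genuinely dissimilar datasets can only be
  studied qualitatively at this scale.
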