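# Methods

## The pipeline in one paragraph

passforge implements profile-augmentation pseudo-labelling for
three-class protein secondary structure. A profile-based teacher
predicts H/E/C labels for the representative sequence of each
unlabelled cluster; the representative plus those pseudo-labels —
never the alignment — becomes one training example for a
single-sequence student. Clusters are filtered, screened against the
validation and test sets for homology, and purged by family
annotation before any pseudo-label is emitted. The student is
pretrained on the pseudo-labelled pool and fine-tuned on the small
labelled set; a labelled validation set steers early stopping in both
phases, and the labelled test set is touched only by the evaluator.

## Synthetic universe

The generator reproduces the statistical situation the method
assumes, not protein biophysics.

**Structure.** Each family's ground-truth label string is a
first-order Markov chain over H/E/C with self-transitions 0.90 (H),
0.90 (E) and 0.85 (C), giving mean segment lengths of ~10, ~10 and ~7
residues; the first state is drawn from the chain's stationary
distribution. Lengths are uniform on 40–80 residues.

**Residues.** Class-conditional emission rows are
`(1 − d)·uniform + d·uniform-over-a-preferred-set` with preferred sets
of 8 (H), 7 (E) and 5 (C) residues chosen to echo real helix, strand
and coil propensities, at separation `d = 0.6`. The rows overlap by
construction: the single-position Bayes rate is around 0.6 (context
raises the practical ceiling into the mid-80s), while an alignment
column of ten or more draws identifies its class almost surely. That
is the profile-beats-single-sequence gap the teacher–student transfer
needs, and `d` is the one dial that controls it.

**Homology.** Members of a family conserve the founder's structure
exactly and mutate each residue independently with probability 0.3,
the replacement drawn from the position's emission row. Expected
within-family identity is `1 − 0.3·(1 − p_same) ≈ 72%` (with
`p_same` the emission-row collision probability); cross-family
identity sits at the background collision rate, ~8%. Indels are not
generated, so alignment coordinates stay trivial; the A3M reader
still handles insertion states for external inputs. Cluster depth is
geometric with mean 18 (minimum 1), so a realistic fraction of
clusters fails the ≥10-non-redundant-members filter.

**Splits and sizes.** Defaults: 16 labelled training families, 12
validation, 12 test, 220 unlabelled clusters. The small labelled set
against the ~120 surviving pseudo-labelled examples (~1:8) mirrors
the labelled-scarce regime the method is for; with a labelled set
comparable in size to the pseudo pool the supervised baseline
saturates and the semi-supervised gap closes, which is the expected
behaviour, not a failure. Labelled train and validation families are
additionally emitted as alignments: the train clusters are the
teacher's training input, and the validation clusters let the teacher
be scored on the same families where the student is scored from
single sequences. A `leak_fraction` (default 0.1) of unlabelled
families are bait — true homologues of test founders mutated at rate
0.25 (~77% identity) that inherit the source family's annotation —
planted solely to measure screen recall.

**Seeding.** One global seed feeds a splittable hierarchy keyed by
(split, family index), so enlarging one split never reshuffles
another, and serialized universes are byte-identical across reruns.

**What the generator does not emulate:** indel evolution, realistic
phylogenies (members are independent mutants of the founder, not a
tree), structure-dependent substitution matrices, length/composition
biases of real chains, and unlabelled-residue noise. Passing tests
therefore demonstrate the pipeline's mechanics — label transfer,
leakage control, the ordering of training schemes — not real-protein
accuracy levels.

## Teacher

Per-cluster profiles are column-wise residue frequencies over the 21
symbols with Laplace pseudocount α = 1/21 (small enough not to blur
low-depth columns, nonzero so depth-1 rows are proper
distributions); gaps contribute nothing and the representative is
included in the counts (a flag excludes it for ablation). The teacher
is a multinomial logistic regression (scikit-learn, lbfgs,
deterministic for fixed seed) on windowed profile features: the 21
frequencies at each of 15 consecutive positions centred on the
target, plus a per-offset out-of-range indicator, 330 features in
all. It is trained only on labelled-training families, so
pseudo-labels can contain no validation or test information. Window
15 and inverse-regularization C = 1 are defaults surfaced in the API.

## Dataset construction and leakage screens

Pipeline order: filter → test screen (aggressive) → validation screen
→ annotation purge → pseudo-label. Every cluster appears exactly once
in the manifest with its fate, and the attrition report must conserve
counts.

* **Filter.** Representative shorter than 20 residues, or fewer than
  10 non-redundant members (unique strings after gap removal and
  uppercasing), strictly less-than on both boundaries.
* **Stage 1 (both screens).** For each member–reference pair, shared
  4-mers anchor ungapped diagonals; the best identity over diagonals
  with ≥20 residues of overlap is compared to a threshold: 0.45 for
  the test screen (aggressive sweep — recall over precision) and 0.55
  for the validation screen (the validation set only steers early
  stopping, so a default-stringency pass suffices). The asymmetry is
  enforced by the config type, and on a fixed reference set the test
  flags provably contain the validation flags. With background
  identity ~8% and bait identity ~77%, 0.45 sits several standard
  deviations above chance while far below any true homologue.
* **Stage 2 (test screen only).** Cluster profiles are scanned
  against complexity-masked test sequences by a gapless local
  alignment: cell score `log(p_col(aa)/0.05)`, best contiguous
  segment over any diagonal, threshold 25 log-odds units. Gapless is
  exact for this universe (no indels) and is the natural analogue of
  an HMM-vs-sequence search at desk scale.
* **Masking.** A residue is masked when the Shannon entropy of
  residue counts in an 11-residue window drops below 2.0 bits —
  windowed-entropy masking of low-complexity sequence, preventing
  compositionally biased regions from seeding spurious hits.
* **Annotation purge.** Clusters whose family annotation matches any
  test-set annotation are removed; unannotated clusters and
  references contribute nothing. This catches homologues the
  sequence-level screens miss.

Pseudo-labels are stored as hard classes; per-residue teacher
probabilities can optionally be retained for soft-label experiments
but are unused by default. E-values are not computed anywhere —
identity and score thresholds with the aggressive/default asymmetry
are the stand-ins.

## Student

A learned 21×E embedding feeds `num_layers` bidirectional GRU layers
(hidden size H per direction, outputs concatenated) and a linear
projection to three logits per residue; masked cross-entropy ignores
positions labelled `.`. Regularization is AWD-style: embedding-row
dropout, DropConnect on the recurrent matrices (rescaled, resampled
per batch), and time-tied variational dropout between layers. Adam
with global-norm gradient clipping at 5.0; early stopping restores
the best-validation checkpoint.

The implementation is plain numpy with hand-derived gradients,
verified against finite differences in the test suite. Padding
freezes the hidden state, so batched and single-sequence predictions
are bitwise identical, and a fixed seed reproduces training exactly
on a single CPU.

Spec-scale defaults are embed 128, hidden 64, two layers; the
packaged end-to-end runs use a `tiny` configuration (embed 32, hidden
32, one layer, ≤30 epochs, patience 4) sized so a full three-scheme
comparison completes in seconds while preserving the mechanism under
study. Class weighting is available but off by default — strand is
the weakest class and is reported, not corrected.

Scheme details: `pretrain_finetune` restores the best-validation
pretrain checkpoint (not the final epoch) before fine-tuning at the
reduced rate, fine-tunes the whole model (no frozen layers), and
treats the restored checkpoint as the epoch-0 early-stopping
candidate, so fine-tuning can never end below the pretrained model
on validation. Argmax ties break toward C, then H, then E,
everywhere.

## Evaluation

Q3 is emitted both residue-pooled (trace of the H/E/C confusion
matrix over its total — an exact identity asserted in tests) and as
the mean of per-sequence scores; the per-sequence mean is the
headline, matching per-chain benchmark framing. Per-class
precision/recall/F1 are pooled over residues, with supports
normalized to sum to 100 for readability. Prediction entropy is
`−Σ p ln p` per residue in nats (maximum ln 3 ≈ 1.099), averaged
within a sequence and then across sequences; the
per-residue-then-per-sequence reading is one of two defensible
interpretations of "averaged across classes, residues and sequences"
and is fixed here. Histogram bins are left-closed right-open with a
closed final bin so a perfect score is counted.

## Data efficiency

Supervised accuracy is fitted as `q3 = a·log10(n) + b` by ordinary
least squares over mean scores per subset size. Subsets are
family-coherent and nested across sizes for a fixed seed (whole
families in or out — no within-family leakage along the curve). The
effective-dataset multiplier inverts the fitted line at the
semi-supervised score: `10^((q3_ssl − b)/a) / n_actual`; the same
inversion, flagged as extrapolation beyond observed scores, yields
the size required to hit a target Q3, and a plain multiplication
utility converts cluster counts to raw-sequence estimates given a
user-supplied mean cluster depth. The log-linear parameterization is
used for both directions (fitting Q3 against log n and inverting is
equivalent to an exponential fit of n against Q3). The learning-curve
experiment runs on a universe with 64 labelled families (sizes 12,
24, 48) because a curve needs a size range to sweep; the
semi-supervised model whose multiplier is read off is trained under
the default 16-family labelled budget on that same universe.
Training on ~12 examples occasionally fails to leave the initial
regime — a real small-data effect that the multiple-seed averaging
absorbs.

## Problem sizes and numerical choices

Packaged experiment sizes — 220-cluster universes, three seeds for
the scheme comparison, two to three seeds and three subset sizes for
the learning curve — are chosen so the full test suite and the
acceptance script each complete in a couple of minutes on one CPU
while every qualitative effect (teacher advantage, semi-supervised
ordering, screen recall/false-positive separation, rising learning
curve) is comfortably resolved. Stochastic-matrix rows are validated
to 1e-9; probability outputs to 1e-6; degenerate cases are defined
rather than erroneous (all-gap profile columns become uniform rows
and are flagged; windows longer than the sequence fall back to
whole-sequence statistics; zero evaluable residues yield NaN rather
than 0).

## Known limitations

The teacher is a windowed linear model, not a neural profile
predictor; it suffices to create the teacher–student gap but
understates what a stronger teacher would transfer. The universe's
emission model makes profile columns close to sufficient statistics,
so teacher accuracy here is optimistic relative to real alignments of
diverged homologues. Absolute Q3 values depend entirely on generator
settings and are not comparable to benchmark figures on real
proteins; only orderings and gaps are meaningful. The screens are
identity/score based and would need E-value calibration for real
databases.
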