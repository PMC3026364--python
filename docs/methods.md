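# Methods

## Problem setting and data model

A SIDD profile assigns each base pair of a single replicon a destabilization
free energy *G(x)* (kcal/mol): the incremental free energy required for the
base pair at *x* to remain permanently open under superhelical stress. Low
values mark easily destabilized DNA. Averaged over many experimentally
verified transcription start sites, bacterial profiles show a well: lowest
energies near the TSS, rising with distance, more steeply downstream than
upstream. `siddprom` treats promoter prediction as binary classification of
fixed 250-bp windows spanning relative positions −200..+50 around a
candidate TSS, with no position 0; relative +1 is the TSS base itself.

Coordinates are 1-based inclusive externally (GenBank/RegulonDB style) and
0-based internally; the conversion lives entirely in `sidd_io`. Windows are
always read along the direction of transcription — on the reverse strand
"upstream" means higher genome coordinates — because the downstream/upstream
asymmetry of the well is only learnable when all windows share one
orientation. Profiles are single-replicon and either linear or circular;
circular windows wrap modulo the genome length, while on linear profiles a
TSS whose window would run off an end is dropped with a logged warning
rather than padded (padding would invent energies).

## Dataset construction

Positive instances are one window per unique TSS (duplicate
(position, strand) pairs collapse to the earliest record). Negative
instances are randomly selected 250-bp regions constrained to keep their
distance from TSSs: a candidate window is rejected if **any** of its 250
positions lies within `exclusion_radius` bp of any TSS base, with distance
measured on the genome and respecting circularity. Two radii are
conventional: 250 bp for evaluating the threshold method, and 50 bp for the
network, which benefits from training on near-promoter negatives. Start
positions are drawn uniformly **without replacement** from the eligible
pool (overlap among negative windows is allowed — forbidding it could
exhaust small genomes), and each negative gets a random strand, since a
background region has no transcription direction. Negatives outnumber
positives `neg_pos_ratio`:1 (default 3:1).

The train/test split is 2/3–1/3, stratified by label with floor rounding on
the training side; stratification stabilizes precision-recall estimates at
small problem sizes and cannot hurt comparability. All sampling and
splitting is a pure function of the configured integer seed (distinct
seeded substreams for negative sampling and splitting).

## The sumG threshold classifier

`sumG` is the unweighted sum of a window's 250 energies; a window is tagged
*promoter* when `sumG ≤ T`, boundary inclusive. The sweep takes as
candidate thresholds exactly the distinct observed sumG values plus one
sentinel below the minimum. This grid yields *every* achievable operating
point of the rule, so the traced curve is the complete PRC. Since raising
*T* can only grow the predicted-positive set, recall is non-decreasing in
*T*; the sweep asserts this invariant on every run. Points with zero
predicted positives carry an explicit undefined-precision flag rather than
a substituted 0 or 1 — either substitution would bias the curve.

## The cost-sensitive 250-2-1 network

Architecture is fixed: 250 inputs (the window energies), 2 sigmoid hidden
units, 1 sigmoid output; the class decision is `score > 0.5`. Inputs are
standardized per relative position using training-set mean and standard
deviation (sd floored at 1e−8), because raw kcal/mol magnitudes saturate
sigmoids.

Cost sensitivity: a cost matrix over (TP, TN, FP, FN) maps to per-class
example weights — positives weigh `cost_fn − cost_tp`, negatives
`cost_fp − cost_tn` — in a weighted cross-entropy loss. For a fixed set of
decisions the expected cost equals this weighted error up to an additive
constant, so minimizing one minimizes the other. Weights are normalized to
unit mean so the effective learning rate is independent of the costs'
overall scale (scaling all costs by a constant provably leaves the
optimization unchanged, and a test asserts bit-identical models).

Training is seeded mini-batch gradient descent with momentum. Defaults:
learning rate 0.1, momentum 0.9, batch size 32, at most 500 epochs,
weights initialized uniformly in [−0.5, 0.5] (biases zero), a stratified
15 % validation holdout monitored every epoch, early stopping after 25
epochs without improvement, and restoration of the best-validation-epoch
weights. Classes with fewer than 4 members cannot be held out; the training
subset then doubles as the validation monitor. Everything is a pure
function of (data, costs, seed); two runs with the same seed produce
bit-identical weight trajectories. On the synthetic benchmarks below the
trained network's F-scores match scikit-learn's logistic regression
baseline on identical data, confirming the optimizer extracts what is
linearly extractable.

The network's PRC is traced by training one model per cost setting
(default grid: `cost_tp = cost_tn = 0`, `cost_fp = 1`,
`cost_fn ∈ {0.25, 0.5, 1, 2, 3, 4, 6, 8}`) and plotting each model's
test-set precision/recall at the fixed 0.5 cutoff. Unlike a threshold
sweep, nothing guarantees monotone or evenly spaced recalls — cost settings
land where they land. Per-model initialization seeds derive
deterministically from (trace seed, grid index). Cutoff sweeping exists in
the API (`MlpModel.decision_cutoff`) but is an auxiliary mode, not how the
curve is defined.

## Evaluation

Precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F-score `2PR/(P+R)`. The
F-score helper is scale-equivariant (percent inputs give percent output)
and curve points carry F on the 0–100 scale, reported to one decimal.
Undefined quantities (zero denominators) are `None`, never substituted.
Maximal-F selection breaks ties toward higher recall, then higher
precision.

## The decision-tree combiner

To test whether the two classifiers are complementary, a small binary tree
is grown over four per-instance features — network score, sumG value, and
both hard labels — by greedy information gain: split candidates are
midpoints of consecutive distinct sorted feature values; growth stops on
purity, zero gain, or a child below `min_leaf` (default 2); no
post-pruning; ties in gain break toward the first feature in the listed
order, then the smaller threshold; routing is `feature ≤ threshold → left`;
leaf labels are majority votes with ties resolved to non-promoter. Full
C4.5 fidelity (gain ratio, error-based pruning) is deliberately out of
proportion for a complementarity probe. When the two base classifiers
predict identically on every instance the tree has nothing to add and its
F-score equals the base F-score exactly.

## Synthetic data generator

The generator emulates the statistical structure the classifiers exploit,
not the thermodynamics that produces it (no sequence is simulated):

* **Background** — Gaussian white noise smoothed by a `smoothing_bp`-wide
  moving average (default 25 bp, a realistic correlation length for
  destabilization energy along DNA), rescaled to mean 10.0 and sd 1.5
  kcal/mol.
* **Promoter wells** — at each planted TSS, energy is reduced by
  `well_depth · exp(−d/decay)` with `well_depth` 6.0 kcal/mol, upstream
  decay 180 bp and downstream decay 90 bp (evaluated over ±500 bp and
  truncated beyond), reproducing the qualitative averaged-profile shape:
  minimum at the TSS, gradual rise, steeper downstream.
* **`pattern_only` mode** — the well shape is restricted to the −200..+50
  window and re-centred to sum to zero there, so promoter windows keep the
  positional shape while their expected sumG equals the background's. This
  is the controlled condition for the claim that a network can exploit
  positional patterns a summed-energy threshold cannot see.

TSS positions are placed uniformly at random (rejection sampling) with a
configurable minimum spacing, random strands, and — on linear genomes — a
501-bp margin at both ends so every ±500 bp neighbourhood fits. The whole
generator is deterministic given its config.

What the generator does **not** emulate: sequence-dependent energy
structure (AT-rich tails, terminators and replication origins also
destabilize), long-range correlation beyond the smoothing length, and the
heavy left tail of real SIDD energy distributions. Passing tests therefore
demonstrate correctness of the pipeline and the *mechanistic* contrast
between the classifiers, not field performance on a real genome.

## Benchmark conditions and what they show

The controlled comparison runs both classifiers on one shared dataset and
split (the network's 50-bp exclusion radius), because a method contrast is
only interpretable on identical data. Problem sizes:

* **Pattern-only experiment** — 50-kb genome, 200 promoters (a dense,
  promoter-rich replicon), zero-sum wells, 10 seeded replicates. The
  network's maximal F exceeds sumG's in 10/10 replicates (≈ 70 vs ≈ 43;
  sumG hovers near the 25 %-positive base-rate F of 40, as it must when
  sums carry no signal).
* **Sum-separable control** — 100-kb genome, 200 promoters, full-depth
  wells, negatives at the threshold method's 250-bp radius so they stay
  clear of well tails. Both methods reach F ≈ 100 and agree within a
  fraction of a point.
* **Published-scale geometry** — the acceptance script rebuilds the dataset
  rules on a 4.64-Mb circular synthetic genome with 1648 promoters,
  recovering 4944 negatives and a 1098/550 positive split by computation.

## Numerical choices and degenerate inputs

Sigmoids via `scipy.special.expit`; probabilities clipped at 1e−12 in the
loss; training aborts on non-finite loss. Threshold classification is
boundary-inclusive by definition. Dataset TSVs store energies with 12
significant digits (round trips agree within 1e−9); model files use 17
significant digits (exact float64 round trip). Empty TSS lists,
single-class training sets, exhausted negative pools and windows leaving a
linear profile all raise typed errors rather than degrading silently. One
global pipeline seed derives per-stage seeds by SHA-256 hashing of the
stage name, keeping stages statistically independent under one
reproducibility knob.

## Known limitations

Real SIDD tracks and curated TSS compilations are consumed as
bedGraph/wiggle + TSV inputs but none are bundled; conclusions about real
genomes require supplying them. The network is intentionally tiny (two
hidden units) and the tree un-pruned; neither is meant as a
state-of-the-art predictor, but as a faithful, reproducible implementation
of the two methods under comparison. Negative sampling is genome-uniform
and annotation-blind (no operon or gene-context awareness).
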