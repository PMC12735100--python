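# Methods

## The model

MACNeXt is a compact ConvNeXt-style CNN for colony-image classification.
Its distinctive elements are (i) a dual-activation residual block that runs
GELU and ReLU branches in parallel and sums them, covering smooth and
sparse activation regimes; (ii) an inverted bottleneck formed by
concatenating parallel grouped 3×3 and 1×1 convolution paths to twice the
stage width before squeezing back; and (iii) a reduced normalization count
relative to conventional designs (four BN layers per block). Stages of
widths F = [96, 192, 384, 768] with repeats R = [1, 1, 3, 1] are separated
by grouped stride-2 downsampling layers; a two-convolution stem quarters
the input resolution; the head is GAP → FC → softmax.

All computation is NumPy: convolutions are evaluated by im2col plus one
batched GEMM over channel groups, and every layer implements an explicit
backward pass (verified against finite differences in the unit suite).

## The grouped-convolution convention

The architecture description labels most convolutions "grouped" but never
states a group count; the only published constraint is the total budget of
4.4 million learnable parameters. The block description is also internally
ambiguous: the equation/pseudocode form marks the 1×1 expansion as grouped
and the 1×1 squeeze as plain, while the transition table renders the
mirror image (plain expansion, grouped squeeze).

We resolved both by calibration against the closed-form parameter count,
scanning a uniform channels-per-group constant over the divisors of the
first stem width (48) jointly with the two block readings:

* pseudocode reading (grouped expansion, plain squeeze): total =
  2,196,936 + 43,872·cpg, at most 4,302,792 (4.3 M) at cpg = 48 — the
  printed budget is unreachable;
* transition-table reading (plain expansion, grouped squeeze): total =
  4,353,480 + 41,664·cpg; cpg = 2 gives **4,436,808 → 4.4 M**. (cpg = 1
  would give 4,395,144 but is structurally invalid: a 2F→F squeeze with 2F
  groups cannot emit F outputs.)

cpg = 2 under the transition-table reading is therefore the unique uniform
divisor-valued convention that reproduces the printed budget, and it is
frozen as the default (`channels_per_group=2`, `expansion_grouped=False`,
`squeeze_grouped=True`). Both flags remain configurable, and the
closed-form/enumeration equality is property-tested across conventions.

## Other architectural choices

* **Bias policy.** No convolution carries a bias (each is immediately
  followed by BN, whose shift subsumes it); the FC layer has one. This
  enters both the closed-form count and the enumeration.
* **Padding.** Stride-1 3×3 convolutions are size preserving; stride-2
  convolutions follow the same/ceil convention (output side = ⌈side/2⌉,
  extra padding on the bottom/right when the total is odd). This is what
  reproduces 224 → 56 → 28 → 14 → 7 and defines behavior on odd sides
  (15 → 8).
* **Activations.** GELU uses the exact erf form, not the tanh
  approximation, so oracle comparisons are deterministic.
* **BN.** ε = 1e−5, running-statistics momentum 0.1, both configurable.
* **Initialization.** Fan-in-scaled normal for convolutions, fan-based
  uniform for the FC layer, all drawn from a single generator seeded by
  `init_seed`, so two builds from one seed are bit-identical.
* **Degenerate inputs.** Configurations whose spatial trace would collapse
  below 2 pixels before the final stage are rejected at validation, as are
  group conventions that do not divide a layer width.

## Training protocol

`TrainConfig` defaults mirror the reference protocol: a two-stage split
(80/20 test hold-out, then 80/20 validation within the training part,
i.e. 64% / 16% / 20%), SGDM (momentum 0.9) at a constant learning rate of
0.01, 30 epochs, batch size 128, cross-entropy loss. Momentum and weight
decay (1e−4) are unstated in the protocol and default to the conventions of
the MATLAB training environment it names. Splits are stratified per class
by default (floor rounding, remainder to train), protecting the
177-sample minority class; an unstratified flag exists. An optional
class-aware sampler (`balanced_batches`) composes near-uniform class mixes
per batch and is off by default. No data augmentation is applied.

After the final epoch the BN running statistics are replaced by population
statistics computed over the training set with frozen weights
(`recalibrate_batchnorm`). Mini-batch running averages lag the rapidly
moving weights on small datasets — we observed inference-mode accuracy
tens of points below batch-statistics accuracy without this step — and
population statistics are also the default behavior of the named training
environment. Per-epoch validation numbers in the log are computed with the
running (uncalibrated) statistics and are therefore conservative.

## The synthetic benchmark

The generator emulates the *structure* of the private 24-species
collection: exact per-class counts at scale 1.0 (total 18,221; max/min
ratio 2562/177), a class-per-folder PNG layout with a CSV manifest, and a
per-image seed derived stably from (global seed, class id, index) so
regeneration is byte-identical and adding classes never perturbs existing
images. Scaled counts use round-half-even with a configurable per-class
floor.

Each image is a red-brown agar disc under a random directional illumination
gradient and vignette, carrying a Gaussian-distributed number of colonies
with lobed borders (low-order harmonic perturbation), domed shading,
multiplicative surface grain, an optional hemolysis-like halo ring
(assigned to the beta-hemolytic species), and additive sensor noise. The
24 class specifications differ pairwise in at least two parameters (colors
are pairwise distinct; the radius/count combination cycles with coprime
periods), which the suite asserts.

What the generator does **not** emulate: real colony morphology, focus and
exposure variation, plate artifacts (streaks, confluent growth), or
inter-class visual similarity structure (real Staphylococcus/Streptococcus
confusions have no synthetic counterpart). Passing the learnability tests
therefore demonstrates that the pipeline can extract class signal and that
the machinery is correct — not that the architecture reaches any particular
accuracy on real clinical images.

## Benchmark sizes and fixed settings

The learnability benchmark trains the tiny preset (F = [16, 32],
R = [1, 1], 64×64 inputs, 4 classes × 200 images) with batch size 32 and
learning rate 0.02 for 30 epochs at fixed seed 3, reaching ≥ 95% held-out
accuracy (98.1% in the recorded run); these settings were fixed once after
the first implementation run and are not tuned per execution. The
overfit-one-batch diagnostic (200 SGDM steps on one 32-sample batch at
32×32) must reach 100% training accuracy. Problem sizes throughout the
suite (image sides 32–64, small stage widths) were chosen so the entire
pipeline is exercisable on one CPU core in minutes.

## Evaluation conventions

Confusion matrices are oriented rows = true, columns = predicted, and this
orientation is stated in serialized outputs. Per-class metrics are
one-vs-rest accuracy, precision, recall and F1; aggregates are overall
accuracy (trace/total) and **macro** (unweighted class-mean) precision,
recall and F1 — macro is chosen because the per-class analyses and the
class-balance framing of the protocol imply class-symmetric averaging.
Zero-denominator cases yield 0 and set a degeneracy flag instead of NaN.
The multiclass AUC is macro one-vs-rest with trapezoidal integration over
the unique-score threshold set (equivalent to the tie-corrected
Mann–Whitney statistic); classes without both positives and negatives are
excluded from the macro mean with a warning. All metrics are cross-checked
against scikit-learn and brute-force pair counting in the suite.

## Known limitations

* No GPU path and no data augmentation; the full-scale 18k-image,
  224×224, 30-epoch reference run is out of practical reach on one CPU,
  and the package makes no claim to reproduce the reference model's
  reported accuracies.
* The checkpoint format stores raw arrays keyed by layer name; it is
  stable within a package version but not a cross-framework interchange
  format.
* BN recalibration uses the simple average of per-batch moments, which
  assumes roughly equal batch sizes (the last partial batch is slightly
  over-weighted).
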