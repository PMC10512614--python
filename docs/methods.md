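# Methods

`oostage` implements a two-stage pipeline for staging the meiotic maturity of
human oocytes from single-cell micrographs, together with the machinery used
to design and validate it: a synthetic phantom generator, stratified
repeated random subsampling (SRRS) evaluation, a per-class
quality-coefficient suite, analytic FLOPs accounting, and a genetic
algorithm that refines the classifier's filter counts.  This note records
the model, the choices that were genuinely open, and what the phantom
experiments do and do not demonstrate.

## The staging problem

An oocyte is assigned to one of three maturity classes.  Two subcellular
structures carry essentially all of the discriminative signal:

* **PI** (prophase I, immature): a **germinal vesicle** (GV) is visible
  inside the cytoplasm;
* **MII** (metaphase II, fertilizable): a **first polar body** (FPB) —
  possibly fragmented (FFPB) — sits in the perivitelline space; no GV;
* **MI** (metaphase I): neither structure is present.

The pipeline therefore (1) segments GV and FPB(+FFPB) pixels from the
grayscale image and (2) classifies the oocyte from a 2-channel tensor of
those region masks.  Stage 2 can also be driven by expert ("manual") masks,
which provides the reference against which the automatic masks are judged.

## Stage 1 — segmentation

A compact encoder–decoder with skip connections (two 2× pooling levels,
3×3 convolutions, nearest-neighbor upsampling; `base_filters` controls
width) predicts per-pixel labels in {background, GV, FPB}.  Inputs are
single-oocyte crops, bilinearly resized to a square (512 px canonically;
the desk-scale experiments use 64 px) and replicated to three channels.
Training minimizes per-pixel cross-entropy with Adam, augmenting with
random rotation (uniform in [0, 360)) and multiplicative brightness jitter.

Two numerical choices matter:

* **Class weighting.** GV and FPB together cover ~2 % of pixels.  The
  unweighted loss collapses to all-background and never recovers within a
  desk-scale budget, while full inverse-frequency weighting floods the rare
  classes with false positives.  The default is tempered median-frequency
  balancing, `w_c ∝ (median(f)/f_c)^0.75`, which trains reliably; the
  weighting can be disabled (`class_weighting=False`).
* **Mask cleanup.** Model selection treats a region as *detected* only when
  ≥ 100 of its ground-truth pixels are predicted correctly; consistent with
  that criterion, `predict_masks` removes connected components smaller than
  100 px by default (sub-detectable specks are overwhelmingly noise, and
  the downstream classifier — trained on clean masks — is sensitive to
  them).  `min_region_px=0` returns the raw argmax.

Per-epoch snapshots record the validation **detection ratio** (DR: detected
regions / ground-truth regions) and mean IoU; the selected snapshot
maximizes DR, then IoU, earliest epoch on ties.

## Stage 2 — classification

The classifier is a SqueezeNet-style network whose tunable part is a
6-gene *chromosome* of per-layer filter counts (conv1, conv2, fire-squeeze,
fire 3×3 branch, fire 1×1 branch, conv6/7), each even and in [2, 128]:

    conv3×3/s2 → relu → maxpool3×3/s2 → conv1×1 → relu → maxpool3×3/s2
    → n × [squeeze1×1 → relu → (3×3 pad 1 ‖ 1×1) → relu → concat → maxpool]
    → conv1×1 → relu → conv1×1 → relu → GAP → fc(3) → softmax

All pooling uses floor-mode output sizes, and the fire 3×3 branch is padded
so the two branches concatenate (the equal-spatial requirement fixes both
choices).  An optional dropout (0.5) before conv6 is off by default.
Inputs are H×W×N tensors of canonical channels (the image plane scaled to
[0, 1]; mask planes binary); oversized records are nearest-neighbor
downscaled to ≤ 550 px, undersized ones symmetrically zero-padded.
Augmentation expands each base tensor into a deterministic rotation grid
(angle 360/n_rot·(i−1)) crossed with random integer shifts realised by
placing the base frame into a larger zero-filled output (550→590 px
canonically; 128→136 px at desk scale), cached on disk or in memory.

Training uses cross-entropy + Adam on class-balanced batches
(batch_size/3 per class, sampled with replacement for rare classes,
redrawn from a fresh deterministic seed each epoch).  Snapshot selection
maximizes plain validation accuracy (fraction of correctly staged
validation oocytes, chance level 1/3); the quality-coefficient suite below
is computed for reporting.  Two robustness details: convolution biases are
initialised at 0.01 (exactly-zero activations on sparse binary inputs
otherwise cut all ReLU gradients in a path and can freeze a class), and the
desk-scale default chromosome is (16, 16, 8, 16, 16, 8) — at half that
width the sparse GV plane is intermittently ignored by an unlucky
initialisation.

The networks are executed by a small in-package NumPy graph engine
(im2col convolutions, hand-written backward passes, Adam); at these sizes
it trains both stages in minutes on one CPU and keeps runs bit-reproducible.

## Quality coefficients

Evaluation decomposes the 3-class problem one-vs-rest into per-class
Tp/Fp/Fn/Tn tallies per SRRS repetition, from which per-class ACC, TPR,
PPV, FDR and f1 are computed; each coefficient is averaged first across
classes within a repetition, then across repetitions (unweighted means).
Per-class ACC defaults to (Tp+Tn)/(Tp+Tn+Fp+Fn); a literal Tp/(Tp+Tn)
variant is selectable (`acc_convention="as-printed"`) for auditing but is
not self-consistent with the rest of the suite.  f1 is the harmonic mean of
PPV and TPR.  Degenerate denominators yield 0 and set a `degenerate` flag.
IoU of two empty masks is defined as 1, so MI oocytes (empty GV and FPB
targets) score vacuous agreement rather than being skipped.

## SRRS

Splits fix per-class validation and test counts (the canonical plan:
5/5/5 validation and 9/58/24 test over a 44/663/59 dataset, leaving
30/600/30 for training) and repeat the draw 3 times by default (10 for
confirmation runs).  Validation/test sets are frozen per repetition; every
record appears in exactly one part.  All draws derive from logged seeds.

## GA refinement

The GA minimizes `OF = 1 − Acc̄ + ΣF_k / F_max` with `F_max = 128·6 = 768`,
so OF ∈ [12/768, 2] for legal chromosomes.  Evolution is generational with
a single elite copied unchanged (with its recorded score — a noisy
evaluator is not re-evaluated, which preserves the monotone
generation-best contract), size-2 tournament selection, uniform per-gene
crossover (rate 0.7) and per-gene ±2k mutation with k ≤ 8 (rate 0.4),
clipped to the even grid.  Evaluations are cached by chromosome.  By
default an individual is scored on one SRRS split; the winner is meant to
be confirmed over the full plan.

## FLOPs

`count_flops` sums, over convolution and fully connected layers, output
elements × kernel area × input channels multiply-accumulates (MAC = 1 by
default; MAC = 2 counts multiply and add separately).  For the reference
chromosome (32, 16, 8, 28, 28, 4) with a 590×590×2 input this gives
73.3e6 MACs (146.5e6 at MAC = 2), and the count is strictly monotone in
every filter count, the input side, and the number of inception blocks.

## The phantom generator

Phantoms emulate the study conditions, not microscopy: concentric ellipses
(cytoplasm inside a PVS gap inside a bright ZP shell, optional cumulus
debris), with a GV disc (≈ 11 % of cytoplasm area) only in PI and an FPB
disc (≈ 12 %) only in MII, fragmented into 2–4 discs with probability 0.2
(a prevalence consistent with clinical reports of polar-body
fragmentation).  Auxiliary organelle regions (vacuoles, dark cytoplasm,
granularity, SER cluster) appear with class-independent probabilities, so
their channels are deliberately uninformative; second/multi-polar-body
channels stay empty (those structures do not occur in unfertilized MI/MII/PI
oocytes).  Rendering paints per-structure mean intensities (ZP bright, PVS
dark, FPB brightest, GV moderately darker than cytoplasm, diffuse
darkening milder than the GV), then applies Gaussian blur (σ 1.2 px),
additive noise (σ 6) and ±10 % brightness jitter.  Only the masks carry
ground truth.  Everything is deterministic in (label, params, seed).

What passing phantom tests shows: the pipeline's machinery — tensor
assembly, augmentation, splits, training loops, selection rules, metrics,
the two-stage wiring — is correct, and the two-stage design degrades
gracefully when predicted masks replace manual ones.  What it does not
show: performance on clinical micrographs, whose texture, focus artifacts
and morphological ambiguity the phantoms do not model.

## Desk-scale study sizes

The package's default experiment sizes are chosen for a single CPU:
end-to-end runs use 300 phantoms (100/class) at 128 px, a 136 px classifier
input (2 rotations × 1 shift cache), a 64 px segmenter (16 epochs), and
2 SRRS repetitions; sweep experiments (depth sweep, feature selection) use
80 phantoms/class at 64 px with 8-epoch trainings.  The canonical
(550/590/512 px, 12×5 augmentation, 200-epoch) configuration remains
available through the same config objects.

## Known limitations

* The segmenter is a lightweight stand-alone encoder–decoder; no
  pretrained backbone or atrous pyramid is included.
* Phantom geometry is convex-ellipse-based; irregular or degenerated
  morphology is out of scope.
* The GA evolves filter counts only (not topology), and its default
  evaluator scores one split per individual.
* Sub-550 px records are zero-padded, an artifact convention; whether the
  original pipeline padded or stretched such images is unknown, so
  padding-sensitivity should be checked before applying the tool to data
  near that boundary.
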