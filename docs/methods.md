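# Methods

`retinavasc` studies how a class-conditional change in retinal branching
geometry propagates through a vessel-segmentation + CNN-classification +
Grad-CAM pipeline. Because no public cohort accompanies the analysis it
reproduces, every experiment runs on a synthetic vascular world whose ground
truth is known exactly; this note records the models, the defaults and why,
and what the synthetic world can and cannot say about real fundus images.

## The synthetic vascular world

A vascular tree grows recursively from `n_roots` trunks placed at an
off-centre "optic disc" point inside a circular 45°-style field of view.
At each bifurcation the daughter calibers obey the optimality relation

    d_parent^m = d_1^m + d_2^m,        m = `murray_exponent` (default 3),

the classical minimum-work (Murray) exponent; m is configurable because
empirical retinal exponents scatter around 3. The split between daughters is
governed by the **branching asymmetry ratio** α = (d₂/d₁)² ∈ (0, 1]
(d₁ ≥ d₂), drawn from a clipped normal with mean `asymmetry_mean` (default
0.80, roughly balanced bifurcations) and SD 0.12. The total opening angle is
drawn from a normal with mean `angle_mean` (default 75°, SD 12°); the
thicker daughter deviates less, weighted by squared caliber. Segment length
is proportional to caliber (`length_diameter_ratio` = 8). Growth stops at
`tree_depth` generations (default 6), at the field-of-view edge, or when a
branch would thin below 1 pixel; if only the thin daughter falls below
1 pixel the trunk continues without recording a bifurcation, so every
recorded bifurcation has exactly two live daughters and Murray's relation
holds exactly (checkable to 1e-9 relative error) at every record.

**Class effect.** The "hypertension" class differs from the control class
only through `class_effect`, an additive shift of `asymmetry_mean` (default
−0.25; more asymmetric bifurcations), optionally accompanied by
`angle_effect` on the mean opening angle. This plants the class difference
in bifurcation geometry. The alternative `effect_mode="diffuse"` instead
rescales the root caliber uniformly (bifurcation geometry identical between
classes) and serves as the negative control for the attribution analysis.
A consequence worth stating explicitly: because branches below 1 pixel are
pruned, a strong asymmetry shift also thins the distal canopy — the
bifurcation-local planting has a global branch-density footprint, which
matters when interpreting attribution (see below).

Rendering draws vessels as anti-aliased dark capsules of width equal to the
segment caliber (radius floored at 0.8 px so sub-pixel branches stay
representable) on a bright disc with a smooth illumination plane
(`illumination_gradient` = 0.15), low-frequency Gaussian texture
(`background_texture_sd` = 0.05) and vessel/background contrast 0.55. The
binary mask is the 0.5-coverage level set of the same rasterization, so
image and mask are aligned by construction. Subjects contribute two eyes
with probability 0.4 (independent trees sharing a subject id), exercising
the grouped splitting policy.

What the generator does **not** emulate: artery/vein duality and colour,
optic disc and macula appearance, pathology (hemorrhages, exudates),
camera noise and blur, correlated eyes within a subject, and vessel
tortuosity. Synthetic raw images are already high-contrast, so the
enhancement chain matters less here than on real, dim acquisitions.

## Preprocessing

Auto-crop finds the smallest square window containing all pixels above
`border_threshold` (0.05), centred on their bounding box; it is idempotent
and never rescales. Resize is bilinear with anti-aliasing. CLAHE uses an
8×8 tile grid with clip limit 0.01 of the tile pixel count (common retinal
practice; the choice is exposed in config), delegated to
scikit-image's `equalize_adapthist`. Gamma correction is the pointwise map
I → p·I^γ with γ = 1/1.2 and p = 1 on [0, 1] intensities, so I = 1 is a
fixed point; γ < 1 lifts dark detail. The order (CLAHE then gamma by
default) is a config flag because either order is defensible. All stages
preserve the [0, 1] intensity contract.

## Vessel segmentation

An encoder–decoder network with skip connections (2 levels, 8 base filters,
two 3×3 conv + batch-norm + ReLU blocks per level) is trained on 32×32
patches — half centred on vessel pixels — with per-pixel binary
cross-entropy and Adam (lr 2e-3, 12 epochs, 24 patches/image). Inference is
fully convolutional on the reflect-padded whole image, avoiding tiling
seams. The "segmented" dataset binarizes the probability map at 0.5
(probability passthrough available for ablation). On held-out synthetic
images the default configuration reaches Dice ≈ 0.99 and pixelwise
ROC-AUC ≈ 0.999; the acceptance thresholds (0.85 / 0.95) are deliberately
conservative.

## Classification

The classifier is a small CNN: five stages of 3×3 convolution →
batch-norm → ReLU → 2×2 max-pool, with the fifth pooling stage replaced by
a global max pool over the final feature maps, then two dense stages with
dropout and a two-class softmax. Keeping the network small is itself the
regularization strategy for modest cohorts. The full-scale default config
(filters 16-32-64-64-64, dense 64→2, dropout 0.5, input 224 after random
crops from 256) mirrors that philosophy; the desk-scale preset used by all
experiments here shrinks it (filters 8-12-16-16-16, dense 32→2, dropout
0.1, input 128 from 144, Adam lr 3e-3, 12 epochs) so a 5-fold run fits a
single CPU. Dropout is kept low at desk scale because with only 16 global
max-pooled features heavy dropout prevents the network from fitting at all.

The evaluation protocol is nested five-fold cross-validation: records are
partitioned into five folds (shuffled within class and dealt round-robin, so
every fold contains both classes even at small n — a deliberate tightening
of a plain random partition, which at desk scale can produce single-class
folds whose AUC is undefined); each fold serves once as the untouched test
set, and the development set splits 75/25 into train/validation, stratified
and (by default) grouped by subject so two eyes of one subject never
straddle a split boundary. Augmentation — random crop to the input side,
horizontal/vertical flips, brightness jitter ±0.2, clipped to [0, 1] —
applies to training images only; the training code records the split
indices so tests can verify validation images never pass through it.
Accuracy, specificity, precision, recall (positive class "hypertension",
threshold 0.5) and midrank Mann-Whitney AUC are computed per fold and
averaged unweighted; zero-denominator metrics are flagged undefined rather
than coerced. Reporting rounds half-up to two-decimal percentages and
four-decimal AUC; internal values keep full precision.

## Attribution

Grad-CAM weights each final-conv activation map by the spatial mean of the
target-class logit gradient, rectifies the weighted sum, upsamples
bilinearly to the input and max-normalizes. The target layer defaults to
the last convolutional stage (8×8 at 128-pixel input — coarse by
construction). The qualitative claim "strong activation sits on or around
bifurcations" is operationalized as an **enrichment ratio**: heat-map mass
density inside radius-r disks around bifurcation points divided by mass
density over the vessel mask dilated by the same r (r defaults to twice the
mean skeleton-based vessel caliber). Maps are produced only for correctly
classified test images, for their true class. Two caveats are inherent to
the statistic: vessel-dense regions are also bifurcation-dense, so a map
that merely follows the vasculature scores slightly above 1; and crossings
are kept inside the reference region.

**What the desk-scale experiments show.** The classification signal is
recovered cleanly: with the large planted effect (asymmetry −0.3, angle
−15°) the 5-fold mean test AUC reaches ≈ 0.78–0.79, and a null cohort
(no effect) stays at chance, so the pipeline detects exactly what was
planted and nothing else. The attribution reading, however, does **not**
reproduce the bifurcation-enrichment expectation in this synthetic world:
hypertension-class enrichment medians scatter around or below 1 and do not
exceed the diffuse-control baseline. The mechanism is visible in the maps:
the asymmetry shift prunes thin distal branches, so the network's
hypertension evidence is largely *branch sparsity* — heat over sparse
regions, away from bifurcations — while control-class maps follow dense
branching and are therefore bifurcation-enriched almost by geometry. In
other words, a bifurcation-local cause with a global density footprint is
attributed globally, not locally. This is reported as a property of the
synthetic world and the small model, not as evidence about real retinas;
it mainly demonstrates that Grad-CAM localization cannot be assumed to
recover the causal locus when the planted cause has diffuse consequences.

## Determinism and numerics

All arithmetic is float32 in the networks and float64 elsewhere. Every
stage seeds its own `numpy` generator; the pipeline derives per-stage seeds
as `seed + crc32(stage_name) mod 2^31`. Two runs with identical config and
seed produce byte-identical metrics CSVs. Batch-norm uses running statistics
at inference and dropout is inference-disabled, so prediction is
deterministic. AUC ties take midrank credit. The max-pool backward routes
gradient to the argmax (first maximum on ties).

## Problem sizes

Experiments are sized for a single CPU: 128×128 images, segmenter trained
on 40 pairs with 20 held out, cohorts of 200 images per class for the
planted/null cross-validations, 40 per class over several seeds for the
diffuse attribution control, and 10 per class at 64×64 for the end-to-end
pipeline determinism check. The full-scale presets (565-pixel intermediate
resize, 224-pixel input, 300/500 epochs) remain available in config.
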