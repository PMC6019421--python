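# Methods

`maskcue` implements the analysis chain used to study individual
differences in hyper-realistic-mask detection: a two-alternative
categorization task (mask vs real face), signal-detection and
mixed-ANOVA statistics over the resulting trial tables, landmark-based
texture averaging of the stimuli, and a slice-wise correlation analysis
that localizes the image information separating the two categories. No
public corpus of hyper-realistic-mask photographs with human responses
exists, so the package ships a synthetic-data generator whose statistical
structure matches what the downstream analyses assume. This note records
the model, the parameters that matter, and what the synthetic results do
and do not say about real data.

## The task and the statistics

Each trial presents one grayscale image; the response is "mask" or
"face". Two designs are emulated: a three-category design (37 high-realism
masks, 37 low-realism masks, 74 real faces) and a two-category design (74
high-realism masks, 74 real faces), both at 50% mask prevalence with 148
trials per participant in an independently shuffled order.

With "mask" as the signal class, H is the hit rate (mask trials answered
"mask") and F the false-alarm rate (face trials answered "mask");
sensitivity and bias follow the standard Gaussian equal-variance model,

    d' = z(H) − z(F),    C = −(z(H) + z(F)) / 2,

with z the inverse standard-normal CDF. Extreme rates are handled with
the log-linear correction (add 0.5 to each response cell and 1 to each
trial count) by default; requesting no correction raises on degenerate
rates rather than clamping silently. The unbiased proportion correct,
p(correct) = (H + (1 − F)) / 2, is always computed from raw rates, so it
is invariant to the correction policy. Group summaries report the mean,
SE = sd/√n, and t-distribution 95% confidence intervals across
participants; the CI construction is a package choice, as is partial
η² = SS_effect / (SS_effect + SS_error) as the ANOVA effect size.

Participants are ranked by mask accuracy and split into performance
quintiles (n = 30 gives five groups of six); ties break by ascending
participant id. When n is not divisible by 5 the extreme quintiles keep
⌊n/5⌋ members and the middle quintiles absorb the remainder, keeping the
contrasted subgroups balanced. The 2 × 2 mixed ANOVA (image type within,
subgroup between) uses the classical cell-means sums-of-squares
decomposition; all three effects are tested on (1, N − 2) degrees of
freedom.

## Shape normalization and texture averaging

Every stimulus carries 60 named landmarks (head outline, brows, eyes,
nose, mouth, interior anchors, and six points pinning the under-eye band).
The mean shape is the generalized Procrustes consensus (translation,
rotation, isotropic scale removed; convergence tolerance 1e-6 on the
unit-size consensus), rescaled to the average centroid and centroid size
of the inputs so it lives in pixel coordinates. Images are mapped onto a
target shape with a piecewise-affine warp: Delaunay triangulation of the
target points plus eight fixed frame-border anchors, one affine transform
per triangle, bilinear sampling, zero outside the triangulation. The
triangulation and per-pixel barycentric coordinates are computed once per
target and reused, so averaging ~150 images costs one warp each.

Veridical category averages weight each contributing image equally;
perceived averages weight image i by the number of times the subgroup
classified it with the given label (raw response counts, not
proportions), dropping zero-weight images. All six averages in the
two-category analysis share a single mean shape computed from the
included stimuli, so difference images between any pair are defined.
Whether to average in fully shape-normalized space or after rigid
alignment only is an open choice; the package normalizes fully and
records the mean shape with each average.

## Difference images and slice correlations

A difference image is the signed, unclipped subtraction (mask average
minus face average). For display, its absolute value is mapped affinely
to 0–255; correlations never use the rescaled values (Pearson r is in
any case invariant to per-image affine rescaling). The background is
cropped to the internal-features rectangle — canonically 300 × 228 pixels
— and cut into equal horizontal slices, canonically 30 slices of
10 × 228 = 2280 pixels, numbered 1-based from the top. Each slice is
flattened row-major and the two images' slice vectors are correlated with
Pearson's r; zero-variance slices are flagged undefined rather than set
to 0. The notch is the slice with the minimum defined correlation, ties
breaking toward the smaller index.

## The synthetic-data generator

Stimuli are 540 × 385 8-bit grayscale renderings of a parametric face
template (elliptical head with radial shading, brows, eyes with irises
and lash lines, nose, mouth, hairline and jaw shading arcs, and a fixed
fine-grain complexion texture attached to the face). Per-stimulus
nuisance variation comprises a global similarity jitter plus small
per-feature displacements (landmarks move consistently), a whole-face
complexion offset (sd 5), a feature-contrast multiplier (sd 0.10), and
i.i.d. pixel noise (sd 1).

Masks differ from faces in two ways:

* a **global cue** — feature contrast is flattened (×0.82 for
  high-realism masks, ×0.55 for low-realism masks) and the face gains a
  small brightness offset — present in every image region; and
* a **local under-eye cue** confined to a 10-row band that coincides with
  analysis slice 15: local contrast is attenuated (×0.2 around its
  band mean), complexion shifts (+55 intensity units with per-stimulus
  jitter), and 35% of masks ("carriers", an exact count per stimulus set)
  additionally show strong complexion-discontinuity blotches at random
  positions, as if the mask's eye holes met the wearer's skin poorly.
  Carriers trade off: their global give-aways are weaker, as if
  poorly-fitting masks were otherwise better made.

Two properties of the band are deliberate and load-bearing. First, its
content is *idiosyncratic*: the fixed template features and the shared
complexion texture are excluded from the band, so the average band
content of a stimulus subset reflects which stimuli were selected, not
the shared template. A subgroup's perceived difference image therefore
reproduces the veridical band pattern only to the extent that its
responses track the true categories — which is exactly what the slice
analysis is supposed to detect. Second, the idiosyncratic fields are
brightness-neutral (zero mean within the band) and taper to zero at the
band edges, so they neither pollute the band-mean intensity cue the
observers read nor leak into neighbouring slices through sub-pixel
resampling.

Observers read, for each of 30 horizontal bands of the analysis crop,
a standardized statistic combining band-mean intensity (weight 0.8) and
mean absolute horizontal neighbor difference (a high-pass local-contrast
measure, weight 0.2, negated), each z-scored across the stimulus set so
that mask-typical content is positive. Decision evidence is the
band-weighted sum plus zero-mean Gaussian internal noise; the response is
"mask" above the observer's criterion, with a small lapse probability
replacing the response by a coin flip. Reaction times are log-normal with
a median that decreases in the evidence margin |D − c| (600 ms floor,
2000 ms at zero margin), purely so RT summaries have realistic structure;
no reaction-time value is treated as reproducible.

The default panel of 30 observers varies a single ability axis: the
weight on the informative band rises from 0 (the bottom third of the
panel ignores it entirely) to 0.95, while internal noise falls from 1.5
to 0.05 and the criterion relaxes from 0.55 to 0. This yields expected
high-realism mask accuracies from below 50% to above 85% across the
panel, with group means near 70% (masks) and 86% (faces) in the
two-category design. Prior-knowledge ratings (1–7 Likert) are drawn
independently of ability with mean ≈ 2.7. All randomness descends from
one integer seed through named `SeedSequence` streams; per-stimulus
draws happen unconditionally in fixed order, so the same seed with a
different category yields a matched pair differing only by the cues.

## What the simulations show — and what they cannot

Passing tests establish that the *pipeline* behaves correctly: the
statistics match independent oracles, the warping and averaging obey
their algebraic invariants, and when a panel contains subgroups that do
or do not use a localized cue, the slice analysis recovers that cue's
location (the low quintile's minimum correlation falls on slice 15 in
≈95% of simulated studies, and its minimum lies below the high
quintile's essentially always). They do not certify anything about real
photographs or human observers: the stimuli are caricatures, the
informative band is placed by construction, and observed effect sizes
are properties of chosen parameters, not measurements.

Known limitations of the generator, accepted deliberately:

* **One ability dimension.** Mask and face accuracies correlate strongly
  across the simulated panel because a single axis drives band weight,
  noise and criterion together. Human data show the two conditions
  nearly uncorrelated; emulating that would need an independent bias
  dimension, which destabilizes the calibrated subgroup structure.
* **Ceiling compression.** Because band statistics are z-scored across
  the stimulus set, no cue — however gross — can exceed a standardized
  separation of about 2.3 s.d.; the noisiest observers therefore top out
  near 90% on low-realism masks rather than the ~98% humans reach.
* **No context effects.** Accuracy on high-realism masks is the same
  whether or not low-realism masks are present, whereas humans improved
  markedly when the easy category was removed.

## Numerical and runtime choices

Rendering uses float32 with feature drawing restricted to bounding
windows (~15 ms per stimulus). Warps cache the target triangulation; a
full two-category study (148 stimuli, 30 observers, six averages, slice
analysis) runs in a few seconds. The Monte-Carlo suites use the study's
own scale — 148 stimuli × 30 observers per replicate, 50 replicates for
the cue-recovery property, 200 for the subgroup-detection property
(twenty panel/trial replicates over each of ten stimulus sets). CSV
output uses 6 significant digits so cross-platform diffs are stable;
degenerate inputs (zero-variance correlations, all-zero weights,
non-divisible slice heights, extreme rates without correction) raise
explicit errors rather than returning placeholder values.
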