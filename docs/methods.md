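# Methods

## Motion quantity

The motion series is the raw sum of per-keypoint Euclidean displacements
between consecutive sampled poses, in pixels. No smoothing, filtering,
per-joint decomposition or normalisation by image size or infant scale is
applied: the quantity is deliberately simple, and its only job is to rank
windows within one video, where the scale factors (camera distance, infant
size) are constant.

With F pose frames there are F − 1 displacement values, indexed 0..F−2;
`values[i]` is attached to the leading frame's timestamp. A window of
`window_s` seconds therefore sums exactly `W = round(window_s × rate)`
displacement values: a 60 s interval at 1 Hz spans 60 inter-frame
displacements, bounded half-open in sample space. (Writing the window sum
with an inclusive upper bound would make a "60 s" window sum 61 terms; we
treat that as an off-by-one of notation, not of intent.)

**Confidence policies.** The displacement sum itself contains no confidence
term, and `include_all` (the default) computes it literally. Real pose
estimators emit low-confidence garbage for occluded limbs, so two opt-in
policies exist: `drop_keypoint` sums only keypoints at or above a confidence
threshold in *both* frames of a pair, and `normalize` additionally rescales
by 17/(retained count) so values stay comparable across frames with
different numbers of retained keypoints (a pair retaining nothing scores 0
by convention). These are robustness modes; every agreement number reported
by the package's own pipeline uses the default.

## Sequence selection

Window scores are computed with a running cumulative sum (O(n)); the best
sequence starts at the smallest index attaining the maximum. Ties break to
the minimum start index everywhere — the same convention the matching step
uses — so selection is deterministic on constant or symmetric inputs.

The multi-sequence rule is greedy non-overlapping selection: take the argmax
window, discard every window overlapping it in sample-index space, repeat.
Greedy (rather than jointly optimal k-window packing) matches how a
clinician skims a recording — take the most active minute, then the next
most active elsewhere — and guarantees scores are non-increasing in rank. A
`free` mode that permits overlaps exists for sensitivity analysis; when
disjoint candidates run out, fewer than k sequences are returned and the
evaluation denominator uses the returned count.

Fractional windows: `window_s × rate` is rounded to the nearest sample
count, with a warning whenever the requested duration is not a whole number
of samples.

## Agreement metrics

Intersection and dice similarity operate on half-open intervals in seconds;
unequal durations are supported (the dice denominator is the sum of both
lengths). Matching a software interval to an expert is independent per
software sequence — the same expert interval may be matched repeatedly; the
definitions impose no one-to-one assignment, and none is added.

`Precision(τ)` uses a strict inequality (`MDS > τ`). A consequence worth
knowing: a perfect selector scores 0 at τ = 1.0. This is a property of the
definition and is left intact; tests assert it explicitly.

The default threshold grid is 0.00, 0.01, …, 1.00. Average curves use the
pointwise arithmetic mean and *population* standard deviation across the
component curves.

## Synthetic data

The generator emulates the intended recording protocol: hour-long (3600 s)
supine recordings sampled at one pose per second in 1280×720 frames. Its
defaults are fixed once and shared by the test suite and the acceptance
script:

| parameter            | default | rationale                                            |
| -------------------- | ------- | ---------------------------------------------------- |
| `video_length_s`     | 3600    | hour-long recordings                                 |
| `sample_rate_hz`     | 1       | the selector's operating rate                        |
| `baseline_jitter_px` | 1       | realistic pose-estimator noise at 720p (≈1 px σ)     |
| burst amplitude      | 20 px   | vigorous limb movement; ≥10× the baseline jitter     |
| burst duration       | 60 s    | the one-minute GMA sequence length                   |
| `n_experts`          | 4       | panel size of the evaluation protocol                |
| `ns_per_expert`      | 5       | sequences each rater selects per video               |
| `expert_jitter_s`    | 5       | rater start-time disagreement (σ of a Gaussian)      |

Keypoints sit on a static supine skeleton template plus i.i.d. Gaussian
jitter; inside a burst each keypoint additionally receives an independent
random-direction offset of magnitude |Normal(A, A/4)| per frame. The
skeleton enforces no kinematic chain: the motion quantity is pose-agnostic,
so anatomical realism buys no test power. Simulated experts are jittered
oracles — they annotate the true bursts, largest amplitude first, with
Gaussian start perturbations — the minimal rater model that exercises
matching, dice and precision nontrivially.

What this does **not** model, and hence what passing tests do not show about
clinical data: caregiver interventions and crying/fussing episodes (which
produce high motion the selector will happily pick), estimator failure modes
(identity swaps, occlusion dropouts), camera motion, and raters who weigh
movement *quality* rather than quantity. Agreement numbers from synthetic
studies characterise the machinery, not clinical performance.

Randomness: one root seed, split hierarchically (`[seed, 0]` poses,
`[seed, 1, e]` expert e, `[seed, 2]` burst placement), so adding an expert
never perturbs existing streams and runs are bit-reproducible.

## Numerical and I/O choices

- Window sums use a cumulative sum; scores are compared exactly for
  tie-breaking, which is safe because ties in practice arise from constructed
  integer-valued series (random continuous series have no exact ties).
- Timestamps, motion values, selections and annotations are written with
  shortest round-trip float formatting and parsed with exact conversion, so
  CSV round trips and CLI-vs-library comparisons are bit-identical.
  Keypoint coordinates and confidences are written at 6 decimal places —
  far below estimator noise.
- Pose files are validated on read: exactly 17 keypoints per frame in fixed
  COCO-17 order, strictly increasing timestamps (out-of-order rows are an
  error, never silently sorted), uniform sampling within 1 µs, confidences
  in [0, 1], finite coordinates. Missing detections are encoded as
  confidence 0, never as NaN.
- Resampling is integer decimation only (keep every n-th frame); anything
  else would fabricate poses.
- A pose series requires at least two frames (one displacement) by
  construction.

## Problem sizes used in tests

The randomized selector-equivalence check runs 1000 series of length
100–1000 with windows of 5–90 samples against a direct per-window summation
oracle. Planted-burst recovery uses 100 seeded replicates of a 600 s video
with three bursts at 20 px amplitude over 1 px jitter. The end-to-end study
uses the full default conditions above (6 × 3600 s videos). These sizes make
the whole suite run in seconds while keeping every check at or above the
scale the procedures are designed for.

## Known limitations

- The selector ranks by motion quantity alone; it cannot distinguish infant
  general movements from any other source of keypoint motion.
- Evaluation assumes every selected video has annotations from every rater
  considered; partially annotated studies must be filtered upstream.
- The inter-rater computation treats each rater's intervals as "selections"
  against the others, so its denominator is that rater's interval count —
  asymmetric panels (raters with different Ns) are supported but flagged.
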