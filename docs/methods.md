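# Methods

## Problem setting

The MDS-UPDRS Part III motor exam scores each task on a 5-point ordinal
scale (0 = normal … 4 = severe). Expert ratings of the same video
disagree systematically, and the disagreement grows with *task
complexity* — the number of behavioral cues a rater must track
simultaneously (2 for Arising from Chair; 7 for Gait: stride amplitude,
stride speed, foot lift, heel strike, turning, arm swing, assistive
device). `kinescore` therefore treats the rating target not as a single
label but as a distribution over raters, predicting its mean and
variance, and evaluates predictions against consensus-aware bands.

The input is a 2D pose-keypoint time series per video — per-frame joint
(x, y, confidence) triples from any standard pose estimator — plus task
metadata and, for training, panels of three ordinal ratings.

## Pipeline

1. **Cleaning** (`pose`). Joint observations below a confidence
   threshold (default 0.5) become missing; gaps of at most `max_gap`
   (default 15 frames, 0.5 s at 30 fps) are bridged by linear
   interpolation and the trajectories smoothed with a centered moving
   average (default 5 frames; edges use shrinking windows). Coordinates
   are then scaled by the median shoulder-hip distance and the image y
   axis flipped, so all downstream quantities are in body-scaled,
   up-positive units, independent of camera distance. Longer gaps stay
   missing and are excluded from signals. Filtering precedes smoothing
   so low-confidence detections never leak into the averages.

2. **Segmentation** (`segmentation`). The task window is found by
   thresholding joint kinematics: onset is the first frame at which the
   speed of any task joint and its displacement from the initial
   baseline (median position over the first 10 frames) both reach the
   calibrated thresholds; the window ends when the speed envelope stays
   below `baseline_fraction` (0.5) of the velocity threshold for 15
   consecutive frames. Thresholds are calibrated per task as a low
   percentile (default 20th) of within-window *peak* speed and
   displacement across labeled training clips. Deployment scales the
   calibrated values by a margin of 0.35: within a movement cycle, speed
   peaks at the displacement zero-crossing and displacement at the speed
   zero, so the frame-wise joint condition is only satisfiable at about
   0.8 of the separate peaks, and the weakest (severity-4) performances
   move at roughly a quarter of the severity-0 amplitude-speed product.
   The speed trace is compared as a 5-frame envelope because the
   frame-wise speed of a jittering keypoint is Rayleigh-distributed with
   a non-zero floor. Windows are half-open `[start, end)` in 0-based
   frames. For bilateral tasks the active side is the one with the
   greater within-window path length (ties to left, logged).

3. **Signals and features** (`kinematics`). Each task maps to one 1D
   signal: thumb-index distance (finger tapping), mean fingertip-palm
   distance (hand movements), vertical displacement of wrist / toe /
   knee / torso relative to the window start (pronation-supination, toe
   tapping, leg agility, arising from chair), per-step inter-ankle peak
   distances baseline-subtracted by the first step (gait; the signal's
   rate field then holds steps/second), and torso vertical displacement
   relative to the pull instant (postural stability; the pull frame is
   taken from an annotation when present, otherwise the frame of peak
   torso speed). Twelve descriptors summarize each signal: mean absolute
   first/second/third finite differences scaled to per-second units
   (velocity, acceleration, jerk); the power-weighted mean frequency
   (spectral centroid) and maximum power of the detrended periodogram
   over 0.25-10 Hz; mean inter-peak and inter-trough intervals (s); mean
   and SD of per-cycle peak-to-trough amplitude; least-squares slopes of
   per-cycle amplitude and of per-cycle mean speed against cycle index
   (bradykinetic decrement); and the range of inter-peak intervals
   (rhythm irregularity). Cycles come from Savitzky-Golay smoothing
   followed by prominence-gated peak detection (prominence ≥ 10% of the
   signal range, minimum separation 0.15 s) with alternation pruning.
   When fewer than two cycles exist the cycle-based entries are NaN —
   never silent zeros — and are median-imputed at model time. The
   spectral centroid was preferred over the periodogram argmax for the
   "mean dominant frequency" because it degrades gracefully for
   quasi-periodic, hesitating movement; the argmax information is kept
   separately as the maximum power. Decrement slopes regress on cycle
   index rather than time so hesitation pauses do not dilute the decay
   estimate.

4. **Ordinal model** (`ordinal`, `nn`). A dual-branch network scores one
   clip: a 1D CNN (three blocks of convolution → batch normalization →
   ReLU → max pooling: 16/32/64 channels, kernels 7/5/3, pool 2,
   followed by global average pooling) reads the task signal resampled
   to T = 256 samples and z-scored per clip; an MLP (widths 32, 16)
   reads the standardized 12-feature vector. The concatenated embedding
   is reduced to a scalar score s, and a CORAL head produces K−1 = 4
   cumulative logits g_k = s − b_k against thresholds parameterized as
   b_k = θ₀ + Σ_{i≤k} exp(θ_i), which are strictly increasing, so
   P(y > k) = σ(g_k) is non-increasing in k *by construction* — rank
   consistency cannot be violated even mid-training. Expanding the
   cumulative probabilities gives the class distribution, whose mean μ̂
   and variance σ̂² enter the disagreement-aware loss

       L = Huber(μ̂ − t; δ) + λ·σ̂²,

   with t the rater-panel mean, δ = 1 severity class, and λ (default
   0.1) trading accuracy against predicted spread: unanimous panels push
   the model toward confident (low-variance) distributions while
   genuinely contested clips can stay broad at modest cost. σ̂² here is
   the *predicted* distribution's variance — the regularization reading
   under which confident predictions are rewarded — not the rater
   panel's variance. The gradients are closed-form: with cumulative
   probabilities c_k, μ̂ = Σc_k and E[y²] = Σ(2k+1)c_k, giving
   ∂L/∂c_k = Huber′(μ̂−t) + λ((2k+1) − 2μ̂). Training uses Adam at
   learning rate 1e-3, batch size 32, 100 epochs, one model per task
   with bilateral sides pooled as separate samples; everything is
   deterministic under the configured seed. The network is implemented
   directly in NumPy with analytic backpropagation (verified against
   finite differences in the test suite); at these model sizes a
   framework would add nothing but a dependency.

5. **Consensus metrics** (`consensus`). Panel summaries use the sample
   (n−1) standard deviation — the convention under which a (1, 2, 2)
   panel is mean 1.67, SD 0.58. Agreement categories: *complete* (all
   raters equal), *majority* (a strict majority shares one score),
   *none*; percentages are reported disjointly, with a cumulative
   two-or-more view available. The ±1 accuracy rule is applied to the
   continuous predicted mean against the continuous panel mean
   (|μ̂ − t| ≤ 1). The distribution-aware rule accepts μ̂ within
   k·max(σ, σ_floor) of t with k ∈ {1, 1.5}; the floor (default 0.5
   class) keeps unanimous panels from collapsing the band to a point
   while still tightening sharply for high-consensus tasks. A strict
   mode rounds mean and SD to two decimals first, reproducing
   printed-table bounds such as [1.09, 2.25]. Composite scores sum μ̂
   over all present task/side slots (13 for the shipped battery, both
   sides of bilateral tasks included); the ON/OFF medication contrast is
   the per-patient ON − OFF composite delta and the fraction improved.

## The simulator and what it does — and does not — show

The package ships a severity-parameterized generator (`simulate`)
standing in for clinical recordings, which cannot be redistributed.
Motion: a quasi-periodic drive with severity-scaled amplitude
(×(1 − 0.18·s)) and frequency (×(1 − 0.12·s)), per-cycle amplitude
decrement (0.02·s), random 3-10-frame hesitation freezes (probability
0.05·s per cycle), Gaussian keypoint jitter (0.4 px at a 100 px trunk),
occasional sub-threshold-confidence detections, and static pre/post
segments — encoding exactly the constructs the scale rates: speed,
amplitude, rhythm, smoothness, progressive slowing. Severities are
continuous in [0, 4] (patients genuinely sit between adjacent scores);
OFF-state values follow a moderate-disease distribution
(0.10/0.25/0.30/0.25/0.10 over the five classes, jittered ±0.5) and the
ON state subtracts one class on average (SD 0.3, clamped to [0, 4]).

Raters: each reports clamp(round(s + bias_r + ε), 0, 4) with a small
fixed per-rater bias (SD 0.15) and ε ~ N(0, 0.10 + 0.02·complexity).
With probability 0.10·complexity a clip is *cue-conflicted* — its cues
point at different scores — and ε's scale jumps to 2.0 for all raters. A
single noise scale cannot simultaneously produce frequent unanimity and
a sizable no-agreement minority on a clamped 5-point scale; the mixture
can, and calibrates to ~41% complete and ~80% two-or-more agreement on
the default battery. The cue-conflict probability rising with cue count
is also what produces the complexity-consensus tradeoff the consensus
module must detect (negative complete-agreement slope, positive
panel-SD slope).

What passing on this generator shows: that every stage is wired
correctly end to end — segmentation recovers known windows, features are
monotone in the latent severity, the ordinal model recovers that
severity out of sample (Spearman ≳ 0.9 at 200 training clips per task),
and the medication contrast is detected for nearly all patients. What it
does **not** show: performance on real clinical video. Synthetic
trajectories have no camera motion, occlusion, clothing artifacts,
inter-patient anatomy differences, or correlated pose-estimator failure
modes, and the severity-to-kinematics map is by construction the one the
features measure. The published clinical-dataset results — the per-task
accuracy tables, the agreement-regression magnitudes (slope −6.7 for
complete agreement, +0.03 for panel SD), and the baseline comparison —
depend on the private patient cohort and are **not** reproduction
targets of this package; only their mechanisms (metric definitions,
sign structure, aggregation logic) are implemented and exercised here.

## Evaluation protocol and problem sizes

Experiments split by patient (GroupKFold) so no patient contributes to
both training and evaluation; out-of-fold predictions feed all metrics
and the per-patient composites. The shipped experiment sizes — 200
train / 50 test clips per task for severity recovery, a 48-patient
cohort with 2 grouped folds for the medication contrast — were chosen as
the smallest sizes at which the stochastic checks are stable and are the
package's defaults; larger cohorts and 5-fold evaluation are a config
change. λ can be tuned by grouped cross-validation over {0, 0.01, 0.1,
1}; the default 0.1 was adequate across all tasks.

## Numerical choices and degenerate inputs

- Non-monotone cumulative vectors passed to `expand_distribution` are
  repaired by a running maximum from the right and logged; model output
  cannot trigger this (ordered thresholds) but external inputs can.
- Per-clip signal z-scoring uses a 1e-12 floor; constant signals pass
  through unscaled. Feature standardization constants live in the
  trained model and checkpoint.
- An unanimous panel has SD exactly 0; the σ_floor applies at metric
  time only and is configurable (0 restores the raw criterion).
- Ties in active-side path length break to the left with a warning;
  a side with no detected joints yields the other side with a warning.
- Savitzky-Golay windows shrink for short signals; signals shorter than
  two samples, flat signals, and monotone ramps raise typed errors
  rather than returning fabricated cycle features.
- `detect_window` with no supra-threshold frame raises a no-activity
  error; the pipeline logs it and falls back to the full clip.

## Known limitations

- 2D keypoints only; out-of-plane motion (true pronation-supination
  rotation) is observed through its vertical projection.
- The postural-stability pull instant is inferred from peak torso speed
  when unannotated, which fails for multi-pull recordings.
- Gait signals are per-step sequences; clips with fewer than two
  detected steps are rejected rather than zero-filled.
- The 12 shipped features are the common cross-task set; two optional
  task-specific slots exist in the design but ship disabled.
- Agreement calibration cannot match every published percentage at
  once (see above); the shipped defaults favor the complete-agreement
  level and the monotone complexity trends.
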