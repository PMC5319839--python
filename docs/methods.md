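# Methods

`bcisim` is a closed-loop simulation of a point-and-click intracortical
brain-computer interface (iBCI). A synthetic motor-cortical participant
stands in for a human user; everything downstream of the electrode — the
signal chain, the cursor and click decoders, the selection logic, the
session protocol and the throughput metrics — is implemented as it would
run online, at a 15-ms decoding cadence with 1-ms cursor integration.

## The synthetic participant

Each simulated channel fires with linear cosine tuning to intended cursor
velocity. For channel *c* in one 15-ms bin,

    rate_c = max(0, b_c + d_c(t) + m_c * (u_c . v) + s_c * [click]),

where `b_c` is the baseline (counts/bin), `u_c` the preferred direction on
the unit circle, `m_c` the modulation depth (counts/bin per workspace
unit/s), `v` the intended velocity, and `s_c` an additive mean shift active
while the user attempts a click (a hand squeeze). Counts are Poisson around
this rectified rate. An HF-LFP-like power feature is the same drive passed
through a per-channel gain plus Gaussian noise, rectified at zero, so band
power co-modulates with multiunit rate the way it does on a real array.

Defaults (the study conditions used throughout unless a test documents a
smaller scale): 96 channels, baseline 1.0 counts/bin (~67 Hz), mean depth
1.5 counts/bin per unit speed with ±30% per-channel jitter, click shift 0.6
counts/bin on a random 25% of channels, preferred directions uniform on the
circle. The workspace is [-1, 1]², so typical cursor speeds (~1-1.5
units/s) put peak modulation on the order of the baseline — a deliberately
strong but plausible multiunit SNR.

Slow nonstationarity is an Ornstein-Uhlenbeck walk on per-channel
baselines, advanced once per bin: `db = -theta*b + sigma*eps`. No
quantitative drift magnitude is available to copy, so the profile that uses
drift defaults to `theta = 5e-5`/bin (~5-minute reversion) and
`sigma = 3e-3` counts/bin/√bin, i.e. a stationary s.d. of ~0.3 counts/bin —
large enough that a fixed decoder visibly degrades over minutes, small
enough that per-block baseline re-estimation recovers it. Both parameters
are exposed in the generator config. With `drift_sigma = 0` the generator
is exactly stationary, which the tests verify.

An optional raw-broadband path synthesizes 30 kS/s voltage for the signal
chain only: biphasic ~1-ms spike templates injected at the binned counts
(aligned to 1-ms detector windows, at most one per window), white noise of
configurable RMS, and a common-mode sinusoid shared by all channels to
exercise the reference stage.

What the generator does **not** emulate: spike waveform diversity and
sorting, realistic LFP spectra, array micro-geometry, cross-channel noise
correlations (beyond the injected common mode), and any participant-specific
statistics. Passing tests therefore demonstrate the correctness and
closed-loop behaviour of the decoding stack under its own model
assumptions, not performance on recorded neural data.

## Signal chain

Broadband voltage → common average reference (mean across channels,
per sample) → spike band via a cascaded causal IIR + linear-phase FIR
high-pass → a 1-ms presence detector (a window scores 1 if any sample dips
below threshold) → 15-ms bins. Thresholds are fixed per array (e.g.
-50 µV) or set at -4.5× the per-channel RMS. HF-LFP power is the per-bin
mean square of the 150-450 Hz band of the *referenced* (not spike-filtered)
signal, computed zero-phase so narrowband power lands in the correct bins.

The online filter's exact realization is not documented anywhere we could
copy, so the defaults are our own: 2nd-order Butterworth at 200 Hz applied
causally, then a 401-tap FIR high-pass at 200 Hz whose group delay is
trimmed. A 4th-order IIR stage was rejected because its causal phase lag
clips a biphasic spike's peak by ~32%; the shipped cascade keeps the peak
within 20% while rejecting content below 100 Hz by more than 40 dB. Orders,
cutoffs and taps are all in `SignalConfig`.

Baselines are re-estimated per block from a 30-s rest stream (per-feature
mean); shorter rest periods are accepted with a warning.

Bins are half-open `[t, t+15 ms)` aligned to stream start; the sum of 1-ms
detections over a bin equals the bin's count exactly (conservation is
tested). All operations are pure functions of (segment, config).

## Cursor decoder

A linear-Gaussian Kalman filter over the state `(v_x, v_y, 1)` — velocity
plus a constant that absorbs baseline offsets. Position is excluded from
the observation update (velocity-only decoding); decoded velocity is
integrated at 1 ms with workspace clamping. Kinematics are
`v_t = a v_{t-1} + w` with `a = 0.96`/bin by default; process noise is
matched to the calibration velocity variance, `W = (1-a²) Cov(v)`, so the
kinematic prior is stationary at calibration speeds. The observation model
is fit by regressing features on `(v_x, v_y, 1)`; observation noise is the
residual covariance with a small ridge. The gain recursion is run until the
Riccati iteration converges, then frozen — the steady-state filter is what
ran online in the systems this mirrors.

Feature selection ranks features by tuning significance (F-test p-value of
the velocity regression), adds them in that order, and returns the smallest
prefix whose cross-validated decoding R² is within 1e-3 of the best. The
"no tuning" failure gate is Bonferroni-corrected across channels.

Calibration is two-stage. The open-loop stage fits on a programmed
centre-out-and-back block whose intent mirrors the cursor. The closed-loop
recalibration stage then drives the actual filter, relabels each bin's
intent with the decoded *speed* rotated to point from cursor to target
(zero while over the target), and refits. During recalibration the
perpendicular component of the decoded velocity can be scaled by an
assistive factor γ (default 0.5, off for profiles that did not use it) so
all targets remain reachable with a poor initial filter. A session is
"controllable" if the closed-loop median heading error is under 60°; this
gate is a declared proxy, not a documented rule.

### Bias correction

Decoded velocity carries a slowly drifting offset when baselines drift. The
online estimate updates per axis at 1 ms:

    B(t) = B(t-1) + (V(t) - B(t-1)) * |V(t) - B(t-1)| * dt / tau,

with `tau = 30 s`, gated so updates occur only when decoded speed exceeds
the 15% quantile of recalibration-block speeds (within the documented
10-20% band). The magnitude-weighted term makes the estimator insensitive
to the long stretches of low speed around dwells. `V ≡ B` is a fixed point;
convergence toward a constant offset is monotone per axis; larger `tau`
responds more slowly — all tested. The corrected output is `V - B`. The
update runs at 1 ms on the most recent 15-ms velocity, held between bins.

## Click decoder

Features (one family per profile: spike counts or HF-LFP power) are reduced
to the top four eigenvalue-ranked principal components — enough to carry
the click signature, few enough to estimate two 4×4 Gaussian emission
models from a few minutes of labelled calibration. PC signs follow a
deterministic convention (largest-magnitude loading positive). The
two-state (move/click) HMM uses per-label Gaussian emissions and a bigram
transition matrix with a pseudocount of 1; the filtered posterior follows
the standard one-step recursion with per-bin renormalization, computed with
a log-domain max shift so arbitrarily small likelihoods are safe.

The click threshold is calibrated without supervision at the 93rd
percentile (linear interpolation between order statistics) of the
click-state posterior over the retraining block, so 7% of that block's bins
sit above it by construction. Online, a click fires on the second of two
consecutive above-threshold bins, and the counter then re-arms: a sustained
excursion cannot fire faster than once per two bins, and a fresh pair is
required after each click.

A property worth knowing: when the same feature family feeds both decoders,
very strong velocity tuning can crowd the click signature out of the top
four PCs and *degrade* click detection as SNR rises. This is a real
consequence of an unsupervised shared PCA front end, and it is why the
signal-quality monotonicity property is measured on the dwell-only pathway
(see "Tested properties" below).

## Tasks, selection and protocol

Grid task: an n×n tiling (6×6 or 81-cell 9×9) of equal half-open squares;
one uniformly random cell is cued, a new cue follows each selection
immediately, blocks last two minutes. Trials that reach the per-trial
timeout (default 10 s; the original limit is not documented) log no
selection — they count toward elapsed time but not toward S or E — and by
default a new target is prompted.

Keyboards: a QWERTY sheet (three letter rows plus backspace `<` and a
space bar `_`), an alphabetical sheet with identical key geometry and
permuted labels, and an optimized layout with frequent characters packed
around the centre. The optimized layout's exact published coordinates were
not available; the shipped `opti2` is a synthetic frequency-centred
arrangement (documented in `src/bcisim/data/opti2_synthetic.csv`) that
preserves the defining property — smaller frequency-weighted expected
inter-key travel than QWERTY — which the tests assert.

Selection: dwell with either reset semantics (the counter zeroes on target
exit; 1.0 s) or cumulative semantics (per-target counters persist across
exits; 1.5 s; all counters zero after any selection), plus HMM click where
enabled. Timing is bookkept in integer milliseconds; a dwell fires on the
first 15-ms tick whose accumulated hold *strictly exceeds* the requirement
(so a 1.5-s requirement fires on the 101st tick, 1.515 s). Optional
recentering teleports the cursor to the workspace centre after every
selection — correct or not — and disables selection for 500 ms; a bin is
disabled iff it ends inside the lockout, so exactly 33 full bins are locked
and the 34th may select.

Copy typing cues the next needed character of the prompt given the
committed (net-of-backspace) transcript, and cues backspace after an
error; the block ends at sentence completion or the two-minute cap. The
shipped prompt list is a set of pangram-style sentences; prompt content
affects no metric.

Blocksets: a recalibration block (full decoder refit) or a bias/baseline
update block, then one grid and two copy-typing blocks in an order drawn
uniformly from the four permutations that keep the typing blocks adjacent;
both typing blocks in a blockset share one sentence. A validator enforces
the block counts, adjacency and duration caps on every session log.

Three shipped profiles mirror the documented per-participant recipes:
hybrid features + HF-LFP click + per-blockset refit + error attenuation;
spikes-only + no click + 1.5-s cumulative dwell + recentering + bias
updates + drift; spikes-only + spike click + bias updates (the default).

## The simulated user

A saturating proportional feedback controller with a 200-ms reaction delay
(implemented by lagging the cue the controller acts on): intent speed is
`min(max_speed, gain * distance)` toward the cued target's centre, with
Gaussian angular jitter (s.d. 0.12 rad); intent is zero once the cursor is
within half the target's inradius of its centre (users aim at the middle of
a key, not its edge — without this the cursor parks on the boundary and
dwell never completes). Click intent turns on after 0.3 s of hover and
comes in bounded squeeze pulses (0.25 s on, 0.35 s gap) that release
immediately at the selection beep; the pulse shape bounds the post-click
neural activity that would otherwise re-trigger the two-bin detector.
Defaults: gain 4 /s, max speed 1.5 units/s. All parameters are config; no
human controller model is being copied.

## Metrics

Achieved bitrate `B = log2(N-1) * max(S-2E, 0) / t` (bits/s) and correct
characters per minute `C = max(S-2D, 0) / t_min`, with the standard
5-characters-per-word conversion for wpm. Timeouts never enter S or E but
their time elapses; uncorrected typos count as correct (only deletions mark
errors). Reported values are rounded to one decimal, round-half-even. A
uniform random selector on the 6×6 grid has negative expected `S-2E`, so
its measured bitrate is 0 under the floor — verified by Monte-Carlo. The
click-accuracy summary reports percent-on-cued-target with the histogram of
click-to-cued-centre distances and flags whether misses cluster near target
edges.

## Tested properties and problem sizes

The suite (pytest; hypothesis derandomized) runs in roughly two minutes on
one CPU. The closed-loop fixtures use reduced study conditions chosen once:
the "default profile" end-to-end check runs the full 96-channel profile
through calibration and one two-minute 6×6 grid block (it reproducibly
exceeds 1 bit/s, landing near 3.5 bits/s); most other session tests use 48
or 32 channels with shortened calibration. The signal-quality monotonicity
property (grid bitrate non-decreasing in modulation depth over {0.5, 1, 2,
4} counts/bin, 10 seeds each, Spearman rank test) is measured dwell-only on
16 channels so that throughput is limited by decoding quality rather than
selection latency — with the click decoder enabled the curve saturates and
then inverts at high depth for the PCA reason described above.

Numerical choices worth pinning: quantiles use linear interpolation between
order statistics; PCA signs follow the largest-loading-positive rule;
observation-noise matrices carry a ~1e-9-scale ridge; the HMM recursion
floors propagated priors at 1e-300 before taking logs; the Kalman gain is
frozen when the covariance recursion changes by < 1e-12; exact dwell/lockout
tie-breaks are integer-millisecond comparisons as described above.

## Known limitations

- The synthetic user and participant are idealized: no fatigue, no
  attention lapses, no spiking refractoriness, no correlated noise. Typing
  rates and click accuracies come out near the top of (or above) the range
  a human system produces; they are not calibrated to any person.
- Human performance values from real recordings are context, not targets;
  nothing in the package attempts to match them.
- The shared-PCA click/velocity interference at high SNR is left as-is; a
  supervised or family-separated front end would remove it but would no
  longer be the documented decoder.
- Display latency and frame timing are not simulated; the loop runs at the
  1-ms/15-ms cadences only.
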