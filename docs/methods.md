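# Methods

This note documents the models, conventions, and deliberately made choices
behind `gonogofmri`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic tests do and do
not establish.

## Behavioral model and trial taxonomy

A session is a sequence of blocks, each holding 25 "go" and 25 "no-go"
odor trials interleaved in randomized order. Valve openings are spaced by
onset-to-onset intervals drawn uniformly from [5, 12.5] s. Odor
concentration at the nose reaches steady state roughly 100 ms after the
final valve opens, so the stimulus onset used for reaction times and GLM
regressors is `valve_open_time + onset_latency` with `onset_latency =
0.1 s` (configurable; a sniff-locked onset — first inhalation after valve
opening — can be substituted by passing sniff-derived onsets, which the
lowpassed sniff trace supports).

Classification: the response window is [valve + 0.2 s, valve + 2.2 s].
Go trials with an in-window lick are Hits, otherwise Misses; no-go trials
with an in-window lick are False Alarms, otherwise Correct Rejections. A
CR with licks inside the *adjacency window* — [stimulus onset − 1 s,
window end + 1 s] — but outside the response window is demoted to the
Nuisance class (`adjacent_lick`), since a lick abutting the scoring window
contaminates the trial's hemodynamic interpretation without changing its
nominal outcome. The 1-s adjacency margin is a package choice (no standard
value exists); it is configurable. Misses whose only lick precedes the
window are tagged `random_lick`; the tag is retained in the trial table
but Misses and all censored trials pool into one Nuisance condition at the
GLM level, so the distinction does not affect the maps.

Per-block accuracy is (Hits + CRs) / scoreable trials, with Nuisance
trials excluded from numerator and denominator. Learning stages are the
first and last 10 blocks (naive/expert). Reaction-time tertiles take the
fastest and slowest ⌊n/3⌋ Hit trials per block, ties broken by trial
order; the floor rule keeps the fast and slow sets equal-sized and
disjoint, and blocks with fewer than three Hits contribute nothing. A
performance criterion (default 0.80) exists only as a stage label; no
analysis depends on it.

## HRF model and estimation

The kernel is a difference of two gamma densities in the canonical SPM
parameterization: shape = delay/dispersion, scale = dispersion, for both
the response (p1, p3) and the undershoot (p2, p4), with undershoot
amplitude 1/p5, onset shift p6, and length p7. The kernel is built at a
microtime resolution of 0.1 s and rescaled so its maximum is 1;
downsampling to the acquisition grid is point sampling at TR-bin starts.

The empirical target is an event-locked average: for each Hit onset, the
ROI-mean signal over the following 30 s, expressed as percent change
against the mean of the two pre-onset volumes, averaged over events.
Fitting minimizes the RMSE between the peak-normalized model sampled at TR
and the peak-normalized target. **Peak normalization is the single most
consequential convention here**: the scan compares response *shapes*,
leaving amplitude to the GLM betas. It is exposed as a flag
(`normalize=False` compares raw amplitudes). When multiple animals
contribute, the intended order is normalize per animal, then average.

Two scan strategies are provided. `full` evaluates the complete Cartesian
grid in lexicographic order (ties resolve to the lexicographically
smallest vector); it is exact but the full five-parameter grid has ~1.8e7
points, so it is practical only on restricted grids. `coordinate`
(default) sweeps p1→p2→p3→p4→p5 repeatedly until no parameter changes,
capped at 10 sweeps; on the restricted grids used in the tests it agrees
with the exhaustive scan. `shift_scan` is a one-dimensional scan over p6
against a fixed base kernel, ties toward the smallest shift; it captures
regions whose response is delayed relative to the reference region (the
olfactory bulb in this paradigm, best fitted at a 2-s shift).

## Motion quantification and censoring

Framewise displacement is the Power-style sum of absolute backward
differences of the three translations (µm) plus the three rotations
converted to arc length on a 5-mm sphere (a mouse-head scale; both the
formula and radius are conventions, exposed as parameters). A Hit/FA/CR
trial is censored into the Nuisance condition when the interval from valve
opening to the response-window end (2.2 s) overlaps any volume whose FD
exceeds the in-plane voxel diameter, 200 µm. The per-trial statistic is
the *maximum* FD over the overlapped volumes — the stricter of the
plausible readings. Censoring is idempotent, never rescinds a Nuisance
label, and is monotone in the threshold.

## GLM

Design: per condition, unit sticks at stimulus onsets on the 0.1-s
microtime grid, convolved with the kernel and sampled at TR. Nuisance
columns: six rigid-body parameters, CSF-mean and whole-brain-mean signals
and their backward-difference derivatives, and one intercept per
concatenated block. Conditions with no events yield all-zero columns that
are flagged and barred from contrasts. No prewhitening and no high-pass
filter are applied by default — the global/CSF regression carries the
low-frequency burden; this conservative choice shrinks response
amplitudes, particularly in somatomotor regions, and is the documented
trade-off of the approach. Voxelwise OLS uses the pseudoinverse;
df = volumes − rank. Contrast t maps cap numerically infinite values
(zero residual variance with a nonzero effect, as in noiseless synthetic
data) at a ±1e6 sentinel. The second level is a voxelwise one-sample t
across subjects (df = n − 1), with the same sentinel convention.
Thresholding is two-sided Benjamini–Hochberg over in-mask voxels followed
by removal of face-adjacent (6-connected) clusters smaller than the extent
(default 5 voxels); whole-mask, two-sided inference is the adopted
convention, and "negative" maps are the negated contrast. Smoothing is a
per-volume 3-D Gaussian with a single FWHM in µm converted to per-axis
sigmas in (anisotropic) voxel units.

## FIR ROI analysis and statistics

The FIR model places one delta regressor per post-onset TR bin per
condition (12 bins × 2.5 s = the 30-s kernel length), fitted jointly with
per-block intercepts on the ROI-mean time series, so overlapping responses
are separated by the model rather than by windowed averaging. The series
is scaled per block to percent of the block mean before concatenation.
Because the block mean includes task variance, the noiseless FIR estimate
equals the injected response divided by (1 + mean task signal) — an
inherent property of run-mean scaling, a fraction of a percent under
realistic designs; exactness tests assert against this model-implied
value. The peak-amplitude convention is the value at the third post-onset
bin (5.0–7.5 s).

Statistics: paired and one-sample t are computed from the textbook
formula with Cohen's d = t/√n; this formula reproduces the package's
worked-example set of paired comparisons. Zero-variance differences
return t = 0 when the samples are identical and a signed infinite
sentinel otherwise. The repeated-measures ANOVA computes each
within-subject effect from orthonormal contrast scores (Helmert), with
the Huynh–Feldt ε from the contrast-score covariance (capped at 1;
exactly 1 for 2-level effects, where sphericity holds trivially), the
ε-corrected p from F(ε·df1, ε·df2), and both classical η²
(SS_effect/SS_total) and partial η². Spearman's ρ uses average ranks for
ties; for n ≤ 10 the p-value is a permutation p (exhaustive for n ≤ 7,
seeded 20,000-draw otherwise) rather than the large-sample approximation.
Bonferroni levels are reported at 4 decimals (0.05/9 → 0.0056).

## Synthetic forward model

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Accuracy** follows a saturating exponential in the trial index,
  P(correct) = p_max − (p_max − p0)·exp(−rate·k), defaults p0 = 0.5
  (chance), p_max = 0.92, rate = 1/150 per trial — reaching criterion
  after a few hundred trials, with naive accuracy near chance and expert
  accuracy near 0.92.
* **Reaction times** are lognormal with the log-mean interpolated from
  log(1.0 s) to log(0.55 s) as learning progresses (σ_log = 0.25),
  truncated to the response window; licking is a 6 Hz pulse train of 1 s
  starting at the first lick, which justifies the threshold-crossing lick
  parser. Water delivery follows Hits at 50 ms.
* **Sniffing** is a 4 Hz sinusoid with sensor noise; in proficient trials
  the phase resets and the amplitude rises for 1 s after odor onset — the
  minimal structure needed to exercise lick-locked sniff averaging.
* **BOLD**: every voxel of a region carries the region's mean series,
  baseline × (1 + Σ_condition β·regressor/100) with the regressors built
  by the same convolution machinery the GLM uses; condition amplitudes
  default to the qualitative pattern of the paradigm (striatal Hit
  positive with VS strongest, striatal CR negative, hippocampal Hit
  negative and FA positive, olfactory bulb carried with a 2-s HRF onset
  shift). Each tissue voxel adds stationary AR(1) Gaussian noise
  (marginal SD 0.5% of baseline, lag-1 coefficient 0.4) and a
  random-phase cosine drift (zero-mean across realizations, so the
  expectation equals the noiseless prediction). Motion is a sum of slow
  sinusoids (~10 µm) with occasional 250 µm spikes. The phantom is a
  24 × 16 × 10 grid of 200 × 200 × 300 µm voxels holding disjoint
  box-shaped regions plus CSF.

What it does **not** emulate: optimized (rather than uniform) stimulus
schedules, EPI artifacts (distortion, signal dropout, spikes),
physiological noise beyond AR(1) + drift, spatial noise correlations,
within-region response heterogeneity, or inter-animal variability in the
HRF. Passing tests therefore establish the *correctness of the
computations* under the assumed generative structure — exact label
recovery, unbiased estimation, calibrated error rates — not robustness to
real-data violations of that structure.

## Numerical choices and degenerate inputs

Microtime dt = 0.1 s; TR must be an integer multiple of dt. Grid values
are rounded to 10 decimals to avoid floating-point drift in MATLAB-style
ranges. RMSE ties break lexicographically (smallest parameter vector,
smallest shift). Zero-variance fit targets, empty masks, zero-trial
conditions, and sub-Nyquist sniff sampling raise errors; a stage with no
usable Hit trials in the sniff average returns a flagged empty result
instead. Collinear FIR designs (possible under strictly periodic
interleaved schedules, which jittered designs avoid) are rejected with an
explicit error. Problem sizes used in the test suite — single-voxel
forward runs of 100–200 volumes, 100-seed Monte-Carlo recovery, 500-replicate
FDR nulls, and 1-block end-to-end pipelines on the default phantom — are
the package's desk-scale defaults, chosen so the entire suite runs in
seconds while leaving every estimator's sampling error small relative to
the tolerances asserted.

## Known limitations

Realignment, slice-timing correction, and atlas registration are out of
scope (inputs are assumed aligned; the generator produces aligned data
with known motion tables). HRF estimation at TR 2.5 s cannot distinguish
fine temporal structure; the onset-shift variant is a coarse accommodation
of regional timing differences, not a voxelwise HRF model. The
percent-signal-change convention (run-mean scaling) slightly attenuates
amplitudes as noted above. The Cohen's d convention (t/√n) matches paired
within-condition comparisons; alternative d definitions for
between-condition comparisons are not implemented.
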