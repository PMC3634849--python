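# Methods

`seizdyn` analyses the electrographic and behavioral dynamics of acute
lithium-pilocarpine seizures in rats, with a focus on how an intervention
(here, optogenetic inhibition of hippocampal pyramidal cells) changes the
time to seizure onset and the shape of early seizure development.  Because
per-animal recordings for this design are not publicly available, the
package ships a synthetic cohort generator that reproduces the statistical
structure the analyses assume; every analysis stage is exercised and
validated against that generator and against independent oracles.

## Recording model and standardisation

A `Recording` is a block of equal-length channel traces in µV with a
sampling rate, channel roles (left/right cortical screws, two hippocampal
contacts), and an event timeline (pilocarpine injection, light epochs,
pentobarbital).  Acquisition is assumed band-limited to 0.1–100 Hz at 256
or 512 Hz.  `standardize` resamples every recording to a common 512 Hz by
polyphase (exact rational) resampling — so the 3 s / 1.5 s / 1 s analysis
windows are sample-exact — and re-applies the acquisition band zero-phase
(4th-order Butterworth low- and high-pass, forward–backward).  Two
numerical choices matter:

* the 0.1 Hz high-pass has a transient of tens of seconds; it is applied
  with a 30 s pad and only to records at least three corner periods long
  (shorter inputs, which occur only in tests, are mean-centred instead);
* `standardize` marks its output, and re-standardising a marked recording
  at the same rate is the exact identity.  Re-filtering would re-attenuate
  the band edges, so idempotency cannot be achieved by filtering twice.

All analyses run on standardized recordings, with times re-anchored so the
pilocarpine injection is t = 0.

## Line-length features

Line length of a window is `sum_k |x[k] - x[k-1]|` — a cheap joint measure
of amplitude and frequency.  It is computed raw (not divided by the window
duration; windows have constant length so normalisation would not affect
comparisons) in sliding 3 s windows with 1.5 s overlap, dropping the
trailing partial window.

The *cumulative* line length from seizure onset over a fixed 25 min span is

    LL_cum[n] = ( Σ_{k=2..n} |x[k] − x[k−1]| ) / ( Σ_{k=2..N} |x[k] − x[k−1]| ),

an expanding-window running sum normalised by the total, so every non-flat
signal yields a monotone curve from 0 to exactly 1.  A seizure of constant
intensity traces the diagonal; a slowly building seizure is concave-up and
lies below it.  Curves are linearly interpolated onto a common 1 s grid
(1501 points) for group comparison.  Curves cut short (recording end or
pentobarbital) are computed over the available span, linearly
time-normalised onto the full grid, and flagged `truncated`.  A flat
segment (zero total line length) is a degenerate-input error rather than a
0/0.

Electrographic onset is detected from the windowed line-length track: the
pre-injection baseline (≥ 120 s) sets a threshold at baseline mean +
`k_sd`·SD (default 5), and onset is the start of the first window at or
after injection exceeding it for `hold_windows` (default 3) consecutive
windows.  These defaults are detector tuning, validated against the
generator's ground truth (median absolute error ≈ 9 s, well under the 30 s
contract); they are not estimates of any physiological quantity.

## Spectrogram and high-gamma power

Spectrograms use a short-time FFT with a 1000 ms Hamming window and 500 ms
hop; power is squared magnitude.  High-gamma band power (70–110 Hz, a
spiking surrogate) is computed over contiguous 5 s bins with a single
Slepian taper at time-bandwidth product 1, integrating the tapered
periodogram over the band (capped at Nyquist).  Note the acquisition
filter ends at 100 Hz, so on standardized data the band effectively
integrates 70–100 Hz; the upstream definition is kept and the truncation
is inherited from the bandwidth, not re-decided here.

Each light onset defines a baseline bin (the 5 s immediately preceding
light) and all subsequent bins are divided by it.  Group inference on a
bin across pulses/animals uses a two-sided Mann-Whitney U test of the
per-pulse bin powers against the per-pulse baseline powers, both expressed
relative to the mean baseline (a common monotone scaling, so the rank test
is unchanged).  Testing against a literal constant-1 baseline would make
the U statistic's null variance wrong (simulated type-I error ≈ 9 % at
nominal 5 %); the two-sample form is calibrated (measured 2.5 %, within
the conservative range expected of MWU at these sample sizes).

## Synchrony

Phase synchrony and cross-correlation are computed between electrode pairs
in 1 s windows with 0.5 s overlap on 2–50 Hz.

The phase-synchrony estimator decomposes both signals into 4 Hz sub-bands
(Butterworth band-pass, analytic signal via Hilbert transform) and, per
window, pools the phase-difference phasors across sub-bands and samples
with amplitude-product weights:

    PLV_w = | Σ_{b,t} z_x z_y* | / Σ_{b,t} |z_x| |z_y| .

Weighting was chosen over a plain average of per-band phase-locking values
because the plain average is dominated by empty bands: a shared narrowband
rhythm scores only ≈ 1/12 of its locking, and the small per-band sample
count inflates the null (≈ 0.39 for independent white noise).  The
weighted form keeps identical signals at exactly 1, is invariant to
per-channel amplitude scaling, follows the bands that carry power (a
common 10 Hz tone with small noise scores > 0.99), and has a low null
level (≈ 0.17) because phasors pooled across twelve sub-bands are
effectively independent.

Windowed cross-correlation takes the maximum-magnitude Pearson correlation
over lags within ±100 ms, computed on the overlapping part of the two
same-span windows at each lag, signed by the correlation at the maximizing
lag; positive lag means the second channel is delayed.  Zero-variance
windows are emitted as missing.  No significance testing is attached to
either measure; they are descriptive.

## Group statistics

Seizure-onset times are compared with classical one-way ANOVA.  Because
published cohort data exist only as mean ± SEM with n, the ANOVA also
accepts summaries, reconstructing sums of squares from mean, SD = SEM·√n
and n — this path is exact (tested equal to the raw-value path).
Versus-control comparisons are corrected by the step-down Sidak
(Holm-Sidak) method, `p_adj(i) = max_{j≤i} 1 − (1 − p(j))^(m−j+1)`
(delegated to statsmodels and cross-checked against a hand-rolled oracle).

Time-resolved group curves (cumulative line length; Racine scores) are
compared with a cluster-based permutation test: a pointwise two-sample
statistic per timepoint (pooled-variance t for continuous curves, a
tie-corrected rank-sum z for ordinal scores), two-sided thresholding at a
pointwise alpha (default 0.05), sign-homogeneous contiguous
supra-threshold runs as clusters, cluster mass = summed statistic, and a
max-|mass| permutation null over group-label reassignments.  Monte-Carlo
p-values use `(1 + #{null ≥ observed}) / (n_perm + 1)`; when all distinct
label assignments fit within the requested permutation count the null is
enumerated exhaustively and p-values are exact proportions (verified
against brute-force enumeration on 3-vs-3 problems).  Degenerate
timepoints (zero pooled variance) score 0 when the group means agree and a
large finite sentinel otherwise.  Family-wise error measured on 500 null
cohort simulations is at the nominal level (criterion threshold ≤ 0.07).

## Behavioral (Racine) curves

Racine scores (integers 0–5) in contiguous 30 s epochs are assembled per
group onto the union epoch grid; epochs beyond an animal's record are
missing and excluded pairwise from mean/SEM.  Epochs after pentobarbital
are dropped (`truncated_at`).  Group comparison delegates to the cluster
test with the rank-sum statistic; epochs not rated for every animal in
both groups are excluded from the test.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
surface.  Per subject (deterministically seeded by config seed and subject
index) it draws a ground-truth `SeizureProfile` and synthesises a
4-channel recording:

* 10 min pre-injection baseline; onset delay ~ Normal(printed mean,
  SEM·√n), truncated at 2 min post-injection.  Calibrated group means
  (minutes): sham control 15.2 (SEM 1.1, n 13), opsin-only control 17.3
  (1.3, 7), light-only control 16.3 (1.7, 8), experimental 21 (1.8, 16);
* background: 1/f ("pink") noise, σ = 50 µV per channel;
* pre-ictal transition, duration U(0.5, 3) min: biphasic spikes (15 ms
  Gaussian-derivative kernel, ≈ 11 Hz) at a rate ramping 1.5 → 8 /s and
  amplitude ramping 250 → 450 µV, shared across channels with hippocampus
  leading cortex by 25 ms;
* developed seizure: 20–50 Hz narrowband noise with a sigmoidal amplitude
  envelope `1 − exp(−(t − t1)/τ)` reaching ≈ 600 µV; τ = 30 s for
  controls, 300 s for the experimental group, which is additionally gated
  by remission epochs (Poisson 0.6/min over the first 10 min, duration
  U(15, 45) s, envelope × 0.15) — reproducing the slow, interrupted
  build-up seen under inhibition;
* high-gamma: 70–100 Hz noise (σ = 10 µV) on hippocampal channels,
  multiplied at each light onset by the suppression factor (0.3 for the
  experimental group) with instantaneous drop and 5 s exponential
  recovery, so only the first 5 s illumination bin is strongly reduced;
* Racine scores follow a sigmoidal severity that leads the EEG onset by
  U(1, 3) min, with severity time constant 240 s (controls) / 420 s
  (experimental) and ±1 epoch-level noise;
* illumination schedules: continuous from ≈ 8 min post-injection, or
  intermittent 1–2 min pulses with 1–3 min gaps from ≈ 7.4 min; a
  seizure-free pulse-session generator reproduces the 35 × (5 s on / 30 s
  off) protocol.

Recording length is onset + 26 min by default (a `duration_min` override
errors out if it cannot contain the drawn onset).  What the generator does
*not* emulate: electrode artifacts, drift, spike-wave morphology detail,
state-dependent background changes, pentobarbital effects on the EEG, or
any biophysics of light propagation beyond the fiber-tip irradiance
formula (power / core cross-section area).  Passing tests therefore show
that the pipeline recovers known structure of this class — onset shifts,
envelope-shape differences, band-power suppression — not that it is robust
to real-world artifacts.

For large calibration simulations the generator also emits the cumulative
line-length curve implied by a profile directly (background + spike +
oscillation path-length densities, with per-second lognormal noise),
skipping waveform synthesis.  These profile-implied curves match the
waveform-derived curves closely and make 500-run family-wise-error
simulations affordable; the acceptance script's cohort comparison always
runs the full waveform path.

## Problem sizes and reproducibility

Simulation-based checks use: 500 null cohorts (profile curves, 200
permutations each) for family-wise error; 20 profile-curve cohorts plus
one full-waveform 14-vs-16 cohort (1000 permutations) for sensitivity;
13- and 16-subject full-waveform cohorts for onset recovery; 50 pulse
sessions per arm for the high-gamma analysis.  All randomness flows from
explicit integer seeds through `numpy` `SeedSequence`s; cohort bundles are
byte-identical across re-runs with the same seed, and every report records
the seed and permutation count it used.

## Known limitations

* The experimental group's onset distribution is imposed, not emergent
  from the modelled inhibition; the generator reproduces described
  phenomenology, not mechanism.
* The 70–110 Hz band definition conflicts with the 100 Hz acquisition
  filter inherited from the recording system; power above 100 Hz is
  unavailable by construction.
* Onset detection assumes a stationary pre-injection baseline; it has a
  small positive latency (threshold crossing follows true onset by a few
  seconds), negligible relative to cohort-level tolerances.
* Connectivity measures are descriptive only; no null calibration is
  attached to their seizure-related changes.
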