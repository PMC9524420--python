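# Methods

## Problem

A steady-state visual evoked potential (SSVEP) speller presents M
flickering targets, each assigned a unique stimulation condition.  The
user fixates one target; the visual cortex phase-locks to its flicker,
and the EEG recorded over occipital sites carries power at the flicker
frequency and its harmonics.  The decoder identifies the attended
target, and system throughput is summarized by the information transfer
rate (ITR).

sskit implements the full loop with a synthetic signal generator in
place of human recordings: stimulus coding, forward simulation,
decoding, and simulated-online evaluation.

## Stimulus coding (codec)

Targets sit on a joint frequency-phase grid:

    f_n   = f0 + n * Δf
    φ_n   = (φ0 + n * Δφ) mod 2π,      n = 0 … M−1.

Defaults: M = 40, f0 = 8.0 Hz, Δf = 0.2 Hz, φ0 = 0, Δφ = 0.5π, giving
the standard 40-target grid spanning 8.0–15.8 Hz with a quarter-cycle
phase interval between adjacent targets.  All four grid parameters are
configurable (CLI flags `--f0/--df/--phi0/--dphi`).  The phase interval
set {0, 0.5π, π, 1.5π} arises naturally from Δφ = 0.5π.

The displayable stimulus waveform maps the sine code onto luminance as
`0.5·(1 + sin(2π f k/fr + φ))`, sampled at the display frame rate fr;
values lie in [0, 1] and average 0.5 over whole cycles.  Actual frame
scheduling and display hardware are out of scope.

Indexing is 0-based internally (display layers may add 1).

## Synthetic SSVEP epochs (synth)

The response model is a harmonic series phase-locked to the stimulus:

    s_c(t) = g_c · Σ_{k=1..H} k^(−d) · sin(2π k f t + k φ),

with H = 5 harmonics and decay d = 1 by default.  The k·φ harmonic
phase follows from a waveform delayed/advanced in time: shifting a
periodic signal shifts harmonic k by k times the fundamental phase.
Channel gains g_c encode the occipital topography: channels over or
near visual cortex (O1, O2, T5, T6, P3, Pz, P4) get gain 1.0, all
others 0.2, on a 21-electrode 10–20 montage sampled at 1 kHz with a
0.5–100 Hz acquisition band — the acquisition protocol the evaluation
emulates.

Background activity is Gaussian noise with a 1/f^α spectrum (α = 1 by
default), generated by spectral shaping of white noise and normalized
to unit variance per channel, with an optional 50 Hz mains sinusoid.
Noise is scaled per channel so that the realized signal/noise power
ratio equals `snr_db` exactly (the scaling uses the empirical powers of
the two components, so the calibration error is limited only by the
quantities being finite-sample estimates of the in-band ratio).
Channels with zero signal gain receive the mean noise level of the
active channels.  `snr_db = −inf` produces pure noise; `+inf`, a
noiseless response.

What the generator does *not* reproduce: volume conduction and
inter-channel noise correlation, response latency jitter and
inter-subject variability, blink/EMG artifacts, non-stationarity.
Consequently, passing tests demonstrate the correctness of the decoding
and evaluation machinery under the assumed signal model, not expected
performance on human EEG; published accuracies from real recordings are
not comparable targets.  A constant visual-latency parameter exists
(default 0 ms, i.e. the coded phase is embedded exactly).

Sessions are balanced (equal trials per target), shuffled
deterministically, with per-epoch child seeds spawned from the session
seed, so a whole session is bit-reproducible.

Default study conditions used by the evaluation and the acceptance
script: 40 targets, 2 trials per target (and a 4-target × 30-trial =
120-trial variant for protocol-level tests), 4 s raw trials truncated
to 0.5–4 s windows, snr_db = 0 for the main sweep.  Those sizes keep a
full leave-one-out sweep to tens of seconds on one CPU while the
accuracy estimates remain stable.

## Decoding (decode)

For candidate frequency f_m, the harmonic reference is

    Y_m = [sin(2π f_m t); cos(2π f_m t); … ; sin(2π H f_m t); cos(2π H f_m t)],
    t = 1/F, 2/F, …, P/F,

with H = 5 by default.  The canonical correlation ρ_m between the
epoch X (channels × samples) and Y_m is the largest canonical
correlation; the decision is f̂ = argmax_m ρ_m (ties broken toward the
lowest index, for determinism).

Numerics: covariance blocks Cxx, Cyy receive a relative ridge
ε = 1e−12 · trace/dim; whitening uses Cholesky factors and ρ is the
largest singular value of Lx⁻¹ Cxy Ly⁻ᵀ.  If a block is numerically
rank-deficient the Cholesky fails and the ridge is escalated to
1e−9 · trace/dim with a warning.  The tiny default ridge keeps the
in-span limits exact to ~1e−12 (ρ = 1 for self-correlation and for
noiseless sinusoids inside the reference span) while stabilizing short
windows.  An independent generalized-eigenproblem solver
(Cxy Cyy⁻¹ Cyx v = ρ² Cxx v via `scipy.linalg.eigh`) is kept in the
test suite as a cross-check, never used in production.

**Filter-bank CCA.**  The epoch is filtered into sub-bands (defaults:
lower edges 8, 16, 24, 32, 40 Hz, common upper edge 88 Hz, Chebyshev-I
zero-phase filters), CCA is run per band, and scores combine as
Σ_b w_b ρ_b², w_b = b^(−1.25) + 0.25 — the weighting conventional in
the filter-bank SSVEP literature, emphasizing the fundamental while
still crediting harmonic-dominated bands.  The reported per-target
score is normalized back to a [0, 1] scale.  Everything is
configurable via `FilterBankSpec`.

**Phase templates.**  A zero-phase template can be moved to phase φ by
a circular shift of round(((2π − φ) mod 2π)/(2π f) · F) samples, so
φ = 0 (or any multiple of 2π) is the identity.  Sub-sample shifts are
rounded to the nearest sample; at 1 kHz and grid frequencies the
rounding error is below 2π f/F ≈ 0.1 rad.  The template decoder
averages training trials per target (aligned through the shift rule),
and combines reference and template evidence with equal weight:
score = sqrt((ρ_ref² + ρ_template²)/2).  The equal weighting is a
design choice; no principled combination rule dominates at this model's
noise levels.  Plain CCA is the default decoder because it is
training-free.

## Evaluation (eval)

Each trial is truncated causally to its first round(L·F) samples for
each data length L in the sweep (default 0.5–4.0 s in 0.5 s steps; the
grid is configurable, and a 0.1 s grid below 1 s is the way to probe
short-window optima that fall between the default steps).  In template
mode the templates for each trial come from all remaining trials
(leave-one-out); the training-free CCA/FBCCA modes need no templates,
so cross-validation degenerates to per-trial scoring — the "simulated
online" protocol and the offline one coincide under causal truncation.

Bits per selection follow the Wolpaw formula

    B = log2 N + p log2 p + (1−p) log2((1−p)/(N−1)),

with 0·log2 0 = 0.  B has its global minimum, exactly 0, at chance
p = 1/N, and equals log2 N at p = 1; it is never negative.  The ITR is
B · 60/T bits/min with T = L + gaze-shift allowance.  The gaze-shift
default is 0.5 s — the conventional inter-selection refixation time in
SSVEP spellers; ITR scales as 1/T, so this single parameter moves every
reported rate, and it is exposed everywhere (`--gaze-shift`).

Aggregation across seeds/subjects reports mean ± sample standard
deviation.  A configurable accuracy threshold (default 0.90) flags
which data lengths reach criterion performance.

## I/O conventions

0-based sample indices, half-open [onset, onset+duration) intervals,
seconds as floats.  The epoch container is a directory with
`spec.json`, `codebook.csv` (+ JSON sidecar with grid parameters, full
float precision), an `epochs.csv` index, and one raw little-endian
float32 matrix per epoch (bit-exact round trip) or CSV.  Continuous EEG
can be read from European Data Format (EDF) files with an event table
(`onset_s,label[,duration_s,layout]`).  Stimulus layouts (e.g.
"AR-Pos1"…"AR-Pos4") are carried as epoch metadata tags with an
optional per-layout SNR offset in the simulator; no display geometry is
modeled.

One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage,))`, so stages are
individually reproducible and all derived seeds stay below 2³¹.

## Numerical and degenerate-input choices

- CCA requires more samples than total input rows; shorter windows
  raise a ValueError rather than returning an ill-conditioned ρ.
- The zero-phase band-pass uses a split design — order-8 Butterworth
  low-pass plus order-2 Butterworth high-pass, each forward-backward
  with Gustafsson initial conditions — because a combined IIR band-pass
  with a 0.5 Hz lower edge at 1 kHz rings across an entire short epoch.
  Steady-state attenuation one octave beyond either cutoff exceeds
  40 dB; a small edge transient is unavoidable on finite epochs.
- Frequency collisions, sub-Nyquist frame rates and harmonics above
  Nyquist raise typed errors (`InvalidCodebookError`, `AliasingError`).
- Phases are stored wrapped to [0, 2π); comparisons in tests use
  circular differences.

## Known limitations

- The synthetic noise is spatially white (independent across channels);
  real EEG noise is spatially correlated, which CCA partially absorbs —
  simulated accuracies at a given SNR are therefore optimistic.
- The ITR formula assumes i.i.d. selections and no error correction.
- Template decoding on truncated windows uses circular shifts, exact
  only when the window holds whole stimulus cycles.
- Layout effects are reduced to an SNR offset; no claim is made about
  physical stimulus placement.
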