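# Methods

This note records the models `protodyn` implements, the conventions and
defaults it fixes where several were defensible, and what the synthetic
generators do and do not emulate.

## Signal model and preprocessing

Recordings are uniformly sampled scalar series (potential in mV at 1 Hz
in the motivating experiments; capacitance in F; impedance in Ω). The
`TimeSeries` carrier enforces a strictly increasing, constant-step time
axis (uniformity checked to 1e-9 relative) and finite values after
missing-value handling. Missing CSV cells are marked, then interior
gaps are linearly interpolated and leading/trailing gaps held at the
nearest finite value — the minimal extension of NaN-aware averaging to
a complete series.

Baseline subtraction averages the first 10 s of the recording (samples
flagged as originally missing are excluded from the mean) and subtracts
that constant; the operation is idempotent. Multiple recordings are
compared after linear interpolation onto the time axis of the longest
one, with endpoint clamping outside a series' native span — the
behaviour of `np.interp`, which keeps values at shared time points
exact. Outliers are flagged at 1.5×IQR beyond the quartiles; quartiles
use the linear-interpolation convention throughout the package.

## Oscillation statistics

- **Amplitude** is the range max − min of the analysed segment. This is
  deliberate: the tabulated amplitudes in the motivating data equal the
  difference of the tabulated extrema exactly.
- **Dominant frequency** is the argmax of a Welch PSD excluding the DC
  bin, on linearly detrended segments (Hann taper, 50% overlap, segment
  length min(4096, n/4) rounded down to a power of two). The averaged
  periodogram trades frequency resolution (one bin = fs/nperseg) for
  variance reduction; tests accept peak placement within one bin.
- **CV** uses the sample SD (denominator n−1), matching the descriptive
  statistics convention (mean ± SD) used for the tables.
- Phase-resolved CVs over hand-segmented activity phases are not
  reproduced: the phase boundaries are a property of the raw recordings.

## Spectral estimation

Welch defaults everywhere: Hann taper, 50% overlap, linear detrend per
segment, 1024-point segments at 1 Hz (frequency resolution
≈ 0.0009766 Hz). These keep Parseval consistency — Σ PSD·Δf within 5%
of the signal variance — which is the criterion that fixed the taper
and overlap among the standard choices.

The power-law fit regresses log₁₀PSD on log₁₀f by OLS over a fixed
band, default 0.01–0.5 Hz; only strictly positive PSD points enter, at
least three are required, and the slope's standard error comes from the
OLS covariance. The slope is invariant under amplitude scaling (the
intercept absorbs it). Spectrograms convert the magnitude-squared STFT
to dB re 1 (unit)²/Hz with a −120 dB floor guarding empty cells; total
energy is the double Riemann sum Σ PSD·Δf·Δt and scales quadratically
with amplitude.

Magnitude-squared coherence uses shared Welch segmentation for the
cross- and auto-spectra and refuses single-segment input (MSC from one
segment is identically 1). For independent signals the expected bias
level is ≈ 1/n_segments, which the tests use as the null reference.
Cross-correlation normalises each lag by its overlap length and reports
the argmax lag.

## Coherence metrics

Shannon entropy is computed from a 50-bin equal-width histogram over
[min, max] with probabilities pᵢ = countᵢ/n, reported in bits (log₂).
Probabilities come from counts, not density values: density×binwidth is
the probability, and the entropy of raw density values would not be
invariant under affine transforms of the data. Published entropy values
for the motivating recordings may reflect a different base or density
convention; they are not reproducible without the raw data and are not
asserted anywhere.

The QFI proxy is the classical surrogate F_Q(f) = 4·Var(V)·S(f) with
S(f) = 1/(2πf)² — strictly decreasing in frequency and linear in the
variance. (Published prose describes normalized QFI curves "rising" with
frequency; the defining equations are decreasing in f, and this package
implements the equations.) When a set of recordings is compared, every
curve is divided by the single global maximum over the whole set, so
the normalized peaks equal the variance ratios varᵢ/max_j var_j
independent of the grid — the convention fixed by the fact that the
published normalized peaks equal the squared SD ratios of the published
per-experiment SDs.

Hilbert analysis takes the discrete analytic signal; the envelope is
its modulus, the phase its unwrapped argument, and the phase variance
is computed after removing the best linear trend (otherwise it grows
without bound for any oscillation). Envelope accuracy degrades at the
edges; tests check the inner 80% of a tone.

## Stimulus codec and response modulation

Characters are transmitted MSB-first as eight bit slots (10 s each,
5 V for a 1) plus one 10 s pause after **every** character including
the last — that convention makes the total-duration formula
N_chars·(8·pulse + pause) exact. The effective input frequency is
1000/(8·pulse_ms + pause_ms) Hz ≈ 0.0111 Hz at the defaults. The
decoder thresholds each slot's mean at (v_high+v_low)/2 and refuses an
exact tie rather than guessing. Note the published total duration for
≈350 characters × 13 repeats (≈4.32×10⁸ ms) does not match the formula
(4.095×10⁸ ms); the package implements the formula.

Response modulation is memoryless gain: out(t) = nat(t)·[1 + k·V(t)],
applied after explicit common-axis alignment.

## Electrochemical models

Exponential decays are fitted by Levenberg–Marquardt nonlinear least
squares with a deterministic initialisation (offset ← min y when an
offset is fitted; y0 ← max y − offset; rate ← log-linear regression
slope over the positive part), a small set of rate-scaled restarts, and
a non-negative-rate re-fit if the unconstrained optimum has rate < 0.
Constant input returns a degenerate fit (rate 0, τ = ∞) with a warning
rather than an error. τ and k are exact reciprocals by construction.

The capacitance trajectory model is C(t) = C₀e^(−kt). (The differential
form dC/dt = −k(C−C₀) sometimes quoted alongside it is solved by a
different function; the exponential solution quoted with it solves
dC/dt = −kC, and that is what is implemented.) The memory fit computes
the biased sample autocorrelation (divide by n — the standard choice
for decay-fitting stability) of the mean-removed series over lags
0..n/4 and fits A·e^(−lag/τ) + C. For an AR(1) process with
coefficient φ this recovers τ = −1/ln φ; the sample-ACF tail is noisy
for τ comparable to n, so recovery claims are made for the
seed-averaged estimate.

Randles impedance uses the principal square root for the Warburg term.
With W = 0 the Nyquist locus is a semicircle of diameter Rct with apex
at the relaxation frequency f₀ = 1/(2πRctCdl). EIS summaries report
means/SDs of Z′, Z″, log₁₀|Z| and phase with 95% CIs as
mean ± 1.96·sd/√n; the Bode magnitude is reported explicitly as
log₁₀ Ω (published "mean |Z| = 3.69 Ω" is dimensionally log₁₀ Ω).

The early/late drift test is a pooled-variance (not Welch) two-sample
t-test — variance homogeneity was reported as verified for the
motivating data — between the first and last `split_fraction` of
samples, with Δ = mean(late) − mean(early).

## Boolean-gate extraction

Features are binarized by a single high-percentile threshold with the
≥ rule (value ≥ 75th-percentile threshold → 1), the rule the published
worked examples use; the 25th-percentile threshold is carried as
provenance only, since no published example shows it switching a state.
Binarization is monotone. XOR over five inputs is the left-fold chain
(((A≠B)≠(C≠D))≠E, identical to bit parity, and XNOR is defined as ¬XOR
("even number of true inputs"), resolving the ambiguous precedence of
the chained-equivalence notation. The published gate table contains one
internally inconsistent state assignment (a 20 Hz current above the
stated threshold mapped to 0) and thresholds that are not the
percentiles of the three printed currents; `binarize` therefore takes
explicit thresholds and `gate_panel` explicit states rather than
guessing the original rule.

## Synthetic data: what it does and does not emulate

`gen_colored_noise` synthesises noise in the Fourier domain — complex
Gaussian coefficients scaled by f^(−β/2), DC bin zeroed, inverse
transform, rescale to the target SD — giving the exact target spectrum
in expectation, simpler to verify than AR filtering.
`gen_oscillation` adds a single sinusoid, a constant baseline and an
optional linear drift (real recordings show slow trends but no
published drift law; linear is the one-parameter choice). Default
condition: 1 Hz sampling, 4096 s, f₀ = 0.06 Hz, 325 mV peak-to-peak —
mid-range of the observed 0.03–0.11 Hz / 297–485 mV — with β = 3.5
noise, mid-range of the observed slope magnitudes (≈3.1–3.8).

Not emulated: regime switching between active and quiescent phases,
hysteresis/non-stationarity across repeated runs, and any mechanistic
electrochemistry (redox cycling, charge trapping). Passing tests
therefore demonstrate correctness of the estimators on signals with the
assumed stationary structure, not validity of any claim about the
physical system.

## Problem sizes and tolerances

Slope-recovery checks use n = 2¹⁵ samples over 50 seeds per exponent
(±0.3 tolerance on a single fit; ±0.1 on the 50-seed ensemble mean of
the PSD). Exponential-fit recovery demands 1e-6 relative on noiseless
input and mean-unbiasedness within 3 standard errors over 50 seeds at
2% noise. The Randles semicircle identity is checked to 1e-9 relative.
These sizes keep the full suite under a few seconds on one core while
leaving each statistical check comfortably powered.

## Known limitations

- Published raw-data results (PSD slopes −3.84/−3.11/−3.24, MSC peaks
  0.90/0.85, entropies 2.60/2.84/2.90, t = 9.1758) depend on the
  deposited recordings; the package ships the loaders and estimators
  but verifies them by synthetic recovery, not by matching those
  numbers.
- The QFI proxy is not quantum Fisher information of any modelled
  quantum state; it is the published classical surrogate, computed as
  defined.
- Irregular sampling is out of scope: resample before analysis.
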