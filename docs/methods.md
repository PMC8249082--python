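# Methods

This note records the mathematical choices behind `physioconn` precisely
enough to reimplement them.

## Signals and preprocessing

A recording is a set of simultaneously sampled channels, each assigned
to an organ (`BRAIN`, `HEART`, `LUNGS`). Channels may arrive at
different rates (e.g., ECG at 2 kHz alongside 500 Hz EEG); they are
harmonized by low-pass filtering and integer decimation
(`lowpass_downsample`): a 4th-order digital (bilinear-transform)
Butterworth low-pass at 200 Hz, applied causally by default (a
zero-phase option exists), followed by sample picking. Channels already
at the target rate pass through untouched. The analytic magnitude of the
digital filter at frequency f is

    |H(f)| = 1 / sqrt(1 + (tan(pi f / fs) / tan(pi fc / fs))^8),

which the tests assert directly (for a 300 Hz tone at fs = 2 kHz,
|H| ≈ 0.163 — note this differs from the analog-prototype value
1/sqrt(1 + (f/fc)^8) ≈ 0.194).

EDF files are read through `mne`, with per-signal sampling rates taken
from a direct header parse so that mixed-rate files are read per rate
group rather than silently resampled on load. Delimited text with a
`# fs=` header line round-trips bit-exactly.

## Windowed MVAR model

Each recording is segmented into non-overlapping 10-s windows (trailing
partial windows are dropped and logged). Within a window, the demeaned
D-channel signal x(t) is modeled as

    x(t) = sum_{r=1..p} A_r x(t - r) + e(t),    e(t) ~ (0, Sigma),

with order p = 7 by default. Coefficients are estimated by OLS on the
lag-major stacked design (normal equations solved via Cholesky); the
noise covariance is RSS / (n_eff - pD). At the reference setting
(D = 6, fs = 500 Hz) a window carries 30,000 points for 252
coefficients. Fits with a singular Gram matrix raise and the window is
excluded (never imputed); fits whose companion-matrix spectral radius is
≥ 1 are kept but flagged and logged. Model-order sensitivity can be
checked with `order_sensitivity`, and AIC/BIC diagnostics are available.

## Squared GPDC

With the spectral transfer structure

    Abar(f) = I - sum_{r=1..p} A_r exp(-i 2 pi f r / fs),

the squared generalized partial directed coherence from source j to
target i is

    |pibar_ij(f)|^2 = (|Abar_ij(f)|^2 / sigma_i^2)
                      / sum_k (|Abar_kj(f)|^2 / sigma_k^2),

where sigma_k^2 are the residual variances. Consequences used as test
invariants: each source column sums to 1 over targets at every
frequency; the measure is invariant to rescaling any channel; and a
structurally absent coupling (A_r[i, j] = 0 for all r, i ≠ j) yields
exactly zero at all frequencies. The default grid is 1–200 Hz at 1 Hz.

## Per-value significance (ssGPDC)

Only values passing a per-value test at strict P < 0.05 ("ssGPDC") are
pooled into profiles, comparisons, and dynamics. Two backends:

**Surrogate (reference).** The null of no cross-channel coupling is
built by independently circularly shifting each channel by a uniform
offset of at least p samples, refitting, and recomputing GPDC; the
p-value is the add-one estimator p = (1 + #{null ≥ observed}) /
(1 + n_ok) over n = 99 surrogates by default (minimum 19). With 99
surrogates and a strict < 0.05 rule the finest attainable level is
4/100 = 0.04. If more than 20% of surrogate fits fail, the window is
excluded rather than tested on a thin null.

**Asymptotic (fast alternative).** Conditional on the regressors, the
OLS coefficients of an absent coupling are asymptotically normal with
covariance sigma_i^2 V_j (V_j the per-channel submatrix of the inverse
Gram matrix). |Abar_ij(f)|^2 is then a quadratic form in two jointly
normal variates — a two-term chi-square mixture whose survival function
is evaluated exactly via the polar integral

    P(Q > q) = (2/pi) ∫_0^{pi/2} exp(-q / (2 w(theta))) d theta,
    w(theta) = lambda_1 cos^2 theta + lambda_2 sin^2 theta,

with lambda_1,2 the eigenvalues of the 2×2 covariance of the real and
imaginary parts. This backend is this package's own construction; it is
validated against the surrogate backend (≥ 90% mask agreement on
testbed data) and against null p-value uniformity.

**Calibration.** Both backends are checked on independent white noise
(200 windows): the off-diagonal rejection fraction must lie in the 99%
binomial interval around 0.05 with effective count = windows × ordered
channel pairs — frequencies within a window are strongly dependent and
are deliberately not counted as independent draws. Measured fractions
are ≈ 0.040–0.050 for both backends.

## Bands, pooling, and profiles

Frequencies are grouped into 10-Hz bands, half-open on the left,
(0, 10], (10, 20], …, (190, 200]. Bands containing a multiple of 60 Hz
— (50, 60], (110, 120], (170, 180] — are excluded from all summaries,
leaving 17 retained bands. For an ordered organ pair, significant values
are pooled as a multiset over all its channel pairs × in-band
frequencies × windows × recordings; a band with no significant values
is reported as mean 0 ± 0 and flagged `zero_assigned` (this
conservative zero rule biases profiles of weakly coupled interactions
toward zero — by design, so that "no evidence of flow" reads as no
flow). The complementary `significance_fraction` table reports how much
of each pool was discarded.

## Group comparison

Pooled ssGPDC samples are compared with two-sided
Mann–Whitney–Wilcoxon rank-sum tests: exact enumeration when the
smaller sample has at most 8 values and there are no ties, the
tie-corrected normal approximation otherwise. Annotation: `*` for
p < 0.05, `**` for p < 0.001. Comparisons are run full-spectrum per
interaction, per retained band, and between interactions within a
group. **No multiple-comparison correction is applied by default** —
with 6 interactions × 17 bands the per-band table invites selective
reading; an optional Benjamini–Hochberg adjustment
(`benjamini_hochberg`) is provided for sensitivity analysis. Empty
pools make a comparison "not testable" rather than raising.

## Peri-event dynamics

For one interaction and band, each window contributes the mean of its
significant in-band values (0 when none, or NaN with `empty_as_nan`).
The band is chosen by the minimum rank-sum p between groups, ties
breaking toward the lower frequency. The series is smoothed with a
centered 9-point moving average (half-width k = 4, shrinking
symmetrically at the edges), so each smoothed point summarizes 90 s of
raw data at the 10-s window setting. Group-level mean ± SEM "reference
bands" of the pooled ssGPDC provide the backdrop. Event annotations are
pure metadata and never affect computation.

## Synthetic testbed

The generator defines each channel as an AR(2) resonator with center
frequency f0 and pole radius r (a_1 = 2 r cos(2 pi f0 / fs),
a_2 = -r^2) and adds directed couplings `strength * x_from(t - lag)`.
The implied ground-truth MVAR model is assembled exactly and rejected if
unstable; acyclic coupling graphs inherit stability from the AR(2)
poles and are simulated channel-by-channel with vectorized IIR
filtering, cyclic graphs through the sample recursion. Per-channel
output gains give physiologically flavored magnitudes (EEG ~100 µV,
ECG ~1 mV) and double as a standing exercise of GPDC scale invariance.

Scenarios: `WT_LIKE` (strong bidirectional brain⇄heart coupling,
moderate lung involvement), `KO_LIKE` (brain⇄heart weakened,
brain/heart→lungs elevated), and `KO_SEIZING` (KO_LIKE with 80-s
epochs every 300 s during which brain→lung coupling is further
elevated, confined to the first 60% of the recording). Effect sizes are
chosen so that the designed group differences reach p < 0.001 within
360 windows (1 h per group).

One readout subtlety: near a source's resonance the GPDC column
saturates (the source's own diagonal term of Abar vanishes), so
coupling-strength changes are best read off-resonance, where the
coupling entry of Abar has constant magnitude; the seizure example and
tests use 140–150 Hz for the 40-Hz-source brain→lung coupling.

## Limitations

- The MVAR model is linear and stationary within a window; nonlinear or
  fast-nonstationary coupling is at best partially captured.
- GPDC is column-normalized: it measures *relative* outflow shares of a
  source, so a change in one target's coupling moves other targets'
  values too.
- The zero rule for empty bands biases weak interactions toward zero;
  use `significance_fraction` and `empty_as_nan` to audit.
- No multiple-comparison correction by default (see above).
- Surrogate p-values have resolution 1/(n_surrogates + 1); with 99
  surrogates the strict P < 0.05 rule operates at an attainable level
  of 0.04.
- Group comparisons treat pooled values as exchangeable; values from
  the same window or recording are correlated, so p-values overstate
  independent evidence when few recordings are pooled.
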