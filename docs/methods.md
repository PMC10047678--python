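# Methods

`nlhrv` tests short-term heart-rate-variability (HRV) series for nonlinear
dynamics. The pipeline is: quality control of the beat-interval series,
linear HRV indices, phase-space reconstruction, recurrence quantification,
and a surrogate-data hypothesis test whose null hypothesis is a *linear,
possibly nonstationary* stochastic process. This note documents the models,
the parameters that matter, and the design decisions taken where more than
one defensible choice existed.

## Input model and preprocessing

The unit of analysis is a beat-to-beat (RR) interval series in
milliseconds, roughly 300 s / 250–450 beats per recording. Ectopic beats
and detection artifacts are replaced by an adaptive filter: a running mean
`mu` and running absolute deviation `sigma` are updated beat by beat with
exponential coefficient `c = 0.05`; a beat is replaced by the current `mu`
when it deviates from `mu` by more than `z * sigma + 20 ms` (default
`z = 3`). The 20 ms basal tolerance prevents flagging in very-low-variance
recordings; the exponential update tracks slow physiological trends so they
are not mistaken for ectopy. After replacement the series is called an NN
("normal-to-normal") series. Records are excluded when total duration is
below 300 s or more than 5% of beats were replaced; both thresholds are
config-exposed.

## Linear indices

Time domain: meanNN, SDNN (sample SD, n−1 denominator), SDSD (sample SD of
successive differences). Frequency domain: the NN series is cubic-spline
interpolated against cumulative beat time, resampled at 3 Hz, and analyzed
with a segment-averaged periodogram (300-sample Hamming windows, 50%
overlap, per-segment mean removal only — no detrending, so VLF content is
not altered). Band powers integrate the PSD with each FFT bin assigned to
exactly one band: VLF < 0.04 Hz (DC excluded), LF 0.04–0.15 Hz, HF
0.15–0.4 Hz, total = (0, 0.4]. Defining total over (0, 0.4] makes
normalized units complementary by construction:
`LF(n.u.) = 100·LF/(total − VLF)`, and LF(n.u.) + HF(n.u.) = 100. LF, HF
and LF/HF are natural-log transformed before group testing. Records with
`total − VLF ≤ 0` or `HF = 0` are flagged rather than propagated.

## Embedding

The delay `tau` is the first significant local minimum of the average
mutual information (AMI), estimated from a 2-D histogram with equiprobable
marginal bins, `B = ceil(N^(1/3))` per axis — deterministic and stable at
N ≈ 350. Histogram AMI wobbles by a few percent between adjacent lags, so
a local minimum is accepted only when the curve rises above it by more than
5% of the curve's range within the next 5 lags; with no such minimum the
fallback is `tau = 1` (the correct answer for strongly chaotic maps, whose
AMI decays monotonically). The dimension `m` is chosen by the Kennel
false-nearest-neighbor criterion (`r_tol = 10`, `a_tol = 2`) as the first
`m` with FNN fraction ≤ 1%; for noisy stochastic series the fraction often
never reaches 1% and the fallback is the scan maximum `m = 10` — acceptable
because the FAN recurrence criterion below adapts its tolerance to the
embedding. Scan ranges are `max_lag = 50` beats and `max_m = 10`, covering
physiological HRV time scales at ≈ 1 beat/s. Series are not z-scored
before embedding; the FAN criterion is invariant to uniform rescaling.

## Recurrence quantification

Recurrence plots use the fixed-amount-of-neighbors (FAN) criterion: column
`i` marks the `k = round(0.07 · N')` Euclidean-nearest neighbors of point
`x_i` (self included), so the matrix has fixed density 0.07 and is
asymmetric. Ties at the k-th distance break toward the smaller index,
making the construction deterministic; the implementation is verified
exactly against a brute-force k-NN oracle. Determinism (DET) is the
fraction of recurrence points on diagonal lines of length ≥ 2, laminarity
(LAM) the fraction on vertical lines of length ≥ 2. The line of identity
is kept in the matrix (FAN always self-recurs) but diagonals within a
Theiler window `w = 1` of it are excluded from DET, so self-identity does
not count as determinism; `w = 0` reproduces toolbox variants that keep it.
Verticals are counted over the full matrix (standard practice; exposed).

## Surrogate data

**IAAFT** iterates (a) imposing the original's Fourier amplitude spectrum
on the current phases and (b) rank-ordering values onto the original's
sorted amplitudes, until the rank ordering is a fixed point (or 1000
iterations); ending on (b) makes the amplitude multiset exactly equal to
the original's. This realizes the null of a stationary linear Gaussian
process observed through a static monotone transform.

**PWIAAFT** extends the null to nonstationary linear processes. The series
is decomposed with an undecimated, energy-preserving wavelet transform
(least-asymmetric Daubechies filter of width 8, reflection boundary,
`J = floor(log2 N) − 2` levels; at N = 350, J = 6). The coarse smooth —
fluctuations slower than 2^J beats, which carry the trend — is always
retained. Detail coefficients are ranked by energy and the top fraction
`rho = 0.01` is pinned (held fixed); within each detail scale a cubic
Hermite interpolant through the pinned coefficients is subtracted, the
residual is IAAFT-randomized, and pinned coefficients are restored exactly.
After inverse transform, a full-series IAAFT pass *seeded by the
reconstruction* (not by a random permutation) restores the global amplitude
spectrum, which scale-wise randomization alone distorts; because the
iteration starts at the trend-preserving reconstruction it converges to a
nearby fixed point and the slow structure survives (30-beat moving-average
correlation with the original ≈ 0.9 on trended fixtures, vs ≈ 0 for plain
IAAFT). `rho = 1` pins everything and returns the original; `rho = 0`
still retains the smooth, which is what makes the method robust at the
small default `rho`. The depth J trades off how much slow structure the
null preserves: shallower transforms freeze more of the series and make
the surrogate ensemble too tight (small biases then produce extreme ranks),
deeper ones lose the trend; J = log2(N) − 2 sat at the best calibration in
our experiments. Surrogate `j` of an ensemble with root seed `s` uses seed
`s + j`, so ensembles are byte-reproducible.

At N = 350 the relative RMS discrepancy between original and surrogate
periodograms at the IAAFT fixed point averages ≈ 0.9% for both generators
(individual runs scatter up to ≈ 1.6%); this is the well-known accuracy
floor of ending on the amplitude-adjustment step and shrinks with series
length.

## The nonlinearity decision rule

The discriminating statistic (DET or LAM) is computed on the original and
on 99 surrogates; embedding parameters are selected once on the original
and reused for every surrogate, so the statistic compares dynamics at a
fixed reconstruction. If the original ranks in the lowest or highest five
of the 100 values it is classified nonlinear — a two-sided test at nominal
level 0.10. Ties take the rank least favorable to rejection. Cohort
proportions of nonlinear series carry exact Clopper–Pearson 95% intervals
(verified against a binomial tail-sum bisection oracle); pre/post
proportions can be compared by Pearson chi-square (as commonly reported)
or McNemar's exact test (the appropriate paired analysis — both provided).
Repeated-measures comparisons of index means are implemented as paired /
unpaired t-tests with Bonferroni adjustment, which is equivalent to the
full repeated-measures ANOVA machinery for a 2-group × 2-moment layout.

## Synthetic data: what it emulates and what it does not

All generators are seed-deterministic, clamp output to 200–2000 ms, and
write/read losslessly through the package's file formats.

- `ar_null`: Gaussian AR(2) with coefficients (1.2, −0.4), rescaled to a
  target mean and SD (defaults 882 and 33.9 ms). These coefficients give
  the damped-oscillatory autocorrelation typical of resting HRV and imply
  SDSD/SDNN ≈ 0.53, close to observed resting ratios.
- `transformed_ar_null`: `exp(0.5 z)` of the standardized AR — a static
  monotone transform, still inside the surrogate null.
- `nonstationary_ar_null`: AR plus a deterministic trend in the mean
  (default: linear ramp, 150 ms peak-to-peak ≈ 4.4 × SDNN — a strong but
  physiologically plausible drift over five minutes; sigmoid shape and
  slow variance modulation are options). Linear but nonstationary: the
  case a stationarity-assuming test misclassifies.
- `threshold_ar_alt`: two-regime AR switching on the previous value;
  default lower regime (1.2, −0.4), upper regime (−0.7, −0.1), threshold
  +0.8 SD. Crossing into the upper regime triggers fast mean reversion,
  producing intermittent bursts — genuinely nonlinear dynamics with
  detection power well above the test's nominal level at N = 350. With
  switching disabled it reduces exactly (same seed, same output) to
  `ar_null`.
- `map_modulated_alt`: the RR mean driven by a chaotic logistic-map
  sequence (r = 3.9, weight 0.8) mixed with AR noise; strongly nonlinear.
- the cohort emulator: 68 paired pre/post records whose between-subject
  meanNN and SDNN moments match a short-term pre/post-angioplasty cohort
  (pre 882 ± 149 / 33.9 ± 17.9 ms; post 856 ± 134 / 23.8 ± 13.1 ms), with
  pre/post correlations (0.73 for meanNN, 0.6 for SDNN) chosen so paired
  changes have realistic spread, and metadata with fixed counts (20/68
  prior infarction, 27/68 female). A configurable fraction of subjects
  (default 0.3, matching the observed prevalence of detectable
  nonlinearity) gets threshold-AR dynamics.

The generators emulate the *statistical* structure real recordings impose
on this pipeline — marginal moments, short-range autocorrelation, slow
nonstationarity, regime-switching nonlinearity — but not respiratory sinus
arrhythmia's coupling to breathing, baroreflex feedback loops, or true
measurement artifacts. Passing tests therefore demonstrate correctness and
calibration of the algorithms, not clinical validity on patient data; the
cohort emulator makes no claim of reproducing recurrence values of real
cohorts (those depend on the actual cardiac dynamics).

## Numerical choices and degenerate inputs

- FAN ties (exactly equal distances, e.g. constant series) break toward
  the smaller index; a constant series yields an all-ones first-k-rows
  matrix by that rule.
- Zero-variance series are rejected by both surrogate generators with a
  clear error; zero-variance paired differences in the t-test return
  t = 0, p = 1 (identical) or ±inf, 0 (pure shift).
- AMI of a constant series is an all-zero curve, flagged with a warning.
- Empty line histograms make DET/LAM undefined (NaN), flagged rather than
  silently zero.
- Problem sizes used in validation: 350-beat series; 200 null series for
  the type-I check; 100 nonstationary series for the robustness
  comparison; 100/200 randomized instances for the exact oracle
  equivalence checks. These sizes give binomial confidence bands tight
  enough to detect meaningful miscalibration while keeping the whole
  suite's runtime modest.

## Known limitations

- The type-I calibration of the PWIAAFT-based test is approximate:
  original and surrogates are not exactly exchangeable (the surrogates
  share the original's wavelet smooth), and the test runs a few points
  conservative on stationary nulls at N = 350.
- FAN-based DET/LAM are only mildly sensitive to slow trends (the
  per-column tolerance adapts to local density), so the false-positive
  inflation of stationarity-assuming surrogates — the phenomenon PWIAAFT
  removes — is moderate at these series lengths.
- The FNN criterion rarely reaches zero on noisy stochastic series; the
  resulting fallback to m = 10 is conventional but means m is effectively
  fixed for such records.
- QRS detection and beat annotation are out of scope: the package starts
  from interval series.
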