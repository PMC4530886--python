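# Methods

`erpagree` studies how much single-trial detectors of somatosensory
event-related potentials (ERPs) agree with each other and with a known ground
truth. It implements two automated detectors taken from the literature on
vertex (Cz) potentials evoked by electrical stimulation of the lower limb,
a synthetic study generator, and the full categorical/quantitative agreement
framework used to compare detection methods.

## The signal model behind the simulator

Each epoch spans −200…+1800 ms around the stimulus at a configurable sampling
rate (2048 Hz by default, matching typical recordings). Three peaks are
modelled as Gaussian bumps:

| peak | polarity | mean latency | HWHM (default) |
|------|----------|--------------|----------------|
| N1   | −        | 90 ms        | 20 ms          |
| N2   | −        | 140 ms       | 25 ms          |
| P2   | +        | 250 ms       | 60 ms          |

The N1/N2 half-widths are deliberately large enough that the two negative
deflections overlap without a zero crossing between them, as they do in real
vertex recordings — this overlap is what makes single-trial N1/N2 separation
hard and drives the design of both detectors.

Per trial at intensity factor `x` (in units of the reflex threshold RTh,
six levels 0.50…2.00):

* presence ~ Bernoulli(logistic(a + b·x)); the default intercepts/slopes give
  average detection fractions of roughly 0.80 (N1), 0.57 (N2) and 0.93 (P2),
  increasing with intensity — chosen once for qualitative realism, since
  per-intensity presence rates of real recordings are not published;
* amplitude magnitude = base + slope·x + Gaussian jitter (truncated at
  0.25 µV so polarity is never inverted); defaults put mean magnitudes near
  18 µV (N1/N2) and 22 µV (P2);
* latency = mean + Gaussian jitter (SD 10–15 ms).

Background noise is white + AR(1) (corner 8 Hz), scaled to a total SD of
5 µV, approximating 0.5–30 Hz-band EEG. A single integer seed fans out into
per-subject substreams (`numpy.random.SeedSequence.spawn`), so whole studies
and individual subjects are reproducible.

What the generator does **not** emulate: multi-channel topography, eye/muscle
artifacts, non-Gaussian peak shapes, latency–amplitude coupling, habituation
across blocks. Tests passing on this generator show the algorithms and the
statistics behave as specified; they do not certify detector accuracy on real
EEG.

## Preprocessing

Epochs are band-passed 0.5–30 Hz with a 4th-order Butterworth applied
forward–backward (zero phase, so latencies are not shifted), then
baseline-corrected by subtracting the pre-stimulus mean. Because a 0.5 Hz
high-pass has an impulse response comparable to the 2 s epoch, the filter
uses maximal odd-reflection padding and per-trial demeaning; even so, on
zero-noise traces the residual ~4% ringing can create sub-µV local extrema.
The pipeline therefore allows skipping the filter (`bandpass_hz=None`) for
synthetic data that is in-band by construction; noiseless exactness checks
run that way.

## DRIV: derivative + fuzzy-zone detector

All local maxima/minima are found at sign changes of the first difference
(plateaus count once, at their midpoint sample). Three fuzzy zones — centered
on the N1/N2/P2 latencies of the subject's average ERP, with half-widths
±35/±35/±70 ms — weight each candidate by

    w(t) = 1 − ((t − c)/(b_side − c))²,

1 at the center, 0 at and beyond the boundaries. Per zone, the candidate of
correct amplitude sign maximizing |amplitude|·w is selected (ties go to the
earlier latency). If one minimum wins both negative zones it is assigned to
the zone with the nearer center and the other zone is re-searched; a zone
with no admissible candidate reports the peak absent. There is no amplitude
floor: small noise extrema of the right sign inside a zone are reported as
peaks, which is why detector-vs-truth κ degrades quickly with noise.

When the average ERP's N1/N2 merge into a single trough, no local minimum
exists for one of the zones; the zone center then falls back to the windowed
polarity-constrained extremum (search windows 50–125 / 115–210 / 180–400 ms).

## WVLT: wavelet filtering + regression estimator

1. Complex Morlet CWT, ψ̂(f) = exp(−π² f_b (f − f_0)²) with f_b = 0.05 and
   f_0 = 6, evaluated in the frequency domain with zero padding, on a linear
   0.5–30 Hz grid in 0.5 Hz steps (the pre-filter band). The cone of
   influence is not masked.
2. Across-trial mean power is thresholded at a fraction of its maximum
   (default 0.05) into a binary mask.
3. The mask multiplies each trial's coefficients; the trial is reconstructed
   by delta reconstruction (Σ over scales of Re W/a^{3/2} Δa). Because that
   operator is diagonal in the Fourier domain, its known frequency response
   is divided out (floored at 5% of its maximum), which makes the
   reconstruction exact in-band: the all-ones mask returns the in-band input.
4. From the filtered average ERP, two regressors per peak are built — the
   average restricted to the zero-crossing-bounded segment containing the
   peak latency, and its first derivative. N1/N2 usually share one negative
   segment, so the regression runs twice (pass A: N1+P2, pass B: N2+P2).
5. Each filtered trial is fitted by ordinary least squares; features are read
   off the fitted trace as the correct-polarity extremum in a window centred
   on the average-ERP latency (±25 ms for N1/N2, ±100 ms for P2; the N1/N2
   windows are additionally capped at the midpoint of the two marked
   latencies so the two read-offs cannot land on the same sample). A peak is
   absent only when no sample of the correct sign exists in its window — a
   deliberately weak rule, mirroring the original method's tendency to report
   nearly every trial as containing a peak.

Parameter notes (all configurable): the mask threshold, the frequency grid
and the read-off windows are not published for the original implementation;
the defaults here were fixed once on design grounds. The read-off half-width
for N1/N2 is 25 ms because the two peaks are 50 ms apart — a ±50 ms window
would include the neighbouring trough. For noiseless validation runs the mask
threshold is lowered to 0.02: the threshold's job is to sit above the noise
floor, and with no noise a 5% floor clips genuine N1/N2 support (their blob
power is an order of magnitude below the P2 maximum).

## Agreement framework

Categorical (per subject × peak, from the 2×2 presence table with a = both
present … d = both absent, N trials):

* p_o = 100(a+d)/N, p_pos = 100·2a/(2a+b+c), p_neg = 100·2d/(2d+b+c),
  p_e = 100[(a+b)(a+c)+(c+d)(b+d)]/N²;
* κ = (p_o − p_e)/(100 − p_e), floored at 0; undefined (NaN) when p_e = 100.
  Specific agreements with empty denominators are NaN.

Quantitative (both-present trials only; differences are undefined when one
method reports absence):

* Bland–Altman: bias = |mean difference|, LoA = |bias ± 1.96·SD(diff)|,
  reported as absolute values (the analysis concerns the size of the
  differences, not their sign);
* ICC(2,1): two-way absolute-agreement single-measure form from the ANOVA
  decomposition with k = 2 raters;
* CV: root-mean-square within-pair form, s_i² = (x_i−y_i)²/2,
  m_i = (|x_i|+|y_i|)/2, CV = 100·√mean(s_i²/m_i²). Magnitudes in the
  denominator keep negative-amplitude peaks well-defined; zero-magnitude
  pairs are dropped with a warning. The exact CV formula of the original
  analysis is not printed, so small deviations from published medians are
  expected.

`MethodAgreement(table_a, table_b).fit()` returns an `AgreementResults`
object carrying all indices per peak plus a `summary()` table.

## Group statistics

Friedman's test with tie correction (mean ranks within subjects,
χ² = [12/(nk(k+1)) Σ R_j² − 3n(k+1)] / C, C the standard tie factor; p from
χ²_{k−1}). The χ² approximation is accurate to ~0.02 only in the tail
(p < 0.15) at these sample sizes, which is where decisions are made; tests
compare it against an exact permutation-null enumeration there. Post hoc
comparisons use Student–Newman–Keuls on the Friedman mean ranks (the omnibus
test is rank-based, so the post hoc runs on the same scale), with
SE = √(k(k+1)/(12n)), studentized-range critical values at df = ∞, and the
SNK protection rule (a non-significant range closes its sub-ranges). Rows
with missing index values are dropped listwise with a warning. κ is floored
at 0 before entering any matrix.

Intensity effects: κ and CV recomputed per subject × intensity (≈20 trials
per stratum) and tested across the six intensities within a pairing.

## Pipelines and reproducibility

`run_simulated_study` chains simulate → band-pass/baseline → DRIV + WVLT →
per-subject agreement for TRUTH–DRIV, TRUTH–WVLT, DRIV–WVLT → Friedman/SNK
across pairings and across intensities, and writes CSV/JSON reports stamped
with a configuration hash and the seed; identically seeded runs are
byte-identical. `run_s1_reproduction` applies the same agreement/statistics
stage to four per-method detection containers (MAT v5, one j×10 array per
subject: N1/N2/P2 latency, amplitude, presence, intensity code) covering the
six pairings of two human observers and the two algorithms, including the
per-method summary table (per-subject means over detected trials, then
mean ± SD across subjects; a pooled-trials variant is emitted alongside
because the published aggregation is ambiguous).

Problem sizes: the test suite and `scripts/acceptance.py` run the study at
512 Hz sampling — the full 0.5–30 Hz analysis band is retained with a quarter
of the samples — with the protocol-sized design (16 subjects × 6 intensities
× 20 trials) in the acceptance script and smaller studies in unit tests.

## Numerical conventions and edge cases

* Plateau extrema: midpoint sample; integer midpoint rounds down.
* Score ties within a fuzzy zone: earlier latency wins.
* N1/N2 conflict with equal center distances: assigned to N1.
* Degenerate average with no zero crossing anywhere: whole-epoch regressor
  segments.
* Rank-deficient regression designs raise an error naming the pass.
* Friedman with every row fully tied: χ² = 0, p = 1.
* Exactness tests (detector recovers simulator truth to one sample / 1e-9 µV)
  use zero-noise, zero-jitter configurations with narrow, effectively
  non-overlapping bumps on a sampling grid containing the template latencies;
  with the default overlapping widths the superposed extremum genuinely
  shifts by a few milliseconds, which is a property of the signal, not of the
  detectors.

## Known limitations

* DRIV has no amplitude floor, so under noise its presence calls saturate
  toward "present"; this matches the original design but caps achievable κ
  against ground truth.
* WVLT reports a peak absent only on a polarity violation, so its
  detected-peak counts are near the trial count — the characteristic
  behaviour the agreement analysis is designed to expose.
* When N1 and N2 merge completely in the filtered average, the two-pass
  regression yields distinct but adjacent latency estimates; the method
  cannot resolve what the data do not contain.
* The container reader accepts plain numeric arrays (and single-field struct
  wrappers); exotic MAT layouts may need manual conversion.
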