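# Methods

This note documents the models, statistics and numerical choices behind
`circadam`, and what its synthetic-data validation does and does not show.

## Time conventions

Experiment time is measured in hours from ZT0 (lights-on) of day 0.
Zeitgeber time is `zt = h mod 24`; in constant darkness the same modular
clock is read as circadian time (CT), anchored to the projected lights-on of
the preceding entrainment. All ZT windows are half-open `[start, end)`, so
the minute at exactly ZT12 or ZT24 — where light-driven startle (masking)
activity occurs — belongs to the *following* window and never enters an
anticipation numerator or denominator. In the morning-anticipation formula,
"ZT0" as a window endpoint is read as ZT24, the lights-on boundary of the
same day.

## DAM data model

Counts are per-fly, per-minute beam crossings. Missing readings (invalid
status codes, timestamp gaps) are represented as NaN and propagate: a 30-min
bin containing a missing minute is missing; an averaged profile minute uses
only the days on which that minute was observed (with the per-minute n
tracked). Treating dropped readings as zeros would deflate anticipation
denominators and bias rhythm statistics, so it is never done.

**Survivor filter.** Flies that die during the analysis window must be
excluded, but the conventional wording ("only flies surviving the whole
period") does not pin down a criterion. The rule used here: a fly is dead
iff its counts are all zero from some minute through the end of the window
and that terminal zero run lasts at least `death_run_hours` (default 24 h —
a live fly essentially never produces a full silent circadian day in a DAM
tube). The threshold is configurable and recorded in every report. The
filter is idempotent and each fly's verdict is independent of the others.

## Anticipation indices

`MA = Σ act ZT[21,24) / Σ act ZT[18,24)` and
`EA = Σ act ZT[9,12) / Σ act ZT[6,12)`, computed per fly on its averaged
day (minute-by-minute average of the selected LD days — by default the last
three — before any binning). 0.5 means uniform activity over the 6-h
window; > 0.5 means a rising ramp toward the transition. Indices are
undefined (NaN, excluded from tests) when the denominator window holds no
activity. Group inference is a two-sided one-sample t-test against 0.5 over
per-fly indices. Computing indices per fly and testing across flies (rather
than scoring the genotype-average profile) is the default because it yields
a well-defined sampling unit; the profile-level alternative can be obtained
by passing the group-mean profile to the same function. Zero-variance
samples are handled explicitly (t = 0, p = 1 at mean 0.5; degenerate flag
otherwise). Genotype comparisons use a pooled-variance t-test for two
groups and one-way ANOVA with Tukey HSD for three or more (scipy /
statsmodels implementations behind the package's interface).

## χ² periodogram and the rhythmic/arrhythmic call

For an equally binned series (default 10-min bins over DD days 1–6) and a
candidate period of P bins, bins are folded modulo P into phase columns with
counts K_h and means M_h, and

    Q_P = Σ_h K_h (M_h − M̄)² / σ̂²,   σ̂² = (1/N) Σ_i (x_i − M̄)².

Candidates are every integer number of bins in 16–32 h. All N bins are used
(uneven folds weighted by K_h) rather than truncating to complete cycles;
truncation discards up to one cycle of data for no inferential gain.
Missing bins are excluded from the column statistics.

**Calibration of the verdict.** Classically Q_P is referred to the
χ²(P−1) quantile. Two facts matter for the rhythmicity *call*, which asks
whether *any* candidate exceeds its line:

1. The ~100 candidate folds are nearly independent under white noise, so an
   uncorrected per-period α = 0.05 line yields a family-wise false-positive
   rate near 100% — an arrhythmic fly would almost always be called
   rhythmic.
2. The exact null of Q_P/N is Beta((P−1)/2, (N−P)/2) (Q is N times the
   ANOVA R² of the fold); the χ² approximation is conservative in the far
   tail, so a Bonferroni-corrected χ² line over-corrects (measured ≈1%
   family-wise error).

The default significance line is therefore the exact-Beta quantile at the
Šidák-corrected per-period level `1 − (1 − α)^(1/m)`, which puts the
measured family-wise type-I error of the call at ≈4–5% for α = 0.05 —
matching the nominal error rate the classification claims. The classical
per-period χ² line (`correction="none"`) and the Bonferroni-χ² variant
remain available, e.g. to reproduce legacy software output; the correction
used is recorded in every result.

**Period estimate.** Among exceeding candidates the peak is the maximal
*excess* Q − threshold, not raw Q, because the line rises with period and a
raw-Q argmax is biased long; ties break toward the shorter period. The
estimate's resolution is one bin width (10 min = 0.167 h by default).
Constant series are degenerate (σ̂² = 0): Q ≡ 0, not rhythmic.

Percent rhythmic is reported over *survivors* (flies passing the death
filter), and period mean ± SEM over rhythmic flies only. Period shifts
between genotypes are differences of group means with
SEM(Δ) = √(SEM₁² + SEM₂²) plus a two-sample t-test.

## Cycling quantification

Neuron intensity = mean of the brightest 3×3 pixel block fully inside the
ROI (exhaustive over all positions; block means use contiguous-slice
reductions so results are bit-identical to the definition). Three
backgrounds scored the same way are *averaged* and subtracted — averaging is
the symmetric way to combine three equivalent estimates of one background
level. Corrected intensities may be negative; clamping at zero would bias
damping amplitudes downward. Multiple neurons of one cluster in one brain
should be averaged to a single per-brain value before statistics, matching
the per-brain n convention of such experiments.

Time/genotype dependence: two-way factorial ANOVA with interaction;
balanced designs reduce to the classical sums-of-squares decomposition and
unbalanced designs use Type-II sums of squares (identical when balanced).
Empty design cells make the interaction inestimable and raise an error
naming the cells. Damping amplitude of a brain collected at the peak
timepoint (maximal per-timepoint mean) is its value minus the minimum
per-timepoint mean; when genotypes peak at different times the
genotype-specific peak is used by default (`peak_timepoint` overrides).
Amplitudes are compared across genotypes with the same t-test/ANOVA
machinery as the anticipation indices.

## Synthetic data: what it emulates

Activity counts are inhomogeneous Poisson with rate (counts/min)

- LD: baseline + morning ramp `m·exp((zt−24)/τ_r)` + evening ramp
  `e·exp((zt−12)/τ_r)` for zt < 12 + startle pulses for
  `startle_width_min` after each light transition;
- DD (rhythmic): baseline + `A·max(0, cos(2π(t − φ₀)/τ))` — a rectified
  cosine, so activity bouts are non-negative and the waveform has the
  bout-like shape of free-running locomotion;
- arrhythmic: baseline (startle kept in LD — masking is clock-independent);
- dead: zero from the death day onward.

Defaults (baseline 2/min, ramp amplitudes 4/min, ramp e-folding 3 h,
startle 10/min for 10 min, DD amplitude 4/min, τ = 24 h) give daytime
activity levels, anticipation ramps and signal-to-noise in the range of
healthy wild-type flies in DAM tubes; the 2:1 DD amplitude-to-baseline
ratio is a strong but realistic free-running rhythm. Exponential ramps
terminating at the transitions produce MA/EA > 0.5 by construction, which
is the phenomenology the indices were designed to capture. Fluorescence
time-courses are `mesor + amplitude·(1−damping)^(t/24)·cos(2π(t−acrophase)/24)`
plus Gaussian noise, 5 brains per 6-h timepoint by default.

Populations spawn per-fly random streams from a single seed, so results are
bit-reproducible and insensitive to fly order. Generators record their
ground truth (rhythmic flag, τ, death day, spot centers/peaks) alongside the
data.

**What passing the synthetic validation does not show.** Real DAM data have
sleep-bout microstructure, temperature sensitivity, inter-fly rate
heterogeneity and slow trends that the Poisson model lacks; real confocal
intensities have spatially structured background and scan-session effects.
The validation demonstrates that the *statistics are computed correctly and
are calibrated under their stated assumptions* — not that those assumptions
hold for any particular recording.

## Validation battery and problem sizes

The acceptance script and test suite run the battery at these sizes, chosen
to keep Monte-Carlo error well below the decision margins: 1000 arrhythmic
flies for false-positive calibration (binomial SE ≈ 0.7% around 5%);
3 × 32 flies for period recovery (grid resolution 0.167 h vs the ±0.25 h
margin); 1000 + 200×32 flies for anticipation calibration and 200 groups
for power; 100 replicates of 100-fly mixtures; 200/1000 replicates for
ANOVA power/type-I; 100 random images against the exhaustive ROI oracle.

## Known limitations

- Single-beam DAMSystem3 dialect only; multi-beam and environmental-sensor
  channels are out of scope (a plain-CSV reader covers interchange).
- No Lomb–Scargle/MESA/autocorrelation periodograms and no cosinor phase
  estimation; the χ² periodogram and max−min amplitudes are the implemented
  conventions.
- Neuron segmentation is out of scope: ROIs (masks) are taken as given on
  user-supplied 2-D sections or projections.
- No cross-scan-session intensity normalization; samples are assumed
  scanned under constant settings.
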