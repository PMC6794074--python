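# circadam

Analysis of *Drosophila* circadian behavior and clock-gene cycling.

Chronobiology labs record fly locomotor activity with Trikinetics
*Drosophila* Activity Monitors (DAM): 32 flies per monitor, one infrared
beam-crossing count per fly per minute, typically several days of a 12 h:12 h
light–dark cycle (LD) followed by constant darkness (DD). The same
experiments are usually paired with immunostaining or in-situ hybridization
of the ~75-per-hemisphere clock neurons, quantified as fluorescence
intensities over a 6-h collection grid. `circadam` implements the standard
analysis chain for both data types:

- **DAM I/O** — parse and write DAMSystem3 monitor files, fill gaps as
  missing (never zero), bin counts, and drop flies that die during the
  analysis window (terminal all-zero run ≥ 24 h by default).
- **Daily profiles & anticipation** — per fly, average the minute-by-minute
  activity of the last three LD days, bin into 48 half-hour ZT bins, and
  score morning/evening anticipation as

  `MA = Σ act ZT[21,24) / Σ act ZT[18,24)`,  `EA = Σ act ZT[9,12) / Σ act ZT[6,12)`,

  tested against the no-anticipation value 0.5 with a one-sample t-test and
  compared across genotypes with a pooled t-test or one-way ANOVA + Tukey HSD.
- **Rhythmicity in DD** — the Sokolove–Bushell χ² periodogram
  `Q_P = Σ_h K_h (M_h − M̄)² / σ̂²` over candidate periods 16–32 h
  (10-min bins, DD days 1–6), with a significance line calibrated for the
  scan across candidates; per-genotype percent rhythmic, free-running period
  τ ± SEM over rhythmic flies, and period shifts vs control.
- **Cycling quantification** — neuron intensity as the brightest fully
  in-ROI 3×3 pixel block mean, minus the mean of three backgrounds scored the
  same way; per-timepoint mean ± SEM, genotype × time two-way ANOVA, and
  per-brain damping amplitudes (value at the peak timepoint minus the
  minimum per-timepoint mean).
- **Synthetic data** — Poisson activity with anticipation ramps, startle
  (masking) spikes, a rectified-cosine DD oscillator of period τ, arrhythmic
  flies and fly death; damped-cosine fluorescence time-courses; Gaussian
  spot images. Every generator records its ground truth, so the whole chain
  is validated against known answers.

## Worked example

```python
import numpy as np
from circadam import (FlySimParams, LightSchedule, simulate_population,
                      classify_fly, summarize_population, anticipation_indices)

sch = LightSchedule.ld_dd(5, 6)            # 5 days LD12:12, then 6 days DD
pop = simulate_population([FlySimParams(tau_h=23.5)] * 16, sch, 11, seed=1)

idx = anticipation_indices(pop.counts[0], sch, days=[2, 3, 4])
print(f"MA={idx.ma:.3f} EA={idx.ea:.3f}")

dd = slice(5 * 1440, 11 * 1440)            # DD days 1-6, per-minute
calls = [classify_fly(pop.counts[i][dd], fly_id=f) for i, f in enumerate(pop.fly_ids)]
s = summarize_population(calls, genotype="sim")
print(f"{s.percent_rhythmic:.0f}% rhythmic, tau = {s.period_mean_h:.2f} "
      f"+/- {s.period_sem_h:.2f} h")
```

prints

```
MA=0.618 EA=0.608
100% rhythmic, tau = 23.51 +/- 0.01 h
```

MA and EA above 0.5 show the simulated flies ramp up activity before
lights-on and lights-off, as entrained wild-type flies do; in DD every fly
is called rhythmic and the population period recovers the simulated
free-running period of 23.5 h.

The same analyses run from the shell: `circadam simulate` writes DAM files
with ground truth, `circadam run --config exp.yaml` produces the full report
bundle (survival, profiles, anticipation tests, rhythmicity calls and
summaries, actograms), and `circadam cycling --intensities tc.csv` produces
the cycling summary, two-way ANOVA and damping-amplitude tables.

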