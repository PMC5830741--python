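# stopchrono

Chronometry of response inhibition: a tested Python pipeline for asking
*when* — and in what order — cortical regions become active while a
person stops an ongoing action.

The package is aimed at cognitive neurophysiologists working with the
stop-signal task alongside source-level MEG ("virtual sensor") recordings
and chronometric TMS. It covers the full analysis chain:

- **Stop-signal behaviour.** An independent horse-race model (Go process
  vs Stop process) with a one-up/one-down SSD staircase that titrates
  stopping to 50%, calibration/feedback rules, and SSRT estimation by the
  integration method: SSRT = Q_Go(P(respond | stop)) − mean SSD, where
  Q_Go is the empirical Go-RT quantile function.
- **Temporal region of interest.** tROI = [SSD + 50 ms, mean Go RT − 50 ms],
  the window in which a cortical region can plausibly influence stopping
  after afferent and before efferent transmission delays.
- **Onset-latency quantification.** (Stop − Go) − Fixation contrast traces
  z-scored against the fixation baseline; evoked traces via a 30 Hz
  zero-phase Butterworth low-pass; induced traces via Hilbert amplitude
  envelopes (1 Hz steps, 8 Hz bandwidth) collapsed over a frequency band.
  A per-trace criterion level is found by incrementing in 0.5 SD steps
  while mean |z| ≥ level and max |z| ≥ level + 0.5 over the tROI; latency
  is the first tROI sample whose |z| reaches that level.
- **Band restriction.** Within broad α (6–13 Hz), β (14–30 Hz) and
  γ (31–130 Hz) ranges, every admissible sub-band is scored by a Gaussian
  peak fit *y = a·exp(−((x−b)/c)²)* to the tROI-collapsed spectrum; the
  score is adjusted R² × max |deflection|, and slope-shaped fits never
  beat genuine peaks.
- **Granger causal flow.** Bivariate VAR causal density
  F_{x→y} = ln(var(ε_y | own past) / var(ε_y | both pasts)), with
  ADF-tested differencing, BIC order selection on a bounded range, the
  Geweke frequency-domain decomposition for band-limited analyses, and
  trial-pairing permutation surrogates.
- **Bayesian inference.** Default-prior (JZS, Cauchy scale √0.5)
  one-sample/paired Bayes factors, informed half-normal and uniform
  priors on millisecond effects, default-prior correlation Bayes factors,
  and a sequential BF stopping rule.
- **TMS planning.** Distance-adjusted dosing (2.7 %MSO per mm of extra
  scalp–cortex depth, 110% of adjusted motor threshold, bounded to
  70–130% MT), comfort-threshold propagation across stimulation sites,
  pulse scheduling at 12.5% and 62.5% of the tROI on a 60 Hz refresh
  grid, and hemisphere-aware target aggregation.

A synthetic-data generator (`stopchrono.synthdata`) produces behavioural
trial tables and per-trial virtual-sensor epochs with *known ground
truth* (planted onsets, band-limited amplitude steps, constant SSRT), so
every downstream stage is testable without access to any recording.

## Worked example

```python
import stopchrono as sc

table = sc.simulate_race_trials(sc.RaceParams(), 360,
                                staircase=sc.StaircaseConfig(), seed=7)
s = sc.summarize_behavior(table)
troi = sc.compute_troi(s.mean_go_rt, s.mean_ssd)
print(round(s.mean_go_rt, 1), round(s.prop_stopped, 3), round(s.ssrt, 1))
print(round(troi.start, 1), round(troi.end, 1))
print(round(sc.jzs_bf(-0.857, 13), 3))
```

prints

```
421.6 0.508 204.9
251.2 371.6
0.381
```

That is: over a 360-trial staircased session the simulated participant
answered Go trials in 421.6 ms on average and stopped on 50.8% of stop
trials — the staircase converged on its 50% target — giving an
integration-method SSRT of 204.9 ms (the generator's true stop latency is
210 ms on average). Their tROI runs from 251.2 to 371.6 ms post-stimulus;
TMS pulses would be scheduled at the nearest screen refreshes to 12.5%
and 62.5% of that window (266.7 and 333.3 ms). The last line is the
default JZS Bayes factor for a paired t of −0.857 with n = 13: at 0.381
the data lean toward the null of no latency difference between regions.

A console script exposes the same calculators, e.g.:

```bash
stopchrono bf ttest --t -0.857 --n 13     # -> 0.381
stopchrono tms dose --mt 60 --d-target 14 --d-motor 12
stopchrono run --seed 0 --out results/
```

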