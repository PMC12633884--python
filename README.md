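# duotap

Simulation and analysis toolkit for *paired synchronized tapping*: a
coupled-oscillator "humanizer" that generates realistic two-player drum
sequences, surrogate and isochronous control stimuli, MIDI/WAV renderings,
and signal-detection scoring of listener judgments.

## The problem

When two musicians tap a beat together, each continuously corrects both the
*phase* (when the next tap falls) and the *period* (the underlying tempo) in
response to the partner's taps. This mutual timing adaptation leaves a
characteristic fingerprint in the paired inter-tap-interval (ITI) series: a
negative windowed detrended cross-correlation (WDCC) at lag 0 with positive
peaks at lag ±1, plus an emergent acceleration of the common tempo ("joint
rushing"). `duotap` exists for researchers who want to ask whether listeners
can *hear* this coordination structure: it produces matched stimulus classes
that differ only in cross-correlation structure, and the tooling to score a
two-alternative listening experiment around them.

## The model

Each player *i* is a noisy phase oscillator,

    dθᵢ/dt = ωᵢ + σᵢ ξᵢ(t),      dωᵢ/dt = 0,

integrated by Euler–Maruyama (dt = 1 ms). A player taps when θᵢ reaches 2π
(θᵢ then resets to 0). At that instant the partner *j* is corrected:

    θⱼ ← θⱼ + aⱼ Z(θⱼ)                                (phase correction)
    ωⱼ ← ωⱼ + bⱼ Y(θⱼ) − kⱼ (ωⱼ − ωⱼ(0))              (period correction + tempo rebound)

with pluggable response functions, default Z(θ) = Y(θ) = −sin θ (synchronous
partners receive no correction). Default gains a = 0.3, k = 0.3·b,
σ = 0.3, ω(0) = 2π / 0.5 s (500 ms interbeat interval), 36 taps per player.

Three stimulus classes are built on this model:

- **HUM** — 1000 simulated pairs; the 20 whose ITI-pair WDCC profile lies
  closest (summed squared difference) to the ensemble mean are kept.
- **RAN** — per HUM stimulus, the halved asynchrony series d = (t⁽¹⁾−t⁽²⁾)/2
  is randomly permuted and recombined with the untouched mean-timing series
  (t = m ± d_rand); of 1000 shuffles the candidate closest to the shuffle
  ensemble mean WDCC is kept. Asynchrony mean/SD are conserved *bit-exactly*;
  only the cross-correlation structure is destroyed.
- **ISO** — same machinery with σ = 0.01: near-metronomic attention checks.

Listener responses are scored with equal-variance signal detection theory
(d′ = z(H) − z(F), C = −(z(H)+z(F))/2, 1/(2N) correction for extreme
proportions), with screening rules for inattentive participants.

## Worked example

```python
import numpy as np
from duotap import (SimConfig, simulate_pair, generate_hum_set,
                    generate_ran_set, summarize_set, compute_iti,
                    compute_asynchrony, timeline_wdcc)

cfg = SimConfig.study_default(b=1.0, sigma=0.3, seed=7)
tl = simulate_pair(cfg)
iti = compute_iti(tl, 1).values
a = compute_asynchrony(tl).values
print(f"mean ITI {iti.mean():.2f} ms, SD {iti.std(ddof=1):.2f} ms")
print(f"mean asynchrony {a.mean():.2f} ms, SD {a.std(ddof=1):.2f} ms")

hum = generate_hum_set(cfg, reps=200, keep=20)
s = summarize_set(hum)
print("HUM group: SD ITI %.2f±%.2f, mean async %.2f±%.2f" %
      (*s.sd_iti_p1, *s.mean_async))
ran = generate_ran_set(hum, shuffles=200)
print("RAN mean async identical:",
      summarize_set(ran).mean_async == s.mean_async)
mp = hum.ensemble_mean_profile
print("ensemble WDCC lag -1,0,+1:",
      [round(mp.coefficient_at(l), 3) for l in (-1, 0, 1)])
```

prints

```
mean ITI 498.43 ms, SD 14.90 ms
mean asynchrony 0.01 ms, SD 15.78 ms
HUM group: SD ITI 17.90±2.08, mean async -0.25±1.08
RAN mean async identical: True
ensemble WDCC lag -1,0,+1: [0.139, -0.197, 0.176]
```

The single run shows millisecond-scale mutual fluctuation around the 500 ms
beat with near-zero mean asynchrony; the selected HUM ensemble shows the
mutual-adaptation WDCC signature (negative lag 0, positive lag ±1) and ITI
variability of ~18 ms; the RAN surrogates conserve the asynchrony statistics
exactly while scrambling that signature. Note the slight joint rushing: mean
ITI sits a few ms below the nominal 500 ms.

A CLI mirrors the library: `duotap simulate`, `duotap generate --class hum`,
`duotap export stim.csv --format wav`, `duotap score responses.csv`,
`duotap demo-listener`.

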