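# Methods

## Model and integration scheme

Paired tapping is modelled as two hybrid oscillators: continuous noisy phase
rotation (dθᵢ/dt = ωᵢ + σᵢξᵢ, dωᵢ/dt = 0) punctuated by discrete resets.
The integrator is fixed-step Euler–Maruyama with dt = 1 ms (≈1/500 of the
nominal 500 ms cycle); noise enters the phase only, as σ√dt·ξ per step with
ξ ~ N(0,1). A tap occurs when a player's phase crosses 2π within a step; the
crossing instant is located by linear interpolation of the within-step path,
the tapper's phase is set to exactly 0 there, and the remainder of the step
is integrated. The partner's state at the crossing instant (also obtained by
within-step interpolation, piecewise if the partner itself wrapped earlier
in the same step) receives the discrete correction
θⱼ ← θⱼ + aⱼZ(θⱼ), ωⱼ ← ωⱼ + bⱼY(θⱼ) − kⱼ(ωⱼ − ωⱼ(0)). If a correction
pushes the partner past 2π, the wrap counts as a tap of the partner. When
both players cross in one step, player 1's event is processed first; the
order is configurable (`tap_order`) and has no measurable effect at default
parameters because Z(θ)≈0 near the synchronous fixed point.

Convergence of this event scheme is verified by dt-halving in the noiseless
coupled regime (tap-time changes < 1 ms). With noise, halving dt changes the
realized Brownian path, so pathwise comparison is not meaningful; the
distributional statistics are insensitive to dt at this resolution.

### Degenerate runs

Two failure modes abort a run rather than being silently repaired, since
clamping would bias timing statistics: (i) a period correction driving
ω ≤ 0; (ii) tap counts diverging by more than one (runaway
desynchronization, only possible in the uncoupled noisy limit, ~0.05% of
runs there). Ensemble generation redraws such runs with fresh seeds beyond
the base seed range, up to a retry cap.

### Response functions

The phase/period response functions Z and Y are pluggable via a registry.
The default −sin θ is the simplest smooth correction with the required fixed
point at θ ∈ {0, 2π}: a late partner (θ just below 2π) is advanced and sped
up, an early one retarded and slowed. Empirically estimated human response
functions are asymmetric; with the symmetric default the model nevertheless
reproduces the qualitative phenomenology — the lag-0-negative / lag-±1-
positive WDCC signature that deepens with b, and joint rushing of a few ms
(group mean ITI ≈ 494–496 ms at σ = 0.3 against the nominal 500 ms).

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| a | phase-correction gain | 0.3 | per player, dimensionless |
| b | period-correction gain | 1.0 | study levels 0.5 / 1.0 / 1.5 |
| k | tempo-rebound gain | 0.3·b | pulls ω back to ω(0) |
| σ | phase-noise strength | 0.3 (HUM), 0.01 (ISO) | rad·s^−1/2 |
| ω(0) | initial angular velocity | 2π/0.5 s | 500 ms interbeat |
| n_taps | taps per player | 36 | t = 0 is tap 1, so 35 ITIs |
| dt | integration step | 1 ms | |

Internally time is seconds; every reported statistic is milliseconds.

## Reproducibility

Each run draws from its own `numpy` Generator seeded `base_seed +
run_index`; ensembles are simulated vectorized across runs but consume the
per-run streams in fixed-size chunks, so any member re-simulated alone with
its seed is bit-identical to the ensemble result. Recorded tap times are
snapped to a dyadic grid of 2⁻³¹ s (≈0.5 ns — far below any physical or
perceptual scale). This makes the RAN recombination m ± d exact in IEEE
double arithmetic; combined with correctly-rounded summation (`math.fsum`)
in the descriptive statistics, shuffled surrogates conserve asynchrony
mean/SD bit-for-bit, not merely to rounding error.

## WDCC

Window length 15 intervals, step 1 (fully sliding), lags −10..+10, linear
least-squares detrend per window, Pearson correlation of residuals,
averaged across windows per lag. These window settings are the package's
choice, made so that lag ±10 remains computable on 35-interval series; all
three are exposed as keyword arguments. Sign convention: positive lag l
pairs x at window position n with y at n + l (y lagging x) — the reported
lag ±1 peaks depend on this convention. Windows whose detrended segment has
(numerically) zero variance are excluded from the average and counted, not
imputed; a lag with no valid window raises rather than returning a silent 0.
This matters only for degenerate, exactly-linear inputs — ISO stimuli at
σ = 0.01 retain ample residual variance.

## Stimulus pipeline

HUM: 1000 simulated pairs, per-pair WDCC of the two ITI series, selection of
the 20 pairs with the smallest summed squared deviation from the
ensemble-mean profile (ascending-distance ranks; rank 1 is most typical).
RAN: per source HUM, 1000 random permutations of the halved asynchronies
recombined with the conserved mean-timing series; non-monotone candidates
are discarded (never observed at default parameters, but the contract is
total); the candidate closest to the shuffle-ensemble mean is kept — one
RAN per HUM, which is the only construction consistent with RAN and HUM
having identical group asynchrony statistics. ISO: the HUM machinery at
σ = 0.01, keeping 10. Example/practice stimuli are the ranks {1, 5, 10, 15,
20}, spanning the set's distance range.

## Audio export

MIDI: Standard MIDI File format 1, one tempo track (500 ms/beat) plus one
track/channel per player, note 38 (GM acoustic snare), velocity 100,
PPQ 960, note-on ticks rounded (≈0.52 ms quantization); a reader is included
so written files are verified by round-trip. WAV: 16-bit PCM stereo at
44.1 kHz; each player is a built-in synthetic percussive burst (decaying
tone + noise with a hard attack, distinct spectra per player so the two
virtual players do not fuse); onsets at the nearest sample; left channel
mixes players 1:2 at 4:1 amplitude, right channel the reverse, with weights
normalized so the mix cannot clip at default gain (clipping raises).

## Signal-detection scoring

Hit rate H = "human-like" responses to HUM / non-timeout HUM trials;
false-alarm rate F likewise for RAN; ISO is excluded from d′/C and serves
the screening rules instead (exclude a participant with ≥2 main-phase
timeouts or ≥2 ISO-"human-like" judgments). d′ = z(H) − z(F) and
C = −(z(H)+z(F))/2 after the 1/(2N) adjustment of proportions equal to 0
or 1 (needed because 15 trials/class makes extremes likely). The C sign
convention is the standard conservative-positive one implied by the
formula: a liberal observer (H = F = 0.9) scores C ≈ −1.28. The synthetic
listener draws evidence from N(±d′/2, 1) and answers "human-like" above a
fixed criterion; scoring recovers its generating (d′, C) in expectation,
which the tests verify by parameter recovery.

## Scale choices in the test suite

The shipped tests regenerate stimulus sets at a reduced ensemble scale
(60–200 runs) — enough for group statistics to stabilize within the stated
tolerances — while `scripts/acceptance.py` runs the full 1000-run protocol.
The reduced scale is a deliberate package default for its test suite, with
the full protocol a single command away.

## Limitations

- The synthetic generator reproduces study *conditions*, not human data: no
  fitted response functions, no inter-individual parameter variation, no
  motor-delay or feedback-latency terms.
- Exactly two players; no generalization to larger ensembles or continuous
  (Kuramoto-style) coupling.
- No spectral-slope (1/f^β) analysis: 35-interval series are far too short
  for reliable slope estimation.
- Audio uses synthetic bursts, not sampled drums or soundfonts; claims rest
  on timing, not timbre.
- The synthetic listener is an idealized equal-variance Gaussian observer —
  plumbing for end-to-end tests, not a perceptual model.
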