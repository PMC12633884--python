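"""Generation of the three stimulus classes: HUM, RAN and ISO.

HUM ("humanized") stimuli are coupled-oscillator simulations selected for a
consistent mutual-adaptation structure: an ensemble of runs is simulated,
each run's ITI-pair WDCC profile is computed, and the runs whose profiles
are closest (sum of squared differences) to the ensemble-mean profile are
kept.

RAN ("randomized") stimuli are surrogates of HUM stimuli that destroy the
cross-correlation structure while conserving the marginal asynchrony
statistics exactly: the halved asynchrony series is randomly permuted and
recombined with the untouched mean-timing series,

    t_rand(1) = m + d_rand,    t_rand(2) = m − d_rand,

so the multiset of asynchronies (hence their mean and SD) is identical to
the source HUM stimulus.  Of many shuffles, the candidate closest to the
shuffle-ensemble-mean WDCC is kept (one RAN per source HUM).

ISO ("isochronous") stimuli use the same machinery as HUM with the phase
noise reduced to σ = 0.01, giving near-metronomic sequences used to catch
inattentive listeners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import PairTimeline, SimConfig, simulate_ensemble
from .stats import (
    DEFAULT_MAX_LAG,
    DEFAULT_WINDOW_LEN,
    DEFAULT_WINDOW_STEP,
    WDCCProfile,
    compute_iti,
    wdcc_batch,
)

logger = logging.getLogger(__name__)

HUM_KEEP = 20
RAN_KEEP = 20
ISO_KEEP = 10
DEFAULT_REPS = 1000
EXAMPLE_RANKS = (1, 5, 10, 15, 20)


@dataclass(frozen=True)
class Stimulus:
    """One selected stimulus with its selection metadata."""

    timeline: PairTimeline
    profile: WDCCProfile
    distance: float
    rank: int
    stimulus_id: str


@dataclass(frozen=True)
class ShuffleRecord:
    """Permutation applied to the halved-asynchrony series of a RAN surrogate."""

    permutation: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(perm.size)):
            raise ValueError("permutation is not a bijection on 0..n-1")
        object.__setattr__(self, "permutation", perm)


@dataclass(frozen=True)
class StimulusSet:
    """Labeled, rank-ordered collection of selected stimuli."""

    label: str  # HUM | RAN | ISO
    b_level: float
    stimuli: tuple[Stimulus, ...]
    ensemble_mean_profile: WDCCProfile
    base_seed: int
    config: SimConfig | None = None
    shuffle_records: tuple[ShuffleRecord, ...] = field(default=())

    def __post_init__(self) -> None:
        ranks = sorted(s.rank for s in self.stimuli)
        if ranks != list(range(1, len(self.stimuli) + 1)):
            raise ValueError("stimulus ranks must be a permutation of 1..K")

    @property
    def timelines(self) -> list[PairTimeline]:
        return [s.timeline for s in self.stimuli]

    def by_rank(self, rank: int) -> Stimulus:
        for s in self.stimuli:
            if s.rank == rank:
                return s
        raise KeyError(f"no stimulus with rank {rank}")


def wdcc_distance(profile: WDCCProfile, reference: WDCCProfile) -> float:
    """Sum of squared per-lag differences between two WDCC profiles."""
    if not np.array_equal(profile.lags, reference.lags):
        raise ValueError("profiles have mismatched lag grids")
    return float(np.sum((profile.coefficients - reference.coefficients) ** 2))


def _profiles_of_timelines(
    timelines: list[PairTimeline],
    max_lag: int,
    window_len: int,
    window_step: int,
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([compute_iti(tl, 1).values for tl in timelines])
    Y = np.stack([compute_iti(tl, 2).values for tl in timelines])
    return wdcc_batch(
        X, Y, max_lag=max_lag, window_len=window_len, window_step=window_step
    )


def _select_closest(
    timelines: list[PairTimeline],
    keep: int,
    label: str,
    b_level: float,
    base_seed: int,
    config: SimConfig | None,
    max_lag: int,
    window_len: int,
    window_step: int,
    id_prefix: str,
) -> StimulusSet:
    coefs, n_win = _profiles_of_timelines(timelines, max_lag, window_len, window_step)
    if np.isnan(coefs).any():
        bad = int(np.isnan(coefs).any(axis=1).sum())
        raise ValueError(f"{bad} runs produced undefined WDCC coefficients")
    lags = np.arange(-max_lag, max_lag + 1)
    mean_coefs = coefs.mean(axis=0)
    mean_profile = WDCCProfile(
        lags=lags,
        coefficients=mean_coefs,
        window_len=window_len,
        window_step=window_step,
        n_windows=n_win[0],
    )
    dists = np.sum((coefs - mean_coefs) ** 2, axis=1)
    order = np.argsort(dists, kind="stable")[:keep]
    stimuli = []
    for rank, run in enumerate(order, start=1):
        stimuli.append(
            Stimulus(
                timeline=timelines[run],
                profile=WDCCProfile(
                    lags=lags,
                    coefficients=coefs[run],
                    window_len=window_len,
                    window_step=window_step,
                    n_windows=n_win[run],
                ),
                distance=float(dists[run]),
                rank=rank,
                stimulus_id=f"{id_prefix}{rank:02d}",
            )
        )
    return StimulusSet(
        label=label,
        b_level=b_level,
        stimuli=tuple(stimuli),
        ensemble_mean_profile=mean_profile,
        base_seed=base_seed,
        config=config,
    )


def generate_hum_set(
    config: SimConfig,
    reps: int = DEFAULT_REPS,
    keep: int = HUM_KEEP,
    base_seed: int | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
    label: str = "HUM",
) -> StimulusSet:
    """Simulate ``reps`` runs and keep the ``keep`` closest to the mean WDCC.

    Runs are ranked by the sum of squared differences between their ITI-pair
    WDCC profile and the ensemble-mean profile; ranks are ascending in
    distance (rank 1 = most typical of the ensemble).
    """
    if reps < keep:
        raise ValueError(f"reps ({reps}) must be >= keep ({keep})")
    if base_seed is None:
        base_seed = config.seed
    timelines = simulate_ensemble(config, reps=reps, base_seed=base_seed)
    return _select_closest(
        timelines,
        keep,
        label,
        config.params_p1.b,
        base_seed,
        config,
        max_lag,
        window_len,
        window_step,
        id_prefix=f"{label.lower()}_b{config.params_p1.b:g}_",
    )


def generate_iso_set(
    config: SimConfig,
    reps: int = DEFAULT_REPS,
    keep: int = ISO_KEEP,
    base_seed: int | None = None,
    **kw,
) -> StimulusSet:
    """ISO set: the HUM selection machinery at σ = 0.01, keeping 10."""
    sigma = config.params_p1.sigma
    if sigma > 0.05:
        raise ValueError(
            f"ISO generation expects near-zero phase noise (sigma={sigma})"
        )
    return generate_hum_set(
        config, reps=reps, keep=keep, base_seed=base_seed, label="ISO", **kw
    )


def randomize_stimulus(
    hum: PairTimeline,
    shuffles: int = DEFAULT_REPS,
    seed: int = 0,
    source_id: str = "hum",
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
) -> tuple[PairTimeline, ShuffleRecord]:
    """Asynchrony-shuffled surrogate of one HUM timeline.

    Draws ``shuffles`` random permutations of the halved asynchronies,
    reconstructs each candidate pair, computes its WDCC, and returns the
    candidate closest to the mean profile of all (monotone) candidates.
    The result's asynchrony series is exactly a permutation of the
    source's, and its mean-timing series equals the source's bit-exactly.
    """
    rng = np.random.default_rng(seed)
    t1, t2 = hum.taps_p1, hum.taps_p2
    m = 0.5 * (t1 + t2)
    d = 0.5 * (t1 - t2)  # halved asynchronies, seconds
    n = d.size

    perms = np.stack([rng.permutation(n) for _ in range(shuffles)])
    dr = d[perms]  # (S, n)
    c1 = m + dr
    c2 = m - dr
    mono = np.all(np.diff(c1, axis=1) > 0, axis=1) & np.all(
        np.diff(c2, axis=1) > 0, axis=1
    )
    n_bad = int((~mono).sum())
    if n_bad:
        logger.info(
            "discarded %d/%d non-monotone shuffle candidates for %s",
            n_bad,
            shuffles,
            source_id,
        )
    if not mono.any():
        raise ValueError(f"all {shuffles} shuffle candidates non-monotone")
    c1, c2, perms = c1[mono], c2[mono], perms[mono]

    coefs, _ = wdcc_batch(
        np.diff(c1, axis=1) * 1e3,
        np.diff(c2, axis=1) * 1e3,
        max_lag=max_lag,
        window_len=window_len,
        window_step=window_step,
    )
    mean_coefs = coefs.mean(axis=0)
    dists = np.sum((coefs - mean_coefs) ** 2, axis=1)
    best = int(np.argmin(dists))
    timeline = PairTimeline(c1[best], c2[best], seed=seed, config=hum.config)
    return timeline, ShuffleRecord(permutation=perms[best], source_id=source_id)


def generate_ran_set(
    hum_set: StimulusSet,
    shuffles: int = DEFAULT_REPS,
    base_seed: int | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
) -> StimulusSet:
    """One RAN surrogate per HUM stimulus (1000 shuffles each by default).

    Because every surrogate's asynchronies are a permutation of its source's,
    the RAN set's per-stimulus (and group) asynchrony mean and SD equal the
    HUM set's exactly.
    """
    if base_seed is None:
        base_seed = hum_set.base_seed + 7_000_000
    timelines: list[PairTimeline] = []
    records: list[ShuffleRecord] = []
    for i, stim in enumerate(sorted(hum_set.stimuli, key=lambda s: s.rank)):
        tl, rec = randomize_stimulus(
            stim.timeline,
            shuffles=shuffles,
            seed=base_seed + i,
            source_id=stim.stimulus_id,
            max_lag=max_lag,
            window_len=window_len,
            window_step=window_step,
        )
        timelines.append(tl)
        records.append(rec)
    ran = _select_closest(
        timelines,
        keep=len(timelines),
        label="RAN",
        b_level=hum_set.b_level,
        base_seed=base_seed,
        config=hum_set.config,
        max_lag=max_lag,
        window_len=window_len,
        window_step=window_step,
        id_prefix=f"ran_b{hum_set.b_level:g}_",
    )
    return StimulusSet(
        label="RAN",
        b_level=ran.b_level,
        stimuli=ran.stimuli,
        ensemble_mean_profile=ran.ensemble_mean_profile,
        base_seed=base_seed,
        config=hum_set.config,
        shuffle_records=tuple(records),
    )


def select_examples(stimulus_set: StimulusSet, ranks=EXAMPLE_RANKS) -> list[Stimulus]:
    """The five stimuli spanning the set's distance range (ranks 1,5,10,15,20)."""
    if len(stimulus_set.stimuli) != 20:
        raise ValueError(
            f"example selection requires a 20-stimulus set, got "
            f"{len(stimulus_set.stimuli)}"
        )
    return [stimulus_set.by_rank(r) for r in ranks]
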