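"""Event-driven simulation of the coupled-oscillator model of paired tapping.

Two players are modelled as phase oscillators with phase noise,

    dθ_i/dt = ω_i + σ_i ξ_i(t),      dω_i/dt = 0,

integrated with fixed-step Euler–Maruyama.  A player taps when its phase
reaches 2π; the phase is then reset to 0.  At that instant the *partner* j
receives a discrete correction

    θ_j ← θ_j + a_j Z_j(θ_j)
    ω_j ← ω_j + b_j Y_j(θ_j) − k_j (ω_j − ω_j(0))

where ``a`` is the phase-correction gain, ``b`` the period-correction gain
and ``k`` a tempo-rebound gain pulling the angular velocity back toward its
initial value.  The response functions Z and Y are pluggable; the default
``-sin`` has the fixed point Z(0) = Z(2π) = 0, so perfectly synchronous
partners receive no correction.

Times are seconds internally; reporting in milliseconds happens downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

#: Default interbeat interval of the stimuli, seconds.
DEFAULT_PERIOD = 0.5

ResponseFunction = Callable[[np.ndarray], np.ndarray]

#: Registry of named phase/period response functions.  Each maps a phase
#: array (rad) to a correction (rad for Z, rad/s scale for Y).
RESPONSE_FUNCTIONS: dict[str, ResponseFunction] = {
    "neg_sin": lambda theta: -np.sin(theta),
    "zero": lambda theta: np.zeros_like(theta),
}


def register_response_function(name: str, fn: ResponseFunction) -> None:
    """Register a custom response function under ``name``."""
    RESPONSE_FUNCTIONS[name] = fn


class DegenerateRunError(RuntimeError):
    """A simulation run left the model's valid regime.

    Raised when a partner reset drives ω ≤ 0, or when the two players'
    tap counts diverge by more than one (runaway desynchronization).
    Clamping instead of aborting would silently bias timing statistics.
    """


@dataclass(frozen=True)
class PlayerParams:
    """Per-player model parameters.

    Parameters follow the study defaults: ``a = 0.3``, ``k = 0.3 b``,
    ``sigma`` 0.3 (humanized) or 0.01 (isochronous), and an initial
    angular velocity of ``2π / 0.5 s`` (500 ms interbeat interval).
    """

    a: float = 0.3
    b: float = 1.0
    k: float = 0.3
    sigma: float = 0.3
    omega0: float = TWO_PI / DEFAULT_PERIOD
    phase_response: str = "neg_sin"
    period_response: str = "neg_sin"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.omega0 <= 0:
            raise ValueError(f"omega0 must be > 0, got {self.omega0}")
        if self.phase_response not in RESPONSE_FUNCTIONS:
            raise KeyError(f"unknown phase response {self.phase_response!r}")
        if self.period_response not in RESPONSE_FUNCTIONS:
            raise KeyError(f"unknown period response {self.period_response!r}")

    @classmethod
    def study_default(cls, b: float = 1.0, sigma: float = 0.3) -> "PlayerParams":
        """Parameters as used for stimulus generation: a=0.3, k=0.3b."""
        return cls(a=0.3, b=b, k=0.3 * b, sigma=sigma)

    @property
    def Z(self) -> ResponseFunction:
        return RESPONSE_FUNCTIONS[self.phase_response]

    @property
    def Y(self) -> ResponseFunction:
        return RESPONSE_FUNCTIONS[self.period_response]


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one paired-tapping simulation run."""

    params_p1: PlayerParams = field(default_factory=PlayerParams)
    params_p2: PlayerParams = field(default_factory=PlayerParams)
    n_taps: int = 36
    dt: float = 1e-3
    seed: int = 0
    t0_is_tap: bool = True
    #: processing order of same-step tap events (1-based player ids)
    tap_order: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if self.n_taps < 2:
            raise ValueError("n_taps must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        period = TWO_PI / min(self.params_p1.omega0, self.params_p2.omega0)
        if self.dt > period / 10:
            raise ValueError(f"dt={self.dt} too coarse for period {period}")
        if sorted(self.tap_order) != [1, 2]:
            raise ValueError("tap_order must be a permutation of (1, 2)")

    @classmethod
    def study_default(
        cls, b: float = 1.0, sigma: float = 0.3, seed: int = 0, **kw
    ) -> "SimConfig":
        p = PlayerParams.study_default(b=b, sigma=sigma)
        return cls(params_p1=p, params_p2=p, seed=seed, **kw)


@dataclass
class OscState:
    """Instantaneous oscillator state: phase (rad) and angular velocity (rad/s)."""

    theta: float
    omega: float


@dataclass(frozen=True)
class PairTimeline:
    """Paired tap-time series, seconds, one entry per tap per player."""

    taps_p1: np.ndarray
    taps_p2: np.ndarray
    seed: int
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taps_p1", np.asarray(self.taps_p1, dtype=float))
        object.__setattr__(self, "taps_p2", np.asarray(self.taps_p2, dtype=float))
        for name, taps in (("taps_p1", self.taps_p1), ("taps_p2", self.taps_p2)):
            if len(taps) >= 2 and not np.all(np.diff(taps) > 0):
                raise ValueError(f"{name} is not strictly increasing")
        if len(self.taps_p1) != len(self.taps_p2):
            raise ValueError("players must have equal tap counts")

    @property
    def n_taps(self) -> int:
        return len(self.taps_p1)

    def taps(self, player: int) -> np.ndarray:
        if player == 1:
            return self.taps_p1
        if player == 2:
            return self.taps_p2
        raise ValueError(f"player must be 1 or 2, got {player}")

    def swapped(self) -> "PairTimeline":
        """Timeline with the two players exchanged."""
        return PairTimeline(self.taps_p2, self.taps_p1, self.seed, self.config)


def step_phase(
    state: OscState, params: PlayerParams, dt: float, noise_draw: float
) -> OscState:
    """One Euler–Maruyama phase step: θ += ω·dt + σ·√dt·ξ; ω unchanged."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not np.isfinite(noise_draw):
        raise ValueError(f"noise draw must be finite, got {noise_draw}")
    theta = state.theta + state.omega * dt + params.sigma * math.sqrt(dt) * noise_draw
    return OscState(theta=theta, omega=state.omega)


def apply_partner_reset(state_j: OscState, params_j: PlayerParams) -> OscState:
    """Discrete correction applied to player j when the partner taps.

    Returns the corrected state *unwrapped*: if the phase kick pushes θ_j
    past 2π the caller treats the wrap as a tap of j.  Raises
    :class:`DegenerateRunError` if the period correction drives ω ≤ 0.
    """
    th = np.asarray(state_j.theta, dtype=float)
    theta_new = float(state_j.theta + params_j.a * params_j.Z(th))
    omega_new = float(
        state_j.omega
        + params_j.b * params_j.Y(th)
        - params_j.k * (state_j.omega - params_j.omega0)
    )
    if omega_new <= 0:
        raise DegenerateRunError(
            f"partner reset drove omega to {omega_new:.4f} <= 0 "
            f"(theta={state_j.theta:.4f}, omega={state_j.omega:.4f})"
        )
    return OscState(theta=theta_new, omega=omega_new)


# ---------------------------------------------------------------------------
# vectorized simulation engine
# ---------------------------------------------------------------------------

_NOISE_CHUNK = 1024  # steps of noise drawn per generator at a time

# Recorded tap times are snapped to a dyadic grid (multiples of 2^-31 s,
# ~0.47 ns).  Physically negligible, but it makes the surrogate algebra of
# the randomization pipeline (m ± d recombination) exact in IEEE double, so
# shuffled stimuli conserve the asynchrony multiset bit-for-bit.
_TIME_GRID = 2.0**31


def _simulate_block(
    config: SimConfig, seeds: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate ``len(seeds)`` independent runs of ``config`` in lockstep.

    Each run draws its noise from its own ``np.random.default_rng(seed)``
    in fixed-size chunks, so a run re-simulated alone with the same seed
    reproduces the ensemble member bit-exactly.

    Returns ``(tap_times, degenerate, reasons)`` where ``tap_times`` has
    shape ``(runs, 2, n_taps)`` in seconds, ``degenerate`` is a boolean
    mask and ``reasons`` holds one diagnostic string per degenerate run.
    """
    R = len(seeds)
    n = config.n_taps
    dt = config.dt
    sqdt = math.sqrt(dt)
    pp = (config.params_p1, config.params_p2)
    sigma = np.array([p.sigma for p in pp])
    omega0 = np.array([p.omega0 for p in pp])
    order = tuple(i - 1 for i in config.tap_order)

    rngs = [np.random.default_rng(int(s)) for s in seeds]

    theta = np.zeros((R, 2))
    omega = np.tile(omega0, (R, 1))
    taps = np.full((R, 2, n), np.nan)
    counts = np.zeros((R, 2), dtype=np.int64)
    if config.t0_is_tap:
        taps[:, :, 0] = 0.0
        counts[:] = 1

    degenerate = np.zeros(R, dtype=bool)
    reasons: dict[int, str] = {}
    done = np.zeros(R, dtype=bool)

    t_max = 2.5 * n * TWO_PI / omega0.min()
    n_steps_max = int(math.ceil(t_max / dt))
    t = 0.0
    step = 0

    while step < n_steps_max:
        chunk = min(_NOISE_CHUNK, n_steps_max - step)
        # (R, chunk, 2): per-run generators drawn in a fixed order
        noise = np.stack([rng.standard_normal((chunk, 2)) for rng in rngs])
        for s in range(chunk):
            active = ~(done | degenerate)
            if not active.any():
                step = n_steps_max
                break
            xi = noise[:, s, :]
            theta0 = theta.copy()
            prop = theta + omega * dt + sigma * sqdt * xi
            # fraction of the step at which each player tapped (NaN: no tap yet)
            frac_tap = np.full((R, 2), np.nan)

            for _ in range(4):
                any_cross = False
                for i in order:
                    j = 1 - i
                    cross = active & (prop[:, i] >= TWO_PI) & np.isnan(frac_tap[:, i])
                    if not cross.any():
                        continue
                    any_cross = True
                    idx = np.nonzero(cross)[0]
                    denom = prop[idx, i] - theta0[idx, i]
                    frac = np.clip((TWO_PI - theta0[idx, i]) / denom, 0.0, 1.0)
                    frac_tap[idx, i] = frac
                    t_cross = t + frac * dt
                    rec = idx[counts[idx, i] < n]
                    if rec.size:
                        t_rec = t + frac_tap[rec, i] * dt
                        taps[rec, i, counts[rec, i]] = (
                            np.round(t_rec * _TIME_GRID) / _TIME_GRID
                        )
                        counts[rec, i] += 1
                    # tapper: phase reset to 0 at the crossing, remainder of
                    # the linear within-step path continues from there
                    prop[idx, i] -= TWO_PI

                    # partner phase at the crossing instant, by linear
                    # interpolation of its within-step path (piecewise if the
                    # partner itself already wrapped this step)
                    fj = frac_tap[idx, j]
                    th0j = theta0[idx, j]
                    propj = prop[idx, j]
                    plain = th0j + frac * (propj - th0j)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        after_wrap = propj * (frac - fj) / (1.0 - fj)
                        before_wrap = th0j + frac * (propj + TWO_PI - th0j)
                    theta_jc = np.where(
                        np.isnan(fj), plain, np.where(fj < frac, after_wrap, before_wrap)
                    )
                    pj = pp[j]
                    dtheta = pj.a * pj.Z(theta_jc)
                    om_old = omega[idx, j]
                    om_new = om_old + pj.b * pj.Y(theta_jc) - pj.k * (om_old - pj.omega0)
                    bad = om_new <= 0
                    if bad.any():
                        for r in idx[bad]:
                            degenerate[r] = True
                            reasons[r] = (
                                f"run seed={seeds[r]}: partner reset drove "
                                f"omega <= 0 near t={t:.4f}s"
                            )
                        om_new = np.where(bad, om_old, om_new)
                    # end-of-step phase gains the kick plus the drift change
                    # over the remaining (1 - frac) of the step
                    prop[idx, j] += dtheta + (1.0 - frac) * dt * (om_new - om_old)
                    omega[idx, j] = om_new
                if not any_cross:
                    break

            upd = active
            theta[upd] = prop[upd]
            div = active & (np.abs(counts[:, 0] - counts[:, 1]) > 1)
            if div.any():
                for r in np.nonzero(div)[0]:
                    degenerate[r] = True
                    reasons[r] = (
                        f"run seed={seeds[r]}: tap counts diverged by >1 at "
                        f"t={t + dt:.4f}s (runaway desynchronization)"
                    )
            done |= (counts[:, 0] >= n) & (counts[:, 1] >= n)
            t += dt
        step += chunk

    unfinished = ~(done | degenerate)
    for r in np.nonzero(unfinished)[0]:
        degenerate[r] = True
        reasons[r] = f"run seed={seeds[r]}: did not reach {n} taps by t={t_max:.1f}s"

    reason_list = [reasons.get(r, "") for r in range(R)]
    return taps, degenerate, reason_list


def simulate_pair(config: SimConfig) -> PairTimeline:
    """Simulate one run and return its paired tap-time series.

    Both players start at θ = 0, ω = ω0; with ``t0_is_tap`` (default) the
    shared start event is recorded as tap 1 for both, so a 36-tap timeline
    has 35 inter-tap intervals per player.  Within-step 2π crossings are
    located by linear interpolation.

    Raises :class:`DegenerateRunError` for runs that leave the valid
    regime (ω ≤ 0 after a reset, or tap counts diverging by more than 1).
    """
    taps, degen, reasons = _simulate_block(config, [config.seed])
    if degen[0]:
        raise DegenerateRunError(reasons[0])
    return PairTimeline(taps[0, 0], taps[0, 1], seed=config.seed, config=config)


def simulate_ensemble(
    config: SimConfig,
    reps: int,
    base_seed: int | None = None,
    max_retries: int = 100,
) -> list[PairTimeline]:
    """Simulate ``reps`` independent runs with seeds ``base_seed + i``.

    Degenerate runs (never observed at the study's parameter values) are
    redrawn with fresh seeds beyond the base range, up to ``max_retries``.
    """
    if base_seed is None:
        base_seed = config.seed
    seeds = [base_seed + i for i in range(reps)]
    taps, degen, reasons = _simulate_block(config, seeds)
    timelines: list[PairTimeline | None] = [None] * reps
    for r in range(reps):
        if not degen[r]:
            timelines[r] = PairTimeline(
                taps[r, 0], taps[r, 1], seed=seeds[r], config=config
            )

    retry_seed = base_seed + reps
    retries = 0
    for r in range(reps):
        while timelines[r] is None:
            if retries >= max_retries:
                raise DegenerateRunError(
                    f"exceeded {max_retries} retries; last: {reasons[r]}"
                )
            tr, dg, rs = _simulate_block(
                replace(config, seed=retry_seed), [retry_seed]
            )
            retries += 1
            retry_seed += 1
            if not dg[0]:
                timelines[r] = PairTimeline(
                    tr[0, 0], tr[0, 1], seed=retry_seed - 1, config=config
                )
    return timelines  # type: ignore[return-value]
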