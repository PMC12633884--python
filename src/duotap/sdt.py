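"""Trial scheduling, participant screening and signal-detection scoring.

The listening experiment presents three stimulus classes — HUM (model
simulations with consistent mutual-adaptation structure), RAN (asynchrony-
shuffled surrogates) and ISO (near-isochronous attention checks) — and asks
for a two-alternative "human-like" / "not human-like" judgment within
2.5 s.  Sensitivity and bias are scored under the equal-variance Gaussian
model of signal detection theory with HUM as the signal class:

    d' = z(H) − z(F),        C = −(z(H) + z(F)) / 2,

where ``H`` is the hit rate (HUM judged "human-like"), ``F`` the
false-alarm rate (RAN judged "human-like") and ``z`` the standard-normal
quantile.  ``C`` follows the standard conservative-positive convention of
that formula: a *negative* C marks a liberal observer who says
"human-like" often (H = F = 0.9 gives C ≈ −1.28), a positive C a
conservative one.  Extreme proportions are adjusted by the 1/(2N) rule before
the quantile transform.  ISO trials are excluded from d'/C (they exist to
catch inattentive listeners, via the screening rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

HUMAN = "human-like"
NOT_HUMAN = "not-human-like"
TIMEOUT = "timeout"
CLASSES = ("HUM", "RAN", "ISO")
RESPONSE_DEADLINE_MS = 2500.0

#: example-phase presentations per class (HUM twice, RAN twice, ISO once)
EXAMPLE_PRESENTATIONS = (("HUM", 2), ("RAN", 2), ("ISO", 1))
PRACTICE_PER_CLASS = 3
BLOCKS = 3
BLOCK_COMPOSITION = {"HUM": 5, "RAN": 5, "ISO": 2}
EXAMPLE_RANKS = (1, 5, 10, 15, 20)

RESPONSE_COLUMNS = [
    "participant_id",
    "phase",
    "block",
    "trial",
    "stimulus_class",
    "stimulus_id",
    "response",
    "rt_ms",
]


@dataclass(frozen=True)
class TrialSchedule:
    """Full per-participant trial list: example, practice and main phases."""

    trials: pd.DataFrame  # columns: phase, block, trial, stimulus_class, stimulus_id
    seed: int

    def phase(self, name: str) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == name].reset_index(drop=True)


@dataclass(frozen=True)
class SDTResult:
    hit_rate: float
    false_alarm: float
    d_prime: float
    criterion: float
    n_hum: int
    n_ran: int


def make_trial_schedule(seed: int) -> TrialSchedule:
    """Build the three-phase schedule used in the listening experiment.

    Example phase: HUM, RAN twice each and ISO once, drawn from the
    rank-{1,5,10,15,20} example stimuli.  Practice: 9 trials (3 per class,
    random order).  Main: 3 blocks × 12 trials, each block holding 5 HUM,
    5 RAN and 2 ISO in random order; main-phase HUM/RAN stimuli are the 15
    per class not used as examples, and the 6 main ISO are distinct from
    the 4 example/practice ISO.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    example_ids = {c: [f"{c.lower()}{r:02d}" for r in EXAMPLE_RANKS] for c in CLASSES[:2]}
    iso_ids = [f"iso{i:02d}" for i in range(1, 11)]
    trial_no = 0
    for cls, reps in EXAMPLE_PRESENTATIONS:
        pool = example_ids[cls] if cls != "ISO" else iso_ids[:1]
        for r in range(reps):
            trial_no += 1
            rows.append(
                dict(
                    phase="example",
                    block=0,
                    trial=trial_no,
                    stimulus_class=cls,
                    stimulus_id=pool[r % len(pool)],
                )
            )

    practice = []
    for cls in CLASSES:
        if cls == "ISO":
            ids = iso_ids[1:4]
        else:
            ids = list(rng.choice(example_ids[cls], PRACTICE_PER_CLASS, replace=False))
        practice += [(cls, sid) for sid in ids]
    rng.shuffle(practice)
    for i, (cls, sid) in enumerate(practice, start=1):
        rows.append(
            dict(phase="practice", block=0, trial=i, stimulus_class=cls, stimulus_id=sid)
        )

    main_ranks = [r for r in range(1, 21) if r not in EXAMPLE_RANKS]
    hum_pool = [f"hum{r:02d}" for r in main_ranks]
    ran_pool = [f"ran{r:02d}" for r in main_ranks]
    iso_pool = iso_ids[4:10]
    rng.shuffle(hum_pool)
    rng.shuffle(ran_pool)
    rng.shuffle(iso_pool)
    trial_no = 0
    for block in range(1, BLOCKS + 1):
        block_trials = []
        for cls, count, pool in (
            ("HUM", BLOCK_COMPOSITION["HUM"], hum_pool),
            ("RAN", BLOCK_COMPOSITION["RAN"], ran_pool),
            ("ISO", BLOCK_COMPOSITION["ISO"], iso_pool),
        ):
            for _ in range(count):
                block_trials.append((cls, pool.pop()))
        rng.shuffle(block_trials)
        for cls, sid in block_trials:
            trial_no += 1
            rows.append(
                dict(
                    phase="main",
                    block=block,
                    trial=trial_no,
                    stimulus_class=cls,
                    stimulus_id=sid,
                )
            )

    return TrialSchedule(trials=pd.DataFrame(rows), seed=seed)


def _check_classes(table: pd.DataFrame) -> None:
    unknown = set(table["stimulus_class"]) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown stimulus classes: {sorted(unknown)}")


def screen_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Partition participants into kept/excluded with reason codes.

    A participant is excluded when, in the main phase, they ran out of time
    on two or more trials (``timeout>=2``) or judged ISO "human-like" on
    two or more trials (``iso_error>=2``).  Returns one row per participant
    with boolean ``excluded`` and a semicolon-joined ``reason`` column.
    """
    if table.empty:
        return pd.DataFrame(columns=["participant_id", "excluded", "reason"])
    _check_classes(table)
    main = table[table["phase"] == "main"]
    out = []
    for pid, grp in main.groupby("participant_id", sort=True):
        reasons = []
        if (grp["response"] == TIMEOUT).sum() >= 2:
            reasons.append("timeout>=2")
        iso = grp[grp["stimulus_class"] == "ISO"]
        if (iso["response"] == HUMAN).sum() >= 2:
            reasons.append("iso_error>=2")
        out.append(
            dict(
                participant_id=pid,
                excluded=bool(reasons),
                reason=";".join(reasons),
            )
        )
    return pd.DataFrame(out)


def response_rates(table: pd.DataFrame, participant_id) -> pd.DataFrame:
    """Per-class "human-like" response rates for one participant (main phase).

    The rate is the number of "human-like" responses divided by the number
    of non-timeout responses; a class with no non-timeout responses gets a
    NaN rate and ``defined=False``.
    """
    _check_classes(table)
    main = table[
        (table["phase"] == "main") & (table["participant_id"] == participant_id)
    ]
    if main.empty:
        raise KeyError(f"participant {participant_id!r} has no main-phase trials")
    rows = []
    for cls in CLASSES:
        grp = main[main["stimulus_class"] == cls]
        valid = (grp["response"] != TIMEOUT).sum()
        hits = (grp["response"] == HUMAN).sum()
        rows.append(
            dict(
                stimulus_class=cls,
                n_trials=len(grp),
                n_valid=int(valid),
                rate=hits / valid if valid else np.nan,
                defined=bool(valid),
            )
        )
    return pd.DataFrame(rows)


def compute_dprime_C(H: float, F: float, n_hum: int, n_ran: int) -> SDTResult:
    """d' and criterion C from hit and false-alarm proportions.

    Proportions of exactly 0 or 1 are moved to 1/(2N) or 1 − 1/(2N)
    (N = valid trials of that class) so the quantile transform is finite.
    """
    if n_hum <= 0 or n_ran <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= H <= 1 and 0 <= F <= 1):
        raise ValueError("proportions must lie in [0, 1]")

    def adjust(p: float, n: int) -> float:
        lo = 1.0 / (2 * n)
        return min(max(p, lo), 1.0 - lo)

    zH = norm.ppf(adjust(H, n_hum))
    zF = norm.ppf(adjust(F, n_ran))
    return SDTResult(
        hit_rate=H,
        false_alarm=F,
        d_prime=float(zH - zF),
        criterion=float(-(zH + zF) / 2.0),
        n_hum=n_hum,
        n_ran=n_ran,
    )


def score_participant(table: pd.DataFrame, participant_id) -> SDTResult:
    """Hit/false-alarm rates and d'/C for one participant's main phase."""
    rates = response_rates(table, participant_id).set_index("stimulus_class")
    hum, ran = rates.loc["HUM"], rates.loc["RAN"]
    if not (hum["defined"] and ran["defined"]):
        raise ValueError("undefined response rate (all trials timed out)")
    return compute_dprime_C(
        float(hum["rate"]), float(ran["rate"]), int(hum["n_valid"]), int(ran["n_valid"])
    )


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SDT summary joined with screening results."""
    screening = screen_participants(table).set_index("participant_id")
    rows = []
    for pid in screening.index:
        res = score_participant(table, pid)
        rows.append(
            dict(
                participant_id=pid,
                H=res.hit_rate,
                F=res.false_alarm,
                d_prime=res.d_prime,
                C=res.criterion,
                excluded=screening.loc[pid, "excluded"],
                reason=screening.loc[pid, "reason"],
            )
        )
    return pd.DataFrame(rows)


def simulate_listener(
    d_prime_true: float,
    criterion_true: float,
    schedule: TrialSchedule,
    seed: int,
    participant_id: str = "synthetic",
    timeout_prob: float = 0.0,
) -> pd.DataFrame:
    """Synthetic equal-variance Gaussian observer responding to a schedule.

    Per trial, evidence is drawn from N(+d'/2, 1) for HUM and N(−d'/2, 1)
    for RAN/ISO; the response is "human-like" iff evidence exceeds the
    criterion.  With this generator, scoring recovers ``d_prime_true`` and
    ``criterion_true`` in expectation.  Purely artifact plumbing for
    end-to-end tests — not a model of human listeners.
    """
    if not (np.isfinite(d_prime_true) and np.isfinite(criterion_true)):
        raise ValueError("observer parameters must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in schedule.trials.to_dict("records"):
        mu = d_prime_true / 2.0 if rec["stimulus_class"] == "HUM" else -d_prime_true / 2.0
        if timeout_prob and rng.random() < timeout_prob:
            response, rt = TIMEOUT, RESPONSE_DEADLINE_MS
        else:
            evidence = mu + rng.standard_normal()
            response = HUMAN if evidence > criterion_true else NOT_HUMAN
            rt = float(rng.uniform(400.0, RESPONSE_DEADLINE_MS - 1))
        rows.append(
            dict(
                participant_id=participant_id,
                phase=rec["phase"],
                block=rec["block"],
                trial=rec["trial"],
                stimulus_class=rec["stimulus_class"],
                stimulus_id=rec["stimulus_id"],
                response=response,
                rt_ms=rt,
            )
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
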