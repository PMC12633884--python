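"""Trial scheduling, screening, response rates and d'/C scoring."""

import numpy as np
import pandas as pd
import pytest

from duotap import (
    TrialSchedule,
    compute_dprime_C,
    make_trial_schedule,
    response_rates,
    score_participant,
    screen_participants,
    simulate_listener,
)
from duotap.sdt import HUMAN, NOT_HUMAN, RESPONSE_COLUMNS, TIMEOUT


def response_row(pid="p1", phase="main", cls="HUM", response=NOT_HUMAN, **kw):
    row = dict(
        participant_id=pid,
        phase=phase,
        block=1,
        trial=1,
        stimulus_class=cls,
        stimulus_id=f"{cls.lower()}01",
        response=response,
        rt_ms=1000.0,
    )
    row.update(kw)
    return row


class TestSchedule:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_phase_compositions(self, seed):
        sch = make_trial_schedule(seed)
        main = sch.phase("main")
        assert len(main) == 36
        counts = main["stimulus_class"].value_counts()
        assert counts["HUM"] == 15 and counts["RAN"] == 15 and counts["ISO"] == 6
        per_block = main.groupby("block")["stimulus_class"].value_counts().unstack()
        assert (per_block["HUM"] == 5).all()
        assert (per_block["RAN"] == 5).all()
        assert (per_block["ISO"] == 2).all()
        practice = sch.phase("practice")
        assert len(practice) == 9
        assert practice["stimulus_class"].value_counts().eq(3).all()
        example = sch.phase("example")
        assert example["stimulus_class"].tolist().count("HUM") == 2
        assert example["stimulus_class"].tolist().count("RAN") == 2
        assert example["stimulus_class"].tolist().count("ISO") == 1

    def test_main_stimuli_disjoint_from_examples(self):
        sch = make_trial_schedule(5)
        example_ids = set(sch.phase("example")["stimulus_id"]) | set(
            sch.phase("practice")["stimulus_id"]
        )
        main_ids = set(sch.phase("main")["stimulus_id"])
        assert example_ids.isdisjoint(main_ids)
        assert len(main_ids) == 36  # every main stimulus presented once

    def test_same_seed_identical_schedules(self):
        a, b = make_trial_schedule(42), make_trial_schedule(42)
        pd.testing.assert_frame_equal(a.trials, b.trials)


class TestScreening:
    def test_two_timeouts_excluded(self):
        rows = [response_row(trial=i) for i in range(34)]
        rows += [response_row(trial=35, response=TIMEOUT),
                 response_row(trial=36, response=TIMEOUT)]
        res = screen_participants(pd.DataFrame(rows))
        assert res.loc[0, "excluded"]
        assert res.loc[0, "reason"] == "timeout>=2"

    def test_single_iso_error_kept(self):
        rows = [response_row(trial=1, cls="ISO", response=HUMAN)]
        rows += [response_row(trial=i, cls="ISO") for i in range(2, 7)]
        res = screen_participants(pd.DataFrame(rows))
        assert not res.loc[0, "excluded"]

    def test_two_iso_errors_excluded(self):
        rows = [response_row(trial=i, cls="ISO", response=HUMAN) for i in (1, 2)]
        res = screen_participants(pd.DataFrame(rows))
        assert res.loc[0, "excluded"]
        assert res.loc[0, "reason"] == "iso_error>=2"

    def test_practice_phase_ignored(self):
        rows = [response_row(phase="practice", trial=i, response=TIMEOUT)
                for i in range(5)]
        rows.append(response_row(trial=10))
        res = screen_participants(pd.DataFrame(rows))
        assert not res.loc[0, "excluded"]

    def test_empty_table(self):
        res = screen_participants(pd.DataFrame(columns=RESPONSE_COLUMNS))
        assert res.empty

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            screen_participants(pd.DataFrame([response_row(cls="XXX")]))

    def test_order_independent_and_idempotent(self):
        rows = [response_row(pid=f"p{i}", trial=j, response=TIMEOUT if (i + j) % 9 == 0 else NOT_HUMAN)
                for i in range(4) for j in range(12)]
        table = pd.DataFrame(rows)
        a = screen_participants(table)
        b = screen_participants(table.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(a, b)


class TestResponseRates:
    def test_rate_excludes_timeouts(self):
        rows = [response_row(trial=i, response=HUMAN) for i in range(8)]
        rows += [response_row(trial=i + 10) for i in range(6)]
        rows += [response_row(trial=20, response=TIMEOUT)]
        rates = response_rates(pd.DataFrame(rows), "p1").set_index("stimulus_class")
        assert rates.loc["HUM", "n_valid"] == 14
        assert rates.loc["HUM", "rate"] == pytest.approx(8 / 14)

    def test_all_timeouts_undefined(self):
        rows = [response_row(trial=i, response=TIMEOUT) for i in range(5)]
        rates = response_rates(pd.DataFrame(rows), "p1").set_index("stimulus_class")
        assert not rates.loc["HUM", "defined"]
        assert np.isnan(rates.loc["HUM", "rate"])

    def test_all_human_like_rate_one(self):
        rows = [response_row(trial=i, response=HUMAN) for i in range(5)]
        rates = response_rates(pd.DataFrame(rows), "p1").set_index("stimulus_class")
        assert rates.loc["HUM", "rate"] == 1.0


class TestDPrime:
    @pytest.mark.parametrize(
        "H, F, d_expected, c_expected",
        [
            (0.5, 0.5, 0.0, 0.0),
            (0.8413447, 0.1586553, 2.0, 0.0),  # z = ±1
            (0.9, 0.9, 0.0, -1.2815516),  # z(0.9) = 1.2815516
        ],
    )
    def test_closed_form_cases(self, H, F, d_expected, c_expected):
        res = compute_dprime_C(H, F, 1000, 1000)
        assert res.d_prime == pytest.approx(d_expected, abs=1e-4)
        assert res.criterion == pytest.approx(c_expected, abs=1e-4)

    def test_antisymmetry_under_hf_swap(self):
        a = compute_dprime_C(0.8, 0.3, 15, 15)
        b = compute_dprime_C(0.3, 0.8, 15, 15)
        assert b.d_prime == pytest.approx(-a.d_prime)
        assert abs(b.criterion) == pytest.approx(abs(a.criterion))

    def test_extreme_proportions_use_half_count_rule(self):
        from scipy.stats import norm

        res = compute_dprime_C(1.0, 0.0, 15, 15)
        z = norm.ppf(1 - 1 / 30)
        assert res.d_prime == pytest.approx(2 * z)

    def test_criterion_sign_convention(self):
        """C = −(zH+zF)/2: liberal ('human-like'-prone) observers score
        below conservative ones."""
        liberal = compute_dprime_C(0.9, 0.8, 100, 100)
        conservative = compute_dprime_C(0.2, 0.1, 100, 100)
        assert liberal.criterion < 0 < conservative.criterion

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_dprime_C(0.5, 0.5, 0, 10)
        with pytest.raises(ValueError):
            compute_dprime_C(1.2, 0.5, 10, 10)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    H=st.floats(0.01, 0.99),
    F=st.floats(0.01, 0.99),
    n=st.integers(5, 500),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_dprime_antisymmetry_property(H, F, n):
    """Swapping H and F negates d' and preserves |C| for any proportions."""
    a = compute_dprime_C(H, F, n, n)
    b = compute_dprime_C(F, H, n, n)
    assert b.d_prime == pytest.approx(-a.d_prime, abs=1e-10)
    assert abs(b.criterion) == pytest.approx(abs(a.criterion), abs=1e-10)


class TestSyntheticListener:
    @staticmethod
    def big_schedule(n_per_class=5000):
        rows = []
        for i in range(n_per_class):
            for cls in ("HUM", "RAN"):
                rows.append(
                    dict(phase="main", block=1, trial=len(rows) + 1,
                         stimulus_class=cls, stimulus_id=f"{cls}_{i}")
                )
        return TrialSchedule(trials=pd.DataFrame(rows), seed=0)

    def test_zero_sensitivity_recovered(self):
        table = simulate_listener(0.0, 0.0, self.big_schedule(2000), seed=1)
        res = score_participant(table, "synthetic")
        assert res.d_prime == pytest.approx(0.0, abs=0.1)

    def test_parameter_recovery(self):
        table = simulate_listener(1.5, 0.4, self.big_schedule(10000), seed=2)
        res = score_participant(table, "synthetic")
        assert res.d_prime == pytest.approx(1.5, abs=0.1)
        assert res.criterion == pytest.approx(0.4, abs=0.05)

    def test_criterion_shifts_recovered_c_monotonically(self):
        cs = []
        for c_true in (-0.5, 0.0, 0.5):
            table = simulate_listener(1.0, c_true, self.big_schedule(3000), seed=3)
            cs.append(score_participant(table, "synthetic").criterion)
        assert cs[0] < cs[1] < cs[2]

    def test_full_pipeline_on_experiment_schedule(self):
        sch = make_trial_schedule(11)
        table = simulate_listener(2.0, 0.0, sch, seed=12)
        screening = screen_participants(table)
        assert len(screening) == 1
        res = score_participant(table, "synthetic")
        assert res.n_hum == 15 and res.n_ran == 15
        assert res.d_prime > 0  # a sensitive observer discriminates HUM
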