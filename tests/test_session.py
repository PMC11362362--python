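"""Trial lifecycle and outcome-measure coding."""

import math
import random

import pytest
from scipy import stats

from ideaspark import (
    CloseFar,
    Direction,
    Phase,
    ResponseEvent,
    SessionLog,
    Trial,
    assign_conditions,
    close_far,
    fluency,
    idea_order,
    impasse_break,
    next_recommendation,
    response_times,
    trial_table,
)
from ideaspark.session import TRIAL_TABLE_COLUMNS


def make_trial(n_pre, n_post, object="brick", distance=2,
               direction=Direction.AWAY, trial_id="t0"):
    trial = Trial(trial_id=trial_id, object=object, distance=distance, direction=direction)
    t = 0.0
    for i in range(n_pre):
        trial.responses.append(
            ResponseEvent(trial_id, f"pre idea {i}", Phase.PRE, t, t + 2.0)
        )
        t += 5.0
    trial.impasse_time = t
    for i in range(n_post):
        trial.responses.append(
            ResponseEvent(trial_id, f"post idea {i}", Phase.POST, t + 1.0, t + 3.0)
        )
        t += 5.0
    return trial


class TestMeasures:
    @pytest.mark.parametrize("n_pre, n_post", [(3, 1), (1, 0), (4, 2)])
    def test_fluency_counts_phases(self, n_pre, n_post):
        assert fluency(make_trial(n_pre, n_post)) == (n_pre, n_post)

    @pytest.mark.parametrize("n_post, expected", [(2, 1), (1, 1), (0, 0)])
    def test_impasse_break(self, t1, stoplist, n_post, expected):
        trial = make_trial(2, n_post, object="brick")
        rng = random.Random(1)
        next_recommendation(trial, t1, stoplist, rng=rng)
        assert impasse_break(trial) == expected

    def test_impasse_break_requires_recommendation(self):
        with pytest.raises(ValueError, match="no recommendation"):
            impasse_break(make_trial(2, 0))

    @pytest.mark.parametrize(
        "n_pre, n_post, expected",
        [
            (3, 2, [-2, -1, 0, 1, 2]),
            (1, 0, [0]),
            (2, 3, [-1, 0, 1, 2, 3]),
            (1, 1, [0, 1]),
        ],
    )
    def test_idea_order_coding(self, n_pre, n_post, expected):
        assert idea_order(make_trial(n_pre, n_post)) == expected

    def test_idea_order_steps_by_one_and_crosses_impasse(self):
        rng = random.Random(0)
        for _ in range(50):
            trial = make_trial(rng.randint(1, 6), rng.randint(0, 5))
            order = idea_order(trial)
            assert all(b - a == 1 for a, b in zip(order, order[1:]))
            n_pre, _ = fluency(trial)
            assert order[n_pre - 1] == 0
            if len(order) > n_pre:
                assert order[n_pre] == 1

    def test_response_times(self):
        trial = Trial(trial_id="t", object="brick", distance=1, direction=Direction.TOWARDS)
        trial.responses = [
            ResponseEvent("t", "a", Phase.PRE, 0.0, 5.0),     # trial-start anchor
            ResponseEvent("t", "b", Phase.PRE, 8.0, 8.0),     # zero thinking time
            ResponseEvent("t", "c", Phase.POST, 30.0, 42.0),  # anchored at rec display
        ]
        trial.impasse_time = 20.0
        assert response_times(trial) == [5.0, 0.0, 12.0]

    def test_negative_interval_is_clock_skew(self):
        trial = make_trial(1, 0)
        trial.responses[0].t_typing = trial.responses[0].t_start - 0.5
        with pytest.raises(ValueError, match="clock skew"):
            response_times(trial)

    @pytest.mark.parametrize(
        "distance, expected",
        [(1, CloseFar.CLOSE), (2, CloseFar.CLOSE), (3, CloseFar.FAR), (4, CloseFar.FAR)],
    )
    def test_close_far_dichotomization(self, distance, expected):
        assert close_far(distance) == expected

    @pytest.mark.parametrize("distance", [0, 5, -1])
    def test_close_far_out_of_range(self, distance):
        with pytest.raises(ValueError):
            close_far(distance)


class TestAssignConditions:
    def test_deterministic_under_seed(self):
        a = assign_conditions(20, rng=random.Random(7))
        b = assign_conditions(20, rng=random.Random(7))
        assert a == b

    def test_singleton_space(self):
        conds = assign_conditions(
            5, distance_range=(2,), directions=(Direction.TOWARDS,), rng=random.Random(0)
        )
        assert conds == [(2, Direction.TOWARDS)] * 5

    def test_uniform_over_cells(self):
        """8,000 draws: chi-square GOF against uniform over the 8 cells."""
        conds = assign_conditions(8000, rng=random.Random(123))
        counts = {}
        for c in conds:
            counts[c] = counts.get(c, 0) + 1
        assert len(counts) == 8
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.001

    def test_empty_ranges_error(self):
        with pytest.raises(ValueError):
            assign_conditions(5, distance_range=())
        with pytest.raises(ValueError):
            assign_conditions(0)


class TestNextRecommendation:
    def test_away_from_wall_gives_flare(self, t1, stoplist):
        trial = Trial(trial_id="t", object="brick", distance=2, direction=Direction.AWAY)
        trial.responses = [ResponseEvent("t", "build a wall", Phase.PRE, 0.0, 2.0)]
        trial.impasse_time = 10.0
        rec = next_recommendation(trial, t1, stoplist, shown_time=11.0)
        assert rec.word == "flare"
        assert trial.rec_shown_time == 11.0

    def test_towards_wall_gives_house(self, t1, stoplist):
        trial = Trial(trial_id="t", object="brick", distance=2, direction=Direction.TOWARDS)
        trial.responses = [ResponseEvent("t", "build a wall", Phase.PRE, 0.0, 2.0)]
        trial.impasse_time = 10.0
        assert next_recommendation(trial, t1, stoplist).word == "house"

    def test_requires_pre_response_and_impasse(self, t1, stoplist):
        empty = Trial(trial_id="t", object="brick", distance=2, direction=Direction.AWAY)
        with pytest.raises(ValueError, match="no pre-impasse"):
            next_recommendation(empty, t1, stoplist)
        trial = Trial(trial_id="t", object="brick", distance=2, direction=Direction.AWAY)
        trial.responses = [ResponseEvent("t", "build a wall", Phase.PRE, 0.0, 2.0)]
        with pytest.raises(ValueError, match="impasse"):
            next_recommendation(trial, t1, stoplist)

    def test_object_and_used_words_are_excluded(self, t1, stoplist):
        # idea space {wall}: at distance 1 the towards pick would be wall
        # itself, but used words are excluded, so fire is recommended
        trial = Trial(trial_id="t", object="brick", distance=1, direction=Direction.TOWARDS)
        trial.responses = [ResponseEvent("t", "build a wall", Phase.PRE, 0.0, 2.0)]
        trial.impasse_time = 5.0
        assert next_recommendation(trial, t1, stoplist).word == "fire"


class TestTrialTable:
    def _session(self, t1, stoplist):
        trials = []
        for i, (n_pre, n_post, d, direction) in enumerate(
            [(3, 1, 2, Direction.AWAY), (1, 0, 1, Direction.TOWARDS), (2, 2, 4, Direction.AWAY)]
        ):
            trial = make_trial(n_pre, n_post, object="brick", distance=d,
                               direction=direction, trial_id=f"t{i}")
            next_recommendation(trial, t1, stoplist, rng=random.Random(i))
            trials.append(trial)
        return SessionLog(participant_id="p0", seed=0, trials=trials)

    def test_row_per_trial_with_fixed_columns(self, t1, stoplist):
        df = trial_table(self._session(t1, stoplist), net=t1, stoplist=stoplist)
        assert list(df.columns) == TRIAL_TABLE_COLUMNS
        assert len(df) == 3
        assert df["fluency_before"].tolist() == [3, 1, 2]
        assert df["fluency_after"].tolist() == [1, 0, 2]
        assert df["impasse_break"].tolist() == [1, 0, 1]
        assert df["close_far"].tolist() == ["close", "close", "far"]

    def test_rows_match_per_trial_recomputation(self, t1, stoplist):
        session = self._session(t1, stoplist)
        df = trial_table(session)
        for row, trial in zip(df.itertuples(), session.trials):
            assert (row.fluency_before, row.fluency_after) == fluency(trial)
            assert row.impasse_break == impasse_break(trial)
            assert row.close_far == close_far(trial.distance).value

    def test_unrecommended_trial_has_missing_fields(self, t1, stoplist):
        trial = make_trial(2, 0)
        session = SessionLog(participant_id="p0", seed=0, trials=[trial])
        df = trial_table(session, net=t1, stoplist=stoplist)
        assert math.isnan(df.loc[0, "impasse_break"])
        assert df.loc[0, "recommendation"] is None
        assert math.isnan(df.loc[0, "mean_adherence"])

    def test_originality_passthrough_means(self, t1, stoplist):
        trial = make_trial(2, 2)
        for r, score in zip(trial.responses, [1.0, 3.0, 4.0, 5.0]):
            r.originality = score
        session = SessionLog(participant_id="p0", seed=0, trials=[trial])
        df = trial_table(session)
        assert df.loc[0, "originality_pre"] == 2.0
        assert df.loc[0, "originality_post"] == 4.5
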