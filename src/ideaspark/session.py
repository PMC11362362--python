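"""Trial lifecycle and outcome measures.

A trial presents one object (e.g. "brick") and unfolds in two phases:
the participant types alternative uses until they run out of ideas
(PRE responses), declares an impasse, is shown a word recommendation, and
may then add further uses (POST responses). This module models that
lifecycle and computes the per-trial outcome measures: fluency before and
after the impasse, the binary impasse-break outcome, the serial idea-order
coding, per-response thinking times, the close/far dichotomization of the
distance condition, and the aggregated per-trial table.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ideaspace import IdeaSpace, adherence, build_idea_space
from .network import SemanticNetwork
from .recommend import Direction, Fallback, Recommendation, RecommendationRequest, recommend

__all__ = [
    "Phase",
    "CloseFar",
    "ResponseEvent",
    "Trial",
    "SessionLog",
    "assign_conditions",
    "next_recommendation",
    "fluency",
    "impasse_break",
    "idea_order",
    "response_times",
    "close_far",
    "trial_table",
    "TRIAL_TABLE_COLUMNS",
]


class Phase(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class CloseFar(str, enum.Enum):
    CLOSE = "close"
    FAR = "far"


@dataclass
class ResponseEvent:
    """One submitted response.

    ``t_start`` is when the response slot began (trial start, end of the
    previous response, or the moment the recommendation was shown);
    ``t_typing`` is the first keystroke. Both are seconds since trial
    start, recorded to millisecond precision. ``originality`` is an
    externally supplied human rating in [1, 5], stored pass-through.
    """

    trial_id: str
    text: str
    phase: Phase
    t_start: float
    t_typing: float
    originality: float | None = None


@dataclass
class Trial:
    """One object's full record: responses, impasse, recommendation."""

    trial_id: str
    object: str
    distance: int
    direction: Direction
    responses: list[ResponseEvent] = field(default_factory=list)
    impasse_time: float | None = None
    recommendation: Recommendation | None = None
    rec_shown_time: float | None = None

    def responses_in_phase(self, phase: Phase) -> list[ResponseEvent]:
        return [r for r in self.responses if r.phase is phase]


@dataclass
class SessionLog:
    """One participant's sequence of trials plus the replay seed/config."""

    participant_id: str
    seed: int
    trials: list[Trial] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def assign_conditions(
    n_trials: int,
    distance_range: Sequence[int] = (1, 2, 3, 4),
    directions: Sequence[Direction] = (Direction.TOWARDS, Direction.AWAY),
    rng: random.Random | None = None,
) -> list[tuple[int, Direction]]:
    """Draw each trial's (distance, direction) independently and uniformly."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not distance_range or not directions:
        raise ValueError("distance_range and directions must be nonempty")
    rng = rng if rng is not None else random.Random()
    distances = list(distance_range)
    dirs = [Direction(d) for d in directions]
    return [
        (distances[rng.randrange(len(distances))], dirs[rng.randrange(len(dirs))])
        for _ in range(n_trials)
    ]


def next_recommendation(
    trial: Trial,
    net: SemanticNetwork,
    stoplist: set[str],
    rng: random.Random | None = None,
    idea_space_scope: str = "pre_only",
    idea_space_mode: str = "set",
    fallback_distance: bool = False,
    shown_time: float | None = None,
) -> Recommendation:
    """Wire a trial's responses into the recommender.

    Builds the idea space from the trial's responses (pre-impasse only by
    default; ``cumulative`` also uses earlier post-impasse responses when
    multiple recommendations per trial are configured), assembles the
    exclusion set (all idea-space raw tokens, previously shown
    recommendations, and the object itself), and records the result and
    its display time on the trial.
    """
    pre = trial.responses_in_phase(Phase.PRE)
    if not pre:
        raise ValueError("trial has no pre-impasse responses")
    if trial.impasse_time is None:
        raise ValueError("impasse not marked")
    if idea_space_scope == "pre_only":
        texts = [r.text for r in pre]
    elif idea_space_scope == "cumulative":
        texts = [r.text for r in trial.responses]
    else:
        raise ValueError(f"unknown idea_space_scope: {idea_space_scope!r}")

    space = build_idea_space(texts, net, stoplist)
    exclusions = set(space.raw_tokens) | {trial.object}
    if trial.recommendation is not None:
        exclusions.add(trial.recommendation.word)

    request = RecommendationRequest(
        object=trial.object,
        distance=trial.distance,
        direction=trial.direction,
        idea_space=space,
        exclusions=exclusions,
    )
    rec = recommend(
        net,
        request,
        rng=rng,
        idea_space_mode=idea_space_mode,
        fallback_distance=fallback_distance,
    )
    trial.recommendation = rec
    trial.rec_shown_time = shown_time if shown_time is not None else trial.impasse_time
    return rec


def fluency(trial: Trial) -> tuple[int, int]:
    """(responses before impasse, responses after the recommendation)."""
    return (
        len(trial.responses_in_phase(Phase.PRE)),
        len(trial.responses_in_phase(Phase.POST)),
    )


def impasse_break(trial: Trial) -> int:
    """1 if at least one response followed the recommendation, else 0."""
    if trial.recommendation is None:
        raise ValueError("no recommendation was shown in this trial")
    return 1 if fluency(trial)[1] >= 1 else 0


def idea_order(trial: Trial) -> list[int]:
    """Serial-position coding centred on the impasse.

    The last pre-impasse response is coded 0 and earlier ones count back
    (-1, -2, ...); the first post-recommendation response is coded 1 and
    later ones count forward.
    """
    n_pre, n_post = fluency(trial)
    return list(range(-(n_pre - 1), 1)) + list(range(1, n_post + 1))


def response_times(trial: Trial) -> list[float]:
    """Thinking time per response: slot start until first keystroke."""
    rts = []
    for r in trial.responses:
        rt = r.t_typing - r.t_start
        if rt < 0:
            raise ValueError(
                f"clock skew: typing at {r.t_typing} before slot start {r.t_start}"
            )
        rts.append(rt)
    return rts


def close_far(distance: int) -> CloseFar:
    """Dichotomize the distance condition: 1-2 steps close, 3-4 far."""
    if distance in (1, 2):
        return CloseFar.CLOSE
    if distance in (3, 4):
        return CloseFar.FAR
    raise ValueError(f"distance {distance} outside the configured range 1-4")


TRIAL_TABLE_COLUMNS = [
    "participant_id",
    "trial_id",
    "object",
    "distance",
    "direction",
    "close_far",
    "fluency_before",
    "fluency_after",
    "impasse_break",
    "fallback_used",
    "recommendation",
    "mean_adherence",
    "originality_pre",
    "originality_post",
]


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def trial_table(
    session: SessionLog,
    net: SemanticNetwork | None = None,
    stoplist: set[str] | None = None,
) -> pd.DataFrame:
    """One row of outcome measures per trial, in a fixed column order.

    Adherence of post-impasse responses is computed only when a network
    and stoplist are supplied. Trials without a recommendation get missing
    values in every recommendation-dependent column. Originality columns
    average the externally supplied ratings per phase.
    """
    rows = []
    for trial in session.trials:
        n_pre, n_post = fluency(trial)
        rec = trial.recommendation
        row: dict = {
            "participant_id": session.participant_id,
            "trial_id": trial.trial_id,
            "object": trial.object,
            "distance": trial.distance,
            "direction": Direction(trial.direction).value,
            "close_far": close_far(trial.distance).value,
            "fluency_before": n_pre,
            "fluency_after": n_post,
            "impasse_break": impasse_break(trial) if rec is not None else float("nan"),
            "fallback_used": Fallback(rec.fallback_used).value if rec is not None else None,
            "recommendation": rec.word if rec is not None else None,
            "mean_adherence": float("nan"),
            "originality_pre": _mean_or_nan(
                [r.originality for r in trial.responses_in_phase(Phase.PRE) if r.originality is not None]
            ),
            "originality_post": _mean_or_nan(
                [r.originality for r in trial.responses_in_phase(Phase.POST) if r.originality is not None]
            ),
        }
        if rec is not None and net is not None and stoplist is not None:
            scores = []
            for r in trial.responses_in_phase(Phase.POST):
                a = adherence(net, rec.word, r.text, stoplist)
                if a is not None:
                    scores.append(a)
            row["mean_adherence"] = _mean_or_nan(scores)
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
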