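"""The word recommendation algorithm.

Given an object word (the divergent-thinking cue), a requested graph
distance, a direction, and the participant's idea space, the recommender:

1. collects every network word at exactly the requested shortest-path
   distance from the object (the exact-distance ring);
2. scores each ring member by its mean shortest-path length to the
   in-network idea-space tokens;
3. picks the minimum-score word for a TOWARDS recommendation, the
   maximum-score word for AWAY, skipping excluded words (words the
   participant already used, the object itself, previously shown
   recommendations) in favour of the next best candidate.

Ties are broken lexicographically so the pick is a deterministic function
of its inputs. When the idea space has no in-network token the direction
score is undefined, and the recommendation is a uniform seeded draw from
the eligible ring, flagged via ``fallback_used``.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .ideaspace import IdeaSpace
from .network import SemanticNetwork, nodes_at_distance

__all__ = [
    "Direction",
    "Fallback",
    "RecommendationRequest",
    "Recommendation",
    "rank_candidates",
    "recommend",
]


class Direction(str, enum.Enum):
    """Direction of a recommendation relative to the participant's prior ideas."""

    TOWARDS = "towards"
    AWAY = "away"


class Fallback(str, enum.Enum):
    NONE = "none"
    #: Idea space had no in-network token; uniform seeded draw from the ring.
    EMPTY_IDEA_SPACE_RANDOM = "empty_idea_space_random"
    #: Requested ring empty/exhausted; nearest alternative distance used
    #: (only when explicitly enabled).
    NEAREST_DISTANCE = "nearest_distance"


@dataclass
class RecommendationRequest:
    """One recommendation query: object, condition, idea space, exclusions."""

    object: str
    distance: int
    direction: Direction
    idea_space: IdeaSpace
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        self.direction = Direction(self.direction)


@dataclass
class Recommendation:
    """A recommended word plus its condition and diagnostic scores."""

    word: str
    request: RecommendationRequest
    avg_distance_to_idea_space: float | None
    rank: int
    fallback_used: Fallback = Fallback.NONE
    #: Distance actually used; differs from request.distance only under the
    #: explicit nearest-distance fallback.
    distance_used: int = 0

    def __post_init__(self) -> None:
        if self.distance_used == 0:
            self.distance_used = self.request.distance


def rank_candidates(
    net: SemanticNetwork,
    object: str,
    distance: int,
    idea_space: IdeaSpace | Sequence[str] | set[str],
    idea_space_mode: str = "set",
) -> list[tuple[str, float]]:
    """Score and sort the exact-distance ring against the idea space.

    Returns every ring member paired with its mean shortest-path length to
    the idea-space tokens, sorted ascending by (score, token). The head of
    the list is the TOWARDS pick, the tail (under the descending reordering
    applied by :func:`recommend`) the AWAY pick.
    """
    if isinstance(idea_space, IdeaSpace):
        members = idea_space.members(idea_space_mode)
    else:
        members = sorted(idea_space)
    if not members:
        raise ValueError("empty idea space")
    ring = nodes_at_distance(net, object, distance)
    if not ring:
        raise ValueError(f"no candidates at distance {distance}")
    for t in members:
        net.require(t)

    # One BFS per distinct idea-space token, then score all candidates.
    totals: dict[str, float] = {c: 0.0 for c in ring}
    unique = sorted(set(members))
    weights = {t: members.count(t) for t in unique}
    denom = len(members)
    for t in unique:
        lengths = nx.single_source_shortest_path_length(net.graph, t)
        for c in ring:
            totals[c] += weights[t] * lengths[c]
    scored = [(c, totals[c] / denom) for c in ring]
    scored.sort(key=lambda pair: (pair[1], pair[0]))
    return scored


def recommend(
    net: SemanticNetwork,
    request: RecommendationRequest,
    rng: random.Random | None = None,
    idea_space_mode: str = "set",
    fallback_distance: bool = False,
) -> Recommendation:
    """Select the word recommendation for a request.

    TOWARDS returns the non-excluded ring member with the lowest mean
    distance to the idea space; AWAY the highest. If the requested ring is
    empty or fully excluded the call fails, unless ``fallback_distance`` is
    set, in which case distance-1 then distance+1 are tried and the shift
    is recorded on the result.
    """
    net.require(request.object)
    if request.idea_space.is_empty() and rng is None:
        raise ValueError(
            "empty idea space requires a seeded rng for the random fallback"
        )
    distances_to_try = [request.distance]
    if fallback_distance:
        if request.distance - 1 >= 1:
            distances_to_try.append(request.distance - 1)
        distances_to_try.append(request.distance + 1)

    last_err: Exception | None = None
    for d in distances_to_try:
        try:
            rec = _recommend_at_distance(net, request, d, rng, idea_space_mode)
        except ValueError as err:
            last_err = err
            continue
        if d != request.distance:
            rec.fallback_used = Fallback.NEAREST_DISTANCE
        return rec
    raise ValueError(
        f"exhausted candidates at distance {request.distance}"
    ) from last_err


def _recommend_at_distance(
    net: SemanticNetwork,
    request: RecommendationRequest,
    distance: int,
    rng: random.Random | None,
    idea_space_mode: str,
) -> Recommendation:
    net.require(request.object)

    if request.idea_space.is_empty():
        ring = nodes_at_distance(net, request.object, distance)
        eligible = sorted(ring - request.exclusions)
        if not eligible:
            raise ValueError(f"no candidates at distance {distance}")
        word = eligible[rng.randrange(len(eligible))]
        return Recommendation(
            word=word,
            request=request,
            avg_distance_to_idea_space=None,
            rank=eligible.index(word),
            fallback_used=Fallback.EMPTY_IDEA_SPACE_RANDOM,
            distance_used=distance,
        )

    ranked = rank_candidates(
        net, request.object, distance, request.idea_space, idea_space_mode
    )
    if request.direction is Direction.AWAY:
        # Descending by score; lexicographic tie-break kept ascending.
        ranked = sorted(ranked, key=lambda pair: (-pair[1], pair[0]))
    for rank, (word, score) in enumerate(ranked):
        if word in request.exclusions:
            continue  # "the next best word is selected"
        return Recommendation(
            word=word,
            request=request,
            avg_distance_to_idea_space=score,
            rank=rank,
            distance_used=distance,
        )
    raise ValueError(f"no candidates at distance {distance}")
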