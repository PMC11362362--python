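"""Semantic memory network construction and graph-distance primitives.

A semantic memory network is an undirected, unweighted graph whose nodes
are words and whose edges are free-association links: an edge joins two
words when enough people produced one as a free association to the other.
Word recommendations are selected by shortest-path distance on this graph,
so this module provides the distance primitives (exact-distance rings,
pairwise path lengths, mean distance to a word set) that the recommender
builds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Collection, Iterable

import networkx as nx

__all__ = [
    "INF",
    "AssociationRecord",
    "SemanticNetwork",
    "normalize_token",
    "build_network",
    "largest_connected_component",
    "shortest_path_length",
    "nodes_at_distance",
    "avg_distance_to_set",
]

#: Sentinel returned for disconnected word pairs (cannot occur after the
#: largest-connected-component filter).
INF = math.inf


def normalize_token(token: str) -> str:
    """Lower-case a word token and trim surrounding whitespace."""
    return token.strip().lower()


@dataclass(frozen=True)
class AssociationRecord:
    """One observed cue -> response free association with its count.

    ``count`` is the number of participants who produced ``response`` as
    an association to ``cue`` in the norming dataset.
    """

    cue: str
    response: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(
                f"malformed record: negative count {self.count} "
                f"for {self.cue!r} -> {self.response!r}"
            )
        if not self.cue or not self.response:
            raise ValueError("malformed record: empty cue or response token")

    def normalized(self) -> "AssociationRecord":
        return AssociationRecord(
            normalize_token(self.cue), normalize_token(self.response), self.count
        )


@dataclass
class SemanticNetwork:
    """Undirected, unweighted word graph used as the recommendation substrate.

    Wraps a :class:`networkx.Graph` plus the construction metadata
    (count threshold, counting mode, whether the largest-connected-component
    filter was applied).
    """

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def __contains__(self, token: str) -> bool:
        return token in self.graph

    def require(self, token: str) -> None:
        """Raise if ``token`` is not a network node."""
        if token not in self.graph:
            raise ValueError(f"out-of-network word: {token!r}")

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


def _pool_counts(
    records: Iterable[AssociationRecord],
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], int]]:
    """Aggregate directed and unordered-pair (pooled) counts."""
    directed: dict[tuple[str, str], int] = {}
    pooled: dict[tuple[str, str], int] = {}
    for rec in records:
        rec = rec.normalized()
        if rec.cue == rec.response:
            continue  # self-associations can never form an edge
        key = (rec.cue, rec.response)
        directed[key] = directed.get(key, 0) + rec.count
        pair = tuple(sorted((rec.cue, rec.response)))
        pooled[pair] = pooled.get(pair, 0) + rec.count
    return directed, pooled


def build_network(
    records: list[AssociationRecord],
    min_count: int = 10,
    count_mode: str = "pooled",
) -> SemanticNetwork:
    """Build the semantic memory network from association records.

    An edge joins an unordered word pair {a, b} when enough participants
    associated the pair. Two counting modes are supported:

    - ``"pooled"`` (default): the a->b and b->a counts are summed before
      thresholding, reading "pair" as unordered.
    - ``"either_direction"``: the edge exists if either single directed
      count alone reaches ``min_count``.

    Words that never reach the threshold on any pair are excluded: they can
    never be recommended and contribute no finite path.

    Parameters
    ----------
    records
        Observed associations; normalized (lower-case, trimmed) on entry.
    min_count
        Inclusive threshold on the participant count (default 10 people).
    count_mode
        ``"pooled"`` or ``"either_direction"``.
    """
    if not records:
        raise ValueError("no associations")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if count_mode not in ("pooled", "either_direction"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")

    directed, pooled = _pool_counts(records)

    graph = nx.Graph()
    if count_mode == "pooled":
        for (a, b), total in pooled.items():
            if total >= min_count:
                graph.add_edge(a, b)
    else:
        for (a, b), total in directed.items():
            if total >= min_count:
                graph.add_edge(a, b)

    return SemanticNetwork(
        graph,
        metadata={
            "min_count": min_count,
            "count_mode": count_mode,
            "lcc": False,
        },
    )


def largest_connected_component(net: SemanticNetwork) -> SemanticNetwork:
    """Restrict the network to its largest connected component.

    Ties between equal-size components are broken deterministically in
    favour of the component containing the lexicographically smallest
    node label.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network has no connected component")
    components = sorted(
        nx.connected_components(net.graph),
        key=lambda comp: (-len(comp), min(comp)),
    )
    largest = components[0]
    sub = net.graph.subgraph(largest).copy()
    metadata = dict(net.metadata)
    metadata["lcc"] = True
    return SemanticNetwork(sub, metadata)


def shortest_path_length(net: SemanticNetwork, a: str, b: str) -> float:
    """Number of edges on a shortest path between two in-network words.

    Returns 0 when ``a == b`` and :data:`INF` when the words are
    disconnected (impossible after the largest-connected-component filter).
    """
    net.require(a)
    net.require(b)
    try:
        return nx.shortest_path_length(net.graph, a, b)
    except nx.NetworkXNoPath:
        return INF


def nodes_at_distance(net: SemanticNetwork, source: str, d: int) -> set[str]:
    """The exact-distance ring: all words at shortest-path distance ``d``.

    This is a ring, not a ball — words strictly closer than ``d`` are
    excluded. Ring 0 is the source itself.
    """
    net.require(source)
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    lengths = nx.single_source_shortest_path_length(net.graph, source, cutoff=d)
    return {node for node, dist in lengths.items() if dist == d}


def avg_distance_to_set(
    net: SemanticNetwork, word: str, targets: Collection[str]
) -> float:
    """Arithmetic mean shortest-path length from ``word`` to a word set.

    ``targets`` is treated with set semantics (duplicates collapse).
    Raises when the target set is empty: direction scoring is undefined
    for an empty idea space, and callers must apply their fallback.
    """
    net.require(word)
    unique = set(targets)
    if not unique:
        raise ValueError("empty idea space")
    for t in unique:
        net.require(t)
    lengths = nx.single_source_shortest_path_length(net.graph, word)
    total = 0.0
    for t in unique:
        if t not in lengths:
            return INF
        total += lengths[t]
    return total / len(unique)
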