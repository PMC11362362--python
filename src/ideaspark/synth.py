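"""Synthetic association data and simulated participants.

Free-association norms large enough to build a useful semantic network
are external downloads, so everything here exists to make the full
pipeline runnable and testable from scratch: a fixed 7-node toy network
mirroring the canonical brick example, planted random graphs emitted as
association records (so network construction can be round-tripped), and a
random-walk participant agent that produces complete, schema-valid trial
sessions. The agent is a testing device, not a cognitive model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .ideaspace import default_stoplist
from .network import AssociationRecord, SemanticNetwork, build_network
from .recommend import Direction
from .session import (
    Phase,
    ResponseEvent,
    SessionLog,
    Trial,
    assign_conditions,
    next_recommendation,
)

__all__ = [
    "PlantedGraphSpec",
    "SimulatedAgentSpec",
    "toy_network_T1",
    "planted_graph",
    "generate_association_records",
    "simulate_participant",
    "simulate_study",
]


def toy_network_T1() -> SemanticNetwork:
    """Fixed 7-node tree for worked examples and exact-value tests.

    A brick is linked to the wall/house/garden chain on one side and the
    fire/flare chain on the other, so distance-2 candidates from "brick"
    are {house, flare}: with idea space {wall}, "house" is the towards
    pick (mean distance 1) and "flare" the away pick (mean distance 3).
    """
    g = nx.Graph()
    g.add_edges_from(
        [
            ("brick", "wall"),
            ("wall", "house"),
            ("house", "garden"),
            ("garden", "flower"),
            ("brick", "fire"),
            ("fire", "flare"),
        ]
    )
    return SemanticNetwork(g, metadata={"min_count": 10, "count_mode": "pooled", "lcc": True})


@dataclass
class PlantedGraphSpec:
    """Parameters for a planted connected random graph and its records."""

    n_nodes: int = 30
    edge_probability: float = 0.12
    seed: int = 0
    min_count: int = 10
    #: Non-edges that also receive (sub-threshold) association records,
    #: to exercise the count threshold.
    n_noise_nonedges: int = 10


def planted_graph(spec: PlantedGraphSpec) -> nx.Graph:
    """A connected Erdos-Renyi graph with word-like node labels.

    Regenerates with an incremented seed until connected.
    """
    attempt = 0
    while True:
        g = nx.gnp_random_graph(
            spec.n_nodes, spec.edge_probability, seed=spec.seed + attempt
        )
        if g.number_of_nodes() > 0 and nx.is_connected(g):
            break
        attempt += 1
        if attempt > 1000:
            raise RuntimeError("could not generate a connected planted graph")
    return nx.relabel_nodes(g, {i: f"w{i:03d}" for i in g.nodes})


def generate_association_records(
    spec: PlantedGraphSpec, rng: random.Random | None = None
) -> tuple[list[AssociationRecord], nx.Graph]:
    """Emit association records whose thresholded reconstruction is the planted graph.

    Every planted edge receives a pooled count >= ``min_count`` split
    across the two directions; a controlled set of non-edges receives
    pooled counts <= ``min_count - 1``. Feeding the records back through
    :func:`~ideaspark.network.build_network` therefore reproduces the
    planted edge set exactly.
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    graph = planted_graph(spec)
    records: list[AssociationRecord] = []

    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        pooled = spec.min_count + rng.randrange(0, 6)
        fwd = rng.randrange(0, pooled + 1)
        rev = pooled - fwd
        if fwd:
            records.append(AssociationRecord(a, b, fwd))
        if rev:
            records.append(AssociationRecord(b, a, rev))
        if not fwd and not rev:  # pooled == 0 impossible (min_count >= 1)
            records.append(AssociationRecord(a, b, pooled))

    nodes = sorted(graph.nodes)
    non_edges = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if not graph.has_edge(a, b)
    ]
    rng.shuffle(non_edges)
    for a, b in non_edges[: spec.n_noise_nonedges]:
        if spec.min_count <= 1:
            break
        pooled = rng.randrange(1, spec.min_count)
        fwd = rng.randrange(0, pooled + 1)
        rev = pooled - fwd
        if fwd:
            records.append(AssociationRecord(a, b, fwd))
        if rev:
            records.append(AssociationRecord(b, a, rev))
    return records, graph


@dataclass
class SimulatedAgentSpec:
    """Random-walk participant agent parameters.

    The agent "thinks of" pre-impasse responses by walking the network
    from the object, restarting at the object with probability
    ``restart_probability`` per step to emulate topic-tethered search,
    then responds after the recommendation with probability ``p_break``.
    """

    n_pre_responses: int = 3
    restart_probability: float = 0.2
    p_break: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.restart_probability <= 1.0:
            raise ValueError("restart_probability must be in [0, 1]")
        if not 0.0 <= self.p_break <= 1.0:
            raise ValueError("p_break must be in [0, 1]")
        if self.n_pre_responses < 1:
            raise ValueError("participants must give at least one pre-impasse response")


def _walk_step(net: SemanticNetwork, current: str, origin: str, spec: SimulatedAgentSpec, rng: random.Random) -> str:
    if rng.random() < spec.restart_probability:
        current = origin
    neighbors = sorted(net.graph.neighbors(current))
    return neighbors[rng.randrange(len(neighbors))] if neighbors else current


def simulate_participant(
    net: SemanticNetwork,
    object: str,
    agent: SimulatedAgentSpec,
    condition: tuple[int, Direction],
    rng: random.Random,
    trial_id: str = "t0",
    stoplist: set[str] | None = None,
) -> Trial:
    """Simulate one complete trial: walk, impasse, recommendation, maybe a break."""
    net.require(object)
    stoplist = stoplist if stoplist is not None else default_stoplist()
    distance, direction = condition
    trial = Trial(trial_id=trial_id, object=object, distance=distance, direction=direction)

    clock = 0.0
    current = object
    for _ in range(agent.n_pre_responses):
        current = _walk_step(net, current, object, agent, rng)
        think = round(rng.uniform(1.0, 8.0), 3)
        write = round(rng.uniform(1.0, 5.0), 3)
        trial.responses.append(
            ResponseEvent(
                trial_id=trial_id,
                text=current,
                phase=Phase.PRE,
                t_start=round(clock, 3),
                t_typing=round(clock + think, 3),
            )
        )
        clock = round(clock + think + write, 3)

    trial.impasse_time = clock
    shown = round(clock + round(rng.uniform(0.5, 2.0), 3), 3)
    next_recommendation(
        trial, net, stoplist, rng=rng, fallback_distance=True, shown_time=shown
    )

    if rng.random() < agent.p_break:
        rec_word = trial.recommendation.word
        neighborhood = sorted(net.graph.neighbors(rec_word)) + [rec_word]
        text = neighborhood[rng.randrange(len(neighborhood))]
        think = round(rng.uniform(1.0, 8.0), 3)
        trial.responses.append(
            ResponseEvent(
                trial_id=trial_id,
                text=text,
                phase=Phase.POST,
                t_start=shown,
                t_typing=round(shown + think, 3),
            )
        )
    return trial


def simulate_study(
    n_participants: int,
    n_trials_each: int,
    net: SemanticNetwork,
    agent: SimulatedAgentSpec,
    rng: random.Random | None = None,
    seed: int | None = None,
    distance_range=(1, 2, 3, 4),
    stoplist: set[str] | None = None,
) -> list[SessionLog]:
    """Simulate a full study: each participant sees distinct objects.

    A single seeded random stream drives every choice, so identical seeds
    replay identical sessions byte for byte.
    """
    if seed is None:
        seed = 0
    rng = rng if rng is not None else random.Random(seed)
    stoplist = stoplist if stoplist is not None else default_stoplist()
    nodes = sorted(net.nodes)
    if len(nodes) < n_trials_each:
        raise ValueError("network too small for the requested number of trial objects")

    sessions = []
    for p in range(n_participants):
        participant_id = f"p{p:03d}"
        objects = rng.sample(nodes, n_trials_each)
        conditions = assign_conditions(
            n_trials_each, distance_range=distance_range, rng=rng
        )
        trials = []
        for k, (obj, cond) in enumerate(zip(objects, conditions)):
            trials.append(
                simulate_participant(
                    net,
                    obj,
                    agent,
                    cond,
                    rng,
                    trial_id=f"{participant_id}-t{k}",
                    stoplist=stoplist,
                )
            )
        sessions.append(
            SessionLog(
                participant_id=participant_id,
                seed=seed,
                trials=trials,
                config={
                    "n_trials": n_trials_each,
                    "distance_range": list(distance_range),
                    "p_break": agent.p_break,
                    "restart_probability": agent.restart_probability,
                    "n_pre_responses": agent.n_pre_responses,
                },
            )
        )
    return sessions
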