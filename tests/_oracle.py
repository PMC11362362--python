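"""Brute-force all-pairs shortest-path oracle, independent of networkx.

Plain Floyd-Warshall over an adjacency dict; used to cross-check every
graph-distance primitive in the package.
"""

from __future__ import annotations

import itertools
import math


def all_pairs_shortest_paths(
    nodes: list[str], edges: list[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    dist = {(a, b): (0.0 if a == b else math.inf) for a in nodes for b in nodes}
    for a, b in edges:
        dist[(a, b)] = 1.0
        dist[(b, a)] = 1.0
    for k, i, j in itertools.product(nodes, nodes, nodes):
        via = dist[(i, k)] + dist[(k, j)]
        if via < dist[(i, j)]:
            dist[(i, j)] = via
    return dist


def ring(
    dist: dict[tuple[str, str], float], nodes: list[str], source: str, d: int
) -> set[str]:
    return {n for n in nodes if dist[(source, n)] == d}


def mean_distance(
    dist: dict[tuple[str, str], float], word: str, targets: set[str]
) -> float:
    return sum(dist[(word, t)] for t in targets) / len(targets)
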