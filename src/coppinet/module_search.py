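"""Dense module search on CoPPI networks.

A module is a connected set of edges with score Em = mean component-edge
weight. The search seeds from every edge with weight >= 0.5 and grows
greedily: at each step the candidate edge (any CoPPI edge not yet in the
module with at least one endpoint among the module's nodes) that maximizes
the resulting Em is considered, and accepted only if it strictly improves
Em. Because Em_new = (S + w) / (m + 1) is increasing in w for a fixed
module, the best candidate is always the maximum-weight one and the
acceptance test reduces to w > Em_current; the greedy loop therefore runs
on a max-heap of candidate edges. By construction every returned module has
Em >= its seed weight and every accepted edge's weight exceeds the module
score at the moment of acceptance, hence all component edges sit at or
above the seed threshold.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from coppinet.network import CoppiNetwork


@dataclass(frozen=True)
class Module:
    """A connected weighted subnetwork accepted by the dense module search."""

    point: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str, float], ...]  # (u, v, weight), u < v
    em: float

    @property
    def module_id(self) -> str:
        """Canonical identity: the sorted, semicolon-joined gene list."""
        return ";".join(sorted(self.nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def module_score(edge_weights) -> float:
    """Module score Em: the arithmetic mean of the component edge weights."""
    weights = list(edge_weights)
    if not weights:
        raise ValueError("module score undefined for an empty edge set")
    return float(sum(weights)) / len(weights)


def seed_edges(
    coppi: CoppiNetwork, min_weight: float = 0.5
) -> list[tuple[str, str, float]]:
    """All edges with weight >= ``min_weight`` (boundary inclusive).

    Sorted by descending weight, then lexicographic endpoints, so the search
    iterates seeds deterministically.
    """
    seeds = [
        (min(u, v), max(u, v), float(d["weight"]))
        for u, v, d in coppi.graph.edges(data=True)
        if d["weight"] >= min_weight
    ]
    seeds.sort(key=lambda e: (-e[2], e[0], e[1]))
    return seeds


def expand_module(coppi: CoppiNetwork, seed: tuple[str, str, float] | tuple[str, str]) -> Module:
    """Grow a module from a seed edge under the strict-improvement rule.

    Candidates are all CoPPI edges not yet in the module with >=1 endpoint
    among the module's nodes — both node-adding and densifying edges
    qualify. Ties between equal-weight candidates resolve to lexicographic
    endpoint order. Growth stops when the best candidate no longer strictly
    improves Em.
    """
    g = coppi.graph
    u, v = seed[0], seed[1]
    if not g.has_edge(u, v):
        raise ValueError(f"seed edge ({u}, {v}) not present in the CoPPI network")
    u, v = min(u, v), max(u, v)
    w0 = float(g[u][v]["weight"])

    nodes = {u, v}
    accepted: dict[frozenset, float] = {frozenset((u, v)): w0}
    total = w0
    count = 1

    heap: list[tuple[float, str, str]] = []
    pushed = {frozenset((u, v))}

    def push_incident(x: str) -> None:
        for y in g[x]:
            key = frozenset((x, y))
            if key not in pushed:
                pushed.add(key)
                a, b = (x, y) if x < y else (y, x)
                heapq.heappush(heap, (-float(g[x][y]["weight"]), a, b))

    push_incident(u)
    push_incident(v)

    while heap:
        neg_w, a, b = heap[0]
        w = -neg_w
        if w <= total / count:  # best candidate cannot strictly improve Em
            break
        heapq.heappop(heap)
        accepted[frozenset((a, b))] = w
        total += w
        count += 1
        for x in (a, b):
            if x not in nodes:
                nodes.add(x)
                push_incident(x)

    edges = tuple(
        sorted(
            (min(pair), max(pair), w)
            for pair, w in ((tuple(k), w) for k, w in accepted.items())
        )
    )
    return Module(
        point=coppi.point,
        nodes=frozenset(nodes),
        edges=edges,
        em=total / count,
    )


def search_modules(
    coppi: CoppiNetwork, min_weight: float = 0.5, min_nodes: int = 4
) -> list[Module]:
    """Run the dense module search from every seed edge.

    Modules smaller than ``min_nodes`` are discarded; modules converging to
    the same node set are collapsed to the realization with the higher Em.
    The output is sorted by descending Em, then by module id, and is
    deterministic for a given CoPPI.
    """
    best: dict[frozenset, Module] = {}
    for seed in seed_edges(coppi, min_weight):
        mod = expand_module(coppi, seed)
        if mod.n_nodes < min_nodes:
            continue
        prev = best.get(mod.nodes)
        if prev is None or mod.em > prev.em:
            best[mod.nodes] = mod
    out = list(best.values())
    out.sort(key=lambda m: (-m.em, m.module_id))
    return out
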