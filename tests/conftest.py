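import networkx as nx
import numpy as np
import pandas as pd
import pytest

from herdflow.build import LinkAttributes, MobilityNetwork
from herdflow.simulate import SimulationConfig, generate_dataset


def net_from_volumes(volumes: dict, window=None) -> MobilityNetwork:
    """Minimal weighted network from a {(origin, destination): volume} map."""
    g = nx.DiGraph()
    for (o, d), w in volumes.items():
        g.add_edge(
            o,
            d,
            attrs=LinkAttributes(
                volume=int(w),
                n_movements=1,
                months_active=frozenset({1}),
                species_volume={"small_ruminants": int(w)},
                transport_volume={"foot": int(w)},
            ),
        )
    return MobilityNetwork(graph=g, window=window or frozenset(range(1, 13)))


def random_volume_net(rng: np.random.Generator, n_nodes: int, p: float = 0.3,
                      max_w: int = 100) -> MobilityNetwork:
    vols = {}
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                vols[(f"n{i}", f"n{j}")] = int(rng.integers(1, max_w))
    return net_from_volumes(vols)


def movement_row(origin="a", destination="b", month=1, species="small_ruminants",
                 head_count=10, transport="foot", origin_activity="zone_elevage",
                 destination_activity="market", scope="national"):
    return {
        "origin_id": origin, "destination_id": destination, "month": month,
        "species": species, "head_count": head_count, "transport": transport,
        "origin_activity": origin_activity, "destination_activity": destination_activity,
        "scope": scope,
    }


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic year shared across read-only tests."""
    return generate_dataset(SimulationConfig(), seed=1)


@pytest.fixture
def table1_toy():
    """The printed origin x destination activity counts re-entered as a toy
    movement table (one unit-head row per counted movement)."""
    cells = [
        ("zone_elevage", "slaughterhouse", 51),
        ("zone_elevage", "zone_elevage", 1072),
        ("zone_elevage", "market", 1136),
        ("zone_elevage", "resting_area", 4),
        ("market", "zone_elevage", 18),
        ("market", "market", 104),
    ]
    rows = []
    for origin_activity, destination_activity, count in cells:
        rows.extend(
            movement_row(
                origin_activity=origin_activity,
                destination_activity=destination_activity,
                head_count=1,
            )
            for _ in range(count)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (no networkx, plain dict/loop code)


def brute_nodal_regions(volumes: dict, threshold: float = 0.2):
    """Exhaustive dominant-flow computation straight from the definitions."""
    out_vol: dict = {}
    for (o, _), w in volumes.items():
        out_vol[o] = out_vol.get(o, 0) + w
    pruned = {
        (o, d): w for (o, d), w in volumes.items() if w / out_vol[o] > threshold
    }
    in_vol: dict = {}
    for (_, d), w in pruned.items():
        in_vol[d] = in_vol.get(d, 0) + w
    assignments = {}
    for i in sorted({o for o, _ in pruned}):
        cands = [(d, w) for (o, d), w in pruned.items() if o == i]
        j = min(cands, key=lambda dw: (-dw[1], -in_vol.get(dw[0], 0), dw[0]))[0]
        if in_vol.get(j, 0) > in_vol.get(i, 0):
            assignments[i] = j
    dominant = {p for p in set(assignments.values()) if p not in assignments}
    return assignments, dominant


def brute_graph_metrics(nodes: list, edges: set):
    """Transitivity, components and diameter by direct enumeration."""
    adj = {n: set() for n in nodes}
    for o, d in edges:
        if o != d:
            adj[o].add(d)
            adj[d].add(o)

    closed = 0
    triples = 0
    for a in nodes:
        neigh = sorted(adj[a])
        k = len(neigh)
        triples += k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                if neigh[j] in adj[neigh[i]]:
                    closed += 1
    transitivity = closed / triples if triples else 0.0

    def reach_undirected(start):
        seen, stack = {start}, [start]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    weak_comps = []
    left = set(nodes)
    while left:
        comp = reach_undirected(next(iter(sorted(left))))
        weak_comps.append(comp)
        left -= comp

    succ = {n: set() for n in nodes}
    for o, d in edges:
        if o != d:
            succ[o].add(d)

    def reach_directed(start):
        seen, stack = {start}, [start]
        while stack:
            for nxt in succ[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    fwd = {n: reach_directed(n) for n in nodes}
    largest_strong = max(
        (sum(1 for m in nodes if n in fwd[m] and m in fwd[n]) for n in nodes),
        default=0,
    )

    giant = max(weak_comps, key=len) if weak_comps else set()
    diameter = 0
    for s in giant:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt_frontier = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt_frontier.append(v)
            frontier = nxt_frontier
        diameter = max(diameter, max(dist.values(), default=0))

    return {
        "transitivity": transitivity,
        "largest_weak": max((len(c) for c in weak_comps), default=0),
        "largest_strong": largest_strong,
        "n_components": len(weak_comps),
        "diameter": diameter,
    }
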