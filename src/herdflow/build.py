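"""Aggregate movement records into directed, weighted O-D networks.

A link is drawn between an origin-destination pair as soon as at least one
animal moved between them inside the chosen month window; all matching
records are aggregated onto it. "Frequency" means the number of records on
a link and "volume" the total head count — the two are never conflated.
Monthly snapshots are the same construction restricted to a single month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .records import SPECIES, TRANSPORT_MODES, SCOPES

FULL_YEAR: frozenset = frozenset(range(1, 13))


@dataclass(frozen=True)
class LinkAttributes:
    """Aggregated features of one O-D link."""

    volume: int
    n_movements: int
    months_active: frozenset
    species_volume: Mapping[str, int]
    transport_volume: Mapping[str, int]
    scope: str | None = None

    def __post_init__(self) -> None:
        if self.volume < 1:
            raise ValueError("link volume must be >= 1")


@dataclass
class MobilityNetwork:
    """A directed, weighted, attributed mobility network.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry a single
    ``attrs`` :class:`LinkAttributes`. ``records`` keeps the contributing
    movement rows when the network was built from a table, which makes
    filtered views exact re-aggregations rather than lossy projections;
    networks re-imported from edge lists carry ``records=None``.
    """

    graph: nx.DiGraph
    window: frozenset = FULL_YEAR
    filters: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def links(self) -> dict:
        return {(o, d): data["attrs"] for o, d, data in self.graph.edges(data=True)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_volume(self) -> int:
        return sum(data["attrs"].volume for _, _, data in self.graph.edges(data=True))

    def link(self, origin: str, destination: str) -> LinkAttributes:
        return self.graph.edges[origin, destination]["attrs"]

    def weight_map(self) -> dict:
        """Link -> volume mapping, the weighted-Jaccard currency."""
        return {k: a.volume for k, a in self.links.items()}

    def out_volume(self, node: str) -> int:
        return sum(d["attrs"].volume for _, _, d in self.graph.out_edges(node, data=True))

    def in_volume(self, node: str) -> int:
        return sum(d["attrs"].volume for _, _, d in self.graph.in_edges(node, data=True))

    def undirected(self) -> nx.Graph:
        """Direction-agnostic projection used for clustering/diameter."""
        return self.graph.to_undirected(as_view=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MobilityNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.links == other.links
            and self.window == other.window
        )


def _matching_records(
    table: pd.DataFrame,
    window: Iterable[int],
    species: str | None = None,
    transport: str | None = None,
    scope: str | None = None,
) -> pd.DataFrame:
    mask = table["month"].isin(set(window))
    for col, value, allowed in (
        ("species", species, SPECIES),
        ("transport", transport, TRANSPORT_MODES),
        ("scope", scope, SCOPES),
    ):
        if value is not None:
            if value not in allowed:
                raise ValueError(f"unknown {col} token {value!r}; allowed: {list(allowed)}")
            if col not in table.columns:
                raise ValueError(f"table has no {col!r} column to filter on")
            mask &= table[col] == value
    return table[mask]


def build_network(
    table: pd.DataFrame,
    window: Iterable[int] | None = None,
    species: str | None = None,
    transport: str | None = None,
    scope: str | None = None,
) -> MobilityNetwork:
    """Aggregate records matching ``window`` and filters into one network.

    Nodes are exactly the endpoints of surviving links; endpoints of
    filtered-out records do not appear. Self-loops (origin == destination)
    are dropped with a warning — the O-D framing implies distinct endpoints.
    """
    window_set = frozenset(window) if window is not None else FULL_YEAR
    if not window_set:
        raise ValueError("empty month window")
    bad = window_set - FULL_YEAR
    if bad:
        raise ValueError(f"window months outside 1..12: {sorted(bad)}")

    sub = _matching_records(table, window_set, species, transport, scope)
    n_self = int((sub["origin_id"] == sub["destination_id"]).sum())
    if n_self:
        warnings.warn(f"dropping {n_self} self-loop record(s)", stacklevel=2)
        sub = sub[sub["origin_id"] != sub["destination_id"]]

    g = nx.DiGraph()
    for (o, d), grp in sub.groupby(["origin_id", "destination_id"], sort=True):
        species_vol = grp.groupby("species")["head_count"].sum().to_dict()
        transport_vol = grp.groupby("transport")["head_count"].sum().to_dict()
        link_scope = None
        if "scope" in grp.columns:
            scopes = set(grp["scope"])
            link_scope = scopes.pop() if len(scopes) == 1 else None
        attrs = LinkAttributes(
            volume=int(grp["head_count"].sum()),
            n_movements=int(len(grp)),
            months_active=frozenset(int(m) for m in grp["month"].unique()),
            species_volume={k: int(v) for k, v in species_vol.items()},
            transport_volume={k: int(v) for k, v in transport_vol.items()},
            scope=link_scope,
        )
        g.add_edge(o, d, attrs=attrs)

    applied = {
        k: v
        for k, v in (("species", species), ("transport", transport), ("scope", scope))
        if v is not None
    }
    return MobilityNetwork(
        graph=g, window=window_set, filters=applied, records=sub.reset_index(drop=True)
    )


def monthly_snapshots(
    table: pd.DataFrame,
    species: str | None = None,
    transport: str | None = None,
    scope: str | None = None,
) -> list[MobilityNetwork]:
    """Twelve monthly networks; months with no matching records are empty."""
    return [
        build_network(table, window={m}, species=species, transport=transport, scope=scope)
        for m in range(1, 13)
    ]


def filter_view(
    obj: pd.DataFrame | MobilityNetwork,
    species: str | None = None,
    transport: str | None = None,
    scope: str | None = None,
):
    """Restrict a table or network to matching records; same kind returned.

    Networks must carry their contributing records (built from a table);
    the view is an exact re-aggregation, so chained filters commute.
    """
    if isinstance(obj, pd.DataFrame):
        return _matching_records(
            obj, obj["month"].unique(), species, transport, scope
        ).reset_index(drop=True)
    if isinstance(obj, MobilityNetwork):
        if obj.records is None:
            raise ValueError(
                "network carries no records (imported edge list?); filter the table instead"
            )
        merged = dict(obj.filters)
        for key, value in (("species", species), ("transport", transport), ("scope", scope)):
            if value is not None:
                merged[key] = value
        return build_network(obj.records, window=obj.window, **merged)
    raise TypeError(f"cannot filter object of type {type(obj).__name__}")
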