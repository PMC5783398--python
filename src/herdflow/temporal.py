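"""Temporal dynamics of monthly network snapshots.

Month-to-month change is quantified by the Jaccard index J over node or
link sets and by the weighted variant J' over link-volume maps:

    J  = |A intersect B| / |A union B|
    J' = sum_e min(w_A(e), w_B(e)) / sum_e max(w_A(e), w_B(e))

with absent links contributing weight zero and the both-empty case defined
as 1 (two empty snapshots are identical). The year is segmented into
mobility periods by contiguity-constrained agglomerative clustering of
snapshots under a Jaccard-based dissimilarity, and links are classified by
their number of active months into backbone (12), frequent (7-11),
intermediate (3-6) and occasional (1-2) persistence classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .build import MobilityNetwork, build_network

LINK_CLASSES = ("backbone", "frequent", "intermediate", "occasional")

#: Default index weights (nodes, links, volumes) for period detection: the
#: weighted index alone, since the regime break expresses itself most
#: sharply in link volumes.
DEFAULT_PERIOD_WEIGHTS = (0.0, 0.0, 1.0)


def jaccard_sets(a: set, b: set) -> float:
    """Plain Jaccard index of two sets; both empty -> 1 by convention."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def jaccard_weighted(a: Mapping, b: Mapping) -> float:
    """Weighted Jaccard: min-weight sum over max-weight sum on the union.

    Keys present in only one map contribute their full weight to the
    denominator and nothing to the numerator. Weights must be positive.
    """
    if any(w <= 0 for w in a.values()) or any(w <= 0 for w in b.values()):
        raise ValueError("weighted Jaccard requires positive weights")
    if not a and not b:
        return 1.0
    num = den = 0.0
    for key in set(a) | set(b):
        wa, wb = a.get(key, 0.0), b.get(key, 0.0)
        num += min(wa, wb)
        den += max(wa, wb)
    return num / den


@dataclass(frozen=True)
class JaccardSeries:
    """Jaccard indices over consecutive snapshot pairs (m, m+1)."""

    pairs: tuple  # ((1,2), (2,3), ...)
    j_nodes: tuple
    j_links: tuple
    j_weights: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month_a": [p[0] for p in self.pairs],
                "month_b": [p[1] for p in self.pairs],
                "j_nodes": self.j_nodes,
                "j_links": self.j_links,
                "j_weights": self.j_weights,
            }
        )


def _snapshot_indices(a: MobilityNetwork, b: MobilityNetwork) -> tuple[float, float, float]:
    return (
        jaccard_sets(a.nodes, b.nodes),
        jaccard_sets(set(a.links), set(b.links)),
        jaccard_weighted(a.weight_map(), b.weight_map()),
    )


def jaccard_series(snapshots: Sequence[MobilityNetwork]) -> JaccardSeries:
    """Node, link and volume Jaccard series over consecutive snapshots."""
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots for a Jaccard series")
    months = [min(s.window) if s.window else i + 1 for i, s in enumerate(snapshots)]
    pairs, jn, jl, jw = [], [], [], []
    for a, b, ma, mb in zip(snapshots, snapshots[1:], months, months[1:]):
        n, l, w = _snapshot_indices(a, b)
        pairs.append((ma, mb))
        jn.append(n)
        jl.append(l)
        jw.append(w)
    return JaccardSeries(tuple(pairs), tuple(jn), tuple(jl), tuple(jw))


def snapshot_dissimilarity(
    a: MobilityNetwork,
    b: MobilityNetwork,
    weights: tuple = DEFAULT_PERIOD_WEIGHTS,
) -> float:
    """1 minus the weighted mean of the three Jaccard indices."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("weights must be non-negative and sum to > 0")
    j = np.asarray(_snapshot_indices(a, b))
    return float(1.0 - (w * j).sum() / w.sum())


@dataclass(frozen=True)
class PeriodPartition:
    """Contiguous partition of the snapshot sequence into periods."""

    periods: tuple  # ((start, end), ...) inclusive month intervals
    merge_costs: tuple  # cost of each agglomerative merge, in order
    weights: tuple
    n_periods: int

    def labels(self) -> dict:
        """Month -> period index (0-based)."""
        out = {}
        for idx, (lo, hi) in enumerate(self.periods):
            for m in range(lo, hi + 1):
                out[m] = idx
        return out


def detect_periods(
    snapshots: Sequence[MobilityNetwork],
    weights: tuple = DEFAULT_PERIOD_WEIGHTS,
    n_periods: int | None = None,
) -> PeriodPartition:
    """Segment consecutive snapshots into homogeneous mobility periods.

    Agglomerative clustering under a contiguity constraint: only adjacent
    clusters may merge, the pair with the smallest average pairwise
    snapshot dissimilarity merges first, and merge costs are recorded. With
    ``n_periods=None`` the cut is placed at the largest jump in the merge
    cost sequence; if no jump exists (homogeneous year) a single period is
    returned. Fully deterministic; leftmost pair wins cost ties.
    """
    L = len(snapshots)
    if L < 2:
        raise ValueError("need at least 2 snapshots to detect periods")
    if n_periods is not None and not 1 <= n_periods <= L:
        raise ValueError(f"n_periods must lie in 1..{L}")
    months = [min(s.window) if s.window else i + 1 for i, s in enumerate(snapshots)]

    D = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            D[i, j] = D[j, i] = snapshot_dissimilarity(snapshots[i], snapshots[j], weights)

    clusters: list[list[int]] = [[i] for i in range(L)]
    states = []  # partition before each merge
    costs: list[float] = []
    while len(clusters) > 1:
        states.append([list(c) for c in clusters])
        pair_costs = [
            float(np.mean([D[i, j] for i in clusters[k] for j in clusters[k + 1]]))
            for k in range(len(clusters) - 1)
        ]
        k = int(np.argmin(pair_costs))
        costs.append(pair_costs[k])
        clusters[k] = clusters[k] + clusters.pop(k + 1)
    states.append([list(c) for c in clusters])

    eps = 1e-12
    if n_periods is not None:
        chosen = states[L - n_periods]
    elif costs[-1] <= eps:
        chosen = states[-1]  # all merges free: one homogeneous period
    else:
        gaps = np.diff(costs)
        if len(gaps) == 0 or gaps.max() <= eps:
            chosen = states[-1]
        else:
            # stop just before the costliest merge step
            m_star = int(np.argmax(gaps)) + 1  # 0-based index of that merge
            chosen = states[m_star]

    periods = tuple(
        (months[c[0]], months[c[-1]]) for c in chosen
    )
    return PeriodPartition(
        periods=periods,
        merge_costs=tuple(costs),
        weights=tuple(weights),
        n_periods=len(periods),
    )


# ---------------------------------------------------------------------------
# Link persistence classes


def persistence_class(n_months: int) -> str:
    """Map an active-month count to its persistence class."""
    if not 1 <= n_months <= 12:
        raise ValueError("active-month count must lie in 1..12")
    if n_months == 12:
        return "backbone"
    if n_months >= 7:
        return "frequent"
    if n_months >= 3:
        return "intermediate"
    return "occasional"


@dataclass(frozen=True)
class LinkClassMap:
    """Per-link active-month counts and persistence classes."""

    months_active: Mapping[tuple, frozenset]
    classes: Mapping[tuple, str]

    def links_of(self, cls: str) -> set:
        if cls not in LINK_CLASSES:
            raise ValueError(f"unknown class {cls!r}; allowed: {list(LINK_CLASSES)}")
        return {k for k, c in self.classes.items() if c == cls}

    def class_shares(self) -> dict:
        n = len(self.classes)
        return {
            cls: (len(self.links_of(cls)) / n if n else 0.0) for cls in LINK_CLASSES
        }


def classify_links(annual: MobilityNetwork) -> LinkClassMap:
    """Classify every link of a full-year network by its active months."""
    months = {k: a.months_active for k, a in annual.links.items()}
    classes = {k: persistence_class(len(m)) for k, m in months.items()}
    return LinkClassMap(months_active=months, classes=classes)


def class_subnetwork(
    annual: MobilityNetwork, class_map: LinkClassMap, cls: str
) -> MobilityNetwork:
    """Induced network of the links of one persistence class, volumes kept."""
    members = class_map.links_of(cls)
    if annual.records is not None:
        keys = list(zip(annual.records["origin_id"], annual.records["destination_id"]))
        mask = [k in members for k in keys]
        kwargs = {k: v for k, v in annual.filters.items() if k in ("species", "transport", "scope")}
        sub = build_network(annual.records[mask], window=annual.window, **kwargs)
        sub.filters["link_class"] = cls
        return sub
    import networkx as nx

    g = nx.DiGraph()
    for (o, d), attrs in annual.links.items():
        if (o, d) in members:
            g.add_edge(o, d, attrs=attrs)
    return MobilityNetwork(
        graph=g, window=annual.window,
        filters={**annual.filters, "link_class": cls}, records=None,
    )


def activity_raster(annual: MobilityNetwork) -> pd.DataFrame:
    """Boolean link x month activity matrix, row-annotated with class.

    One row per link with columns m1..m12 (True where the link was active),
    the active-month count and the persistence class — the tabular form of
    a link-activity timeline figure.
    """
    cmap = classify_links(annual)
    rows = []
    for (o, d) in sorted(annual.links):
        months = cmap.months_active[(o, d)]
        row = {"origin_id": o, "destination_id": d}
        row.update({f"m{m}": (m in months) for m in range(1, 13)})
        row["n_months"] = len(months)
        row["link_class"] = cmap.classes[(o, d)]
        rows.append(row)
    cols = ["origin_id", "destination_id"] + [f"m{m}" for m in range(1, 13)] + [
        "n_months", "link_class",
    ]
    return pd.DataFrame(rows, columns=cols)
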