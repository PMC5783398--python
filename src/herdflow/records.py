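"""Movement-record and gazetteer data model and tabular I/O.

The unit of observation is one recorded livestock movement: an origin and a
destination location, the month it happened, the species moved (sheep and
goats pooled as small ruminants, cattle, dromedaries), the number of heads,
the transport mode (on foot or by truck) and the activity type at each
endpoint. Movement tables are plain UTF-8 CSV with a header row; the
gazetteer is a second CSV with one row per location (WGS84 coordinates,
country code, semicolon-separated activity types).

A movement is *national* when both endpoints lie in the focal country and
*international* otherwise; the flag is derived at ingestion from the
gazetteer, never trusted from the input file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

ACTIVITIES: tuple[str, ...] = (
    "zone_elevage",
    "market",
    "slaughterhouse",
    "resting_area",
)
SPECIES: tuple[str, ...] = ("small_ruminants", "cattle", "dromedaries")
TRANSPORT_MODES: tuple[str, ...] = ("foot", "truck")
SCOPES: tuple[str, ...] = ("national", "international")
COORD_SOURCES: tuple[str, ...] = ("gps", "commune_centroid")

GAZETTEER_COLUMNS: tuple[str, ...] = ("id", "name", "country", "lon", "lat", "activities")
MOVEMENT_COLUMNS: tuple[str, ...] = (
    "origin_id",
    "destination_id",
    "month",
    "species",
    "head_count",
    "transport",
    "origin_activity",
    "destination_activity",
)

DEFAULT_FOCAL_COUNTRY = "MR"


@dataclass(frozen=True)
class Location:
    """A geocoded place taking part in livestock movements.

    ``activities`` is the non-empty set of roles the place plays
    (livestock-raising *zone d'elevage*, market, slaughterhouse, resting
    area); a single location may play several. ``coord_source`` records
    whether the point is a GPS reading or a commune-centroid fallback; the
    two are treated identically downstream.
    """

    id: str
    name: str
    country: str
    lon: float
    lat: float
    activities: frozenset = field(default_factory=frozenset)
    coord_source: str = "gps"

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"location {self.id!r}: lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"location {self.id!r}: lat {self.lat} outside [-90, 90]")
        if not self.activities:
            raise ValueError(f"location {self.id!r}: empty activity set")
        unknown = set(self.activities) - set(ACTIVITIES)
        if unknown:
            raise ValueError(
                f"location {self.id!r}: unknown activities {sorted(unknown)}; "
                f"allowed: {list(ACTIVITIES)}"
            )
        if self.coord_source not in COORD_SOURCES:
            raise ValueError(
                f"location {self.id!r}: coord_source {self.coord_source!r} "
                f"not in {list(COORD_SOURCES)}"
            )


class Gazetteer:
    """Immutable collection of :class:`Location`, keyed by unique id."""

    def __init__(self, locations: Iterable[Location]):
        self._by_id: dict[str, Location] = {}
        for loc in locations:
            if loc.id in self._by_id:
                raise ValueError(f"duplicate location id {loc.id!r} in gazetteer")
            self._by_id[loc.id] = loc

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Location]:
        return iter(self._by_id.values())

    def __contains__(self, loc_id: object) -> bool:
        return loc_id in self._by_id

    def __getitem__(self, loc_id: str) -> Location:
        return self._by_id[loc_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Gazetteer):
            return NotImplemented
        return self._by_id == other._by_id

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def country_of(self, loc_id: str) -> str:
        return self._by_id[loc_id].country

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": loc.id,
                "name": loc.name,
                "country": loc.country,
                "lon": loc.lon,
                "lat": loc.lat,
                "activities": ";".join(sorted(loc.activities)),
                "coord_source": loc.coord_source,
            }
            for loc in self
        ]
        return pd.DataFrame(rows, columns=list(GAZETTEER_COLUMNS) + ["coord_source"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Gazetteer":
        missing = [c for c in GAZETTEER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gazetteer table missing required column(s): {missing}")
        locations = []
        for idx, row in df.iterrows():
            try:
                lon, lat = float(row["lon"]), float(row["lat"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"gazetteer row {idx}: malformed coordinates") from exc
            activities = frozenset(
                a for a in str(row["activities"]).split(";") if a
            )
            coord_source = str(row.get("coord_source", "gps") or "gps")
            try:
                locations.append(
                    Location(
                        id=str(row["id"]),
                        name=str(row["name"]),
                        country=str(row["country"]),
                        lon=lon,
                        lat=lat,
                        activities=activities,
                        coord_source=coord_source,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"gazetteer row {idx}: {exc}") from exc
        return cls(locations)


@dataclass
class ValidationReport:
    """Outcome of movement-table ingestion.

    ``n_records`` counts the rows retained after cleaning; duplicates and
    records pointing at locations absent from the gazetteer are counted, not
    silently discarded.
    """

    n_records: int = 0
    n_dropped_duplicates: int = 0
    n_unknown_locations: int = 0
    warnings: list = field(default_factory=list)


def read_gazetteer(path: str | Path, **csv_kwargs) -> Gazetteer:
    """Read a location gazetteer from CSV.

    Raises ``ValueError`` naming the offending column or row for missing
    required columns, duplicate ids or out-of-bounds coordinates.
    """
    df = pd.read_csv(path, dtype={"id": str, "name": str, "country": str}, **csv_kwargs)
    return Gazetteer.from_frame(df)


def write_gazetteer(gazetteer: Gazetteer, path: str | Path) -> None:
    gazetteer.to_frame().to_csv(path, index=False)


def _coerce_month(series: pd.Series) -> pd.Series:
    months = pd.to_numeric(series, errors="raise").astype(int)
    bad = months[(months < 1) | (months > 12)]
    if len(bad):
        raise ValueError(f"month values outside 1..12 at rows {list(bad.index[:5])}")
    return months


def validate_movement_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check column presence and categorical tokens; return a typed copy."""
    missing = [c for c in MOVEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"movement table missing required column(s): {missing}")
    out = df.copy()
    out["month"] = _coerce_month(out["month"])
    out["head_count"] = pd.to_numeric(out["head_count"], errors="raise").astype(int)
    if (out["head_count"] < 1).any():
        raise ValueError("head_count must be >= 1 for every record")
    for col, allowed in (
        ("species", SPECIES),
        ("transport", TRANSPORT_MODES),
        ("origin_activity", ACTIVITIES),
        ("destination_activity", ACTIVITIES),
    ):
        bad = sorted(set(out[col].astype(str)) - set(allowed))
        if bad:
            raise ValueError(
                f"unknown {col} token(s) {bad}; allowed tokens: {list(allowed)}"
            )
    return out


def derive_scope(
    df: pd.DataFrame, gazetteer: Gazetteer, focal_country: str = DEFAULT_FOCAL_COUNTRY
) -> pd.Series:
    """National iff both endpoint countries equal the focal country."""
    country = {loc.id: loc.country for loc in gazetteer}
    orig = df["origin_id"].map(country)
    dest = df["destination_id"].map(country)
    return pd.Series(
        [
            "national" if (o == focal_country and d == focal_country) else "international"
            for o, d in zip(orig, dest)
        ],
        index=df.index,
        name="scope",
    )


def read_movements(
    path: str | Path,
    gazetteer: Gazetteer,
    focal_country: str = DEFAULT_FOCAL_COUNTRY,
    **csv_kwargs,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and clean a movement table against a gazetteer.

    Exact duplicate rows (all fields equal) are collapsed; records whose
    endpoints do not resolve in the gazetteer are excluded. Both events are
    counted in the returned :class:`ValidationReport`. The ``scope`` column
    is (re)derived from the gazetteer.
    """
    raw = pd.read_csv(
        path, dtype={c: str for c in MOVEMENT_COLUMNS if c not in ("month", "head_count")},
        **csv_kwargs,
    )
    df = validate_movement_frame(raw)
    df = df[list(MOVEMENT_COLUMNS)]
    report = ValidationReport()

    n0 = len(df)
    df = df.drop_duplicates(keep="first")
    report.n_dropped_duplicates = n0 - len(df)
    if report.n_dropped_duplicates:
        report.warnings.append(
            f"dropped {report.n_dropped_duplicates} exact duplicate row(s)"
        )

    known = df["origin_id"].isin(gazetteer.ids) & df["destination_id"].isin(gazetteer.ids)
    report.n_unknown_locations = int((~known).sum())
    if report.n_unknown_locations:
        bad_ids = sorted(
            set(df.loc[~known, "origin_id"]) | set(df.loc[~known, "destination_id"])
            - set(gazetteer.ids)
        )
        report.warnings.append(
            f"excluded {report.n_unknown_locations} record(s) referencing unknown "
            f"location(s): {bad_ids[:10]}"
        )
    df = df[known].reset_index(drop=True)

    df["scope"] = derive_scope(df, gazetteer, focal_country)
    report.n_records = len(df)
    return df, report


def write_movements(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in list(MOVEMENT_COLUMNS) + ["scope"] if c in table.columns]
    table[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Edge-list export / import

EDGE_LIST_FORMATS = ("csv", "graphml")


def _edge_rows(network) -> list[dict]:
    rows = []
    for (o, d), attrs in sorted(network.links.items()):
        rows.append(
            {
                "origin_id": o,
                "destination_id": d,
                "volume": attrs.volume,
                "n_movements": attrs.n_movements,
                "months_active": "|".join(str(m) for m in sorted(attrs.months_active)),
                "species_volume": json.dumps(dict(sorted(attrs.species_volume.items()))),
                "transport_volume": json.dumps(dict(sorted(attrs.transport_volume.items()))),
                "scope": attrs.scope or "",
            }
        )
    return rows


def write_edge_list(network, path: str | Path, fmt: str = "csv") -> None:
    """Export an aggregated O-D network, one element per link.

    ``csv`` writes one row per link (header-only for an empty network);
    ``graphml`` writes a directed graph readable by standard graph tools,
    with the structured attributes JSON-encoded on the edges.
    """
    if fmt not in EDGE_LIST_FORMATS:
        raise ValueError(f"unknown edge-list format {fmt!r}; allowed: {list(EDGE_LIST_FORMATS)}")
    rows = _edge_rows(network)
    if fmt == "csv":
        cols = [
            "origin_id", "destination_id", "volume", "n_movements",
            "months_active", "species_volume", "transport_volume", "scope",
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for row in rows:
        g.add_edge(
            row["origin_id"],
            row["destination_id"],
            **{k: v for k, v in row.items() if k not in ("origin_id", "destination_id")},
        )
    g.graph["window"] = "|".join(str(m) for m in sorted(network.window))
    nx.write_graphml(g, path)


def read_edge_list(path: str | Path, fmt: str = "csv"):
    """Re-import an exported edge list as a :class:`~herdflow.build.MobilityNetwork`."""
    from .build import LinkAttributes, MobilityNetwork  # local import avoids cycle
    import networkx as nx

    if fmt not in EDGE_LIST_FORMATS:
        raise ValueError(f"unknown edge-list format {fmt!r}; allowed: {list(EDGE_LIST_FORMATS)}")

    def parse(o, d, data) -> tuple:
        months = frozenset(int(m) for m in str(data["months_active"]).split("|") if m != "")
        return (str(o), str(d)), LinkAttributes(
            volume=int(data["volume"]),
            n_movements=int(data["n_movements"]),
            months_active=months,
            species_volume={k: int(v) for k, v in json.loads(data["species_volume"]).items()},
            transport_volume={k: int(v) for k, v in json.loads(data["transport_volume"]).items()},
            scope=(str(data["scope"]) or None) if not pd.isna(data["scope"]) else None,
        )

    g = nx.DiGraph()
    window: frozenset[int] = frozenset(range(1, 13))
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"origin_id": str, "destination_id": str})
        for _, row in df.iterrows():
            (o, d), attrs = parse(row["origin_id"], row["destination_id"], row)
            g.add_edge(o, d, attrs=attrs)
    else:
        raw = nx.read_graphml(path)
        if "window" in raw.graph:
            window = frozenset(int(m) for m in str(raw.graph["window"]).split("|") if m != "")
        g.add_nodes_from(str(n) for n in raw.nodes)
        for o, d, data in raw.edges(data=True):
            (o, d), attrs = parse(o, d, data)
            g.add_edge(o, d, attrs=attrs)
    return MobilityNetwork(graph=g, window=window, filters={}, records=None)
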