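"""Synthetic livestock-movement generator with known ground truth.

The generator emulates the statistical structure of a one-year Sahelian
origin-destination movement survey: ~87 locations (most inside the focal
country, the rest across its borders), a heavy-tailed O-D network of a few
hundred aggregated links, and a two-regime year — routine pastoral and
commercial movements from January to August, then a Tabaski-driven regime
from September to December with a higher truck share, a market-destination
surge and a small-ruminant-dominated species mix.

Structure is generated top-down so ground truth exists by construction:

1. each O-D link is drawn once (uniform origins; destination choice mixes
   preferential attachment on current in-degree, exponential distance
   decay and a market boost, producing heavy-tailed in-degrees);
2. each link receives a persistence class (backbone / frequent /
   intermediate / occasional) and a set of active months consistent with
   that class — occasional links concentrate in the Tabaski regime,
   intermediate links in the routine regime, frequent links spread out;
3. every active link-month emits at least one movement record whose
   species, transport mode and destination activity are drawn from its
   regime, with log-normal herd sizes scaled by a monthly volume profile.

All randomness flows from a single seeded generator, so identical
(config, seed) pairs give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .describe import haversine_km
from .records import (
    Gazetteer,
    Location,
    MOVEMENT_COLUMNS,
    SPECIES,
    derive_scope,
)
from .temporal import LINK_CLASSES

_CLASS_MONTH_RANGE = {
    "backbone": (12, 12),
    "frequent": (7, 11),
    "intermediate": (3, 6),
    "occasional": (1, 2),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic movement year.

    Defaults follow the surveyed year where it quantifies them (location
    split 73/14, ~150 aggregated links, regime change at month 9, truck
    probabilities 0.07/0.50 per regime, persistence-class mix with roughly
    a third backbone and 12% occasional links); the remaining knobs
    (herd-size log-normals, 150 km distance-decay scale, monthly volume
    profile peaking April-June with a secondary September-October bump)
    are plausible stand-ins documented as such.
    """

    n_national: int = 73
    n_international: int = 14
    n_links_target: int = 150
    regime_change_month: int = 9
    # probability vectors over (small_ruminants, cattle, dromedaries)
    species_mix_by_regime: tuple = ((0.57, 0.26, 0.17), (0.81, 0.12, 0.07))
    truck_prob_by_regime: tuple = (0.07, 0.50)
    market_dest_prob_by_regime: tuple = (0.13, 0.64)
    herd_size_lognormal: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "small_ruminants": (5.5, 1.0),
            "cattle": (4.5, 0.8),
            "dromedaries": (3.5, 0.8),
        }
    )
    persistence_class_mix: tuple = (0.30, 0.25, 0.33, 0.12)  # backbone/freq/inter/occ
    monthly_volume_multiplier: tuple = (
        0.8, 0.9, 1.0, 1.4, 1.6, 1.4, 1.0, 0.9, 1.3, 1.1, 0.7, 0.6,
    )
    spatial_extent: tuple = (-17.0, -4.8, 14.7, 27.3)  # lon_min, lon_max, lat_min, lat_max
    distance_decay_km: float = 150.0
    market_fraction: float = 0.25
    market_boost: float = 3.0
    records_extra_per_link_month: float = 1.0  # Poisson mean on top of the guaranteed record
    record_noise_sigma: float = 0.25  # residual log-scale noise per record
    class_month_concentration: float = 0.8  # prob. an occasional/intermediate month falls in its regime
    focal_country: str = "MR"
    international_countries: tuple = ("SN", "ML", "MA", "GN", "GW")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_national <= 0 or self.n_links_target <= 0:
            raise ValueError("location and link counts must be positive")
        if self.n_international < 0:
            raise ValueError("n_international must be non-negative")
        if not 2 <= self.regime_change_month <= 12:
            raise ValueError("regime_change_month must lie in 2..12")
        for name, vecs in (
            ("species_mix_by_regime", self.species_mix_by_regime),
            ("persistence_class_mix", (self.persistence_class_mix,)),
        ):
            for v in vecs:
                if abs(sum(v) - 1.0) > 1e-9:
                    raise ValueError(f"{name} must sum to 1 (got {sum(v)})")
                if any(p < 0 for p in v):
                    raise ValueError(f"{name} has negative entries")
        for p in (*self.truck_prob_by_regime, *self.market_dest_prob_by_regime):
            if not 0.0 <= p <= 1.0:
                raise ValueError("regime probabilities must lie in [0, 1]")
        if len(self.monthly_volume_multiplier) != 12:
            raise ValueError("monthly_volume_multiplier needs 12 entries")

    def regime_of(self, month: int) -> int:
        """0 for the routine regime, 1 for the Tabaski regime."""
        return 0 if month < self.regime_change_month else 1

    def regime_months(self, regime: int) -> list[int]:
        if regime == 0:
            return list(range(1, self.regime_change_month))
        return list(range(self.regime_change_month, 13))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "species_mix_by_regime", "truck_prob_by_regime",
            "market_dest_prob_by_regime", "persistence_class_mix",
            "monthly_volume_multiplier", "spatial_extent", "international_countries",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        if "herd_size_lognormal" in raw:
            raw["herd_size_lognormal"] = {
                k: tuple(v) for k, v in raw["herd_size_lognormal"].items()
            }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Construction-time labels for downstream recovery tests."""

    link_class: dict  # (origin, destination) -> class name
    active_months: dict  # (origin, destination) -> sorted tuple of months
    period_partition: list  # [(start, end), ...]
    dominant_nodes: list  # designated hubs (highest planned in-degree)
    realized_shares: dict  # per-regime realized truck / species record shares

    def to_json(self, path: str | Path) -> None:
        payload = {
            "link_class": {f"{o}->{d}": c for (o, d), c in self.link_class.items()},
            "active_months": {
                f"{o}->{d}": list(m) for (o, d), m in self.active_months.items()
            },
            "period_partition": [list(p) for p in self.period_partition],
            "dominant_nodes": self.dominant_nodes,
            "realized_shares": self.realized_shares,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())

        def unkey(s: str) -> tuple:
            o, d = s.split("->")
            return o, d

        return cls(
            link_class={unkey(k): v for k, v in raw["link_class"].items()},
            active_months={unkey(k): tuple(v) for k, v in raw["active_months"].items()},
            period_partition=[tuple(p) for p in raw["period_partition"]],
            dominant_nodes=list(raw["dominant_nodes"]),
            realized_shares=raw["realized_shares"],
        )


def generate_locations(
    config: SimulationConfig, seed: int | None = None
) -> Gazetteer:
    """Draw the location gazetteer.

    National locations fall inside the focal bounding box with a southward
    latitude skew (animal densities are highest in the south);
    international ones sit just beyond the southern and eastern borders,
    except Moroccan points placed beyond the northern edge. A configurable
    fraction of locations double as markets.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lon_min, lon_max, lat_min, lat_max = config.spatial_extent
    locations = []
    n_total = config.n_national + config.n_international
    for i in range(n_total):
        loc_id = f"L{i + 1:03d}"
        national = i < config.n_national
        if national:
            country = config.focal_country
            lon = float(rng.uniform(lon_min, lon_max))
            lat = float(lat_min + (lat_max - lat_min) * rng.beta(1.2, 3.5))
        else:
            country = str(
                config.international_countries[
                    int(rng.integers(len(config.international_countries)))
                ]
            ) if config.international_countries else "XX"
            if country == "MA":  # northern neighbour
                lon = float(rng.uniform(lon_min, lon_max))
                lat = float(rng.uniform(lat_max, min(lat_max + 2.0, 90.0)))
            else:  # southern / eastern border strip
                lon = float(rng.uniform(lon_min, min(lon_max + 2.0, 180.0)))
                lat = float(rng.uniform(max(lat_min - 2.0, -90.0), lat_min))
        activities = {"zone_elevage"}
        if rng.random() < config.market_fraction:
            activities.add("market")
        if rng.random() < 0.05:
            activities.add("slaughterhouse")
        if rng.random() < 0.05:
            activities.add("resting_area")
        locations.append(
            Location(
                id=loc_id,
                name=f"loc_{i + 1:03d}",
                country=country,
                lon=lon,
                lat=lat,
                activities=frozenset(activities),
                coord_source="gps" if rng.random() < 0.9 else "commune_centroid",
            )
        )
    return Gazetteer(locations)


def _draw_links(
    gazetteer: Gazetteer, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple]:
    """Sequential link construction: uniform origins, destinations by
    preferential attachment x distance decay x market boost."""
    ids = gazetteer.ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 locations to draw links")
    max_links = n * (n - 1)
    if config.n_links_target > max_links:
        raise ValueError(
            f"n_links_target={config.n_links_target} exceeds the {max_links} possible O-D pairs"
        )
    coords = [(gazetteer[i].lon, gazetteer[i].lat) for i in ids]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = haversine_km(coords[i], coords[j])
    decay = np.exp(-dist / config.distance_decay_km)
    market = np.array(
        [config.market_boost if "market" in gazetteer[i].activities else 1.0 for i in ids]
    )

    in_links = np.zeros(n)
    links: list[tuple] = []
    seen: set = set()
    attempts = 0
    while len(links) < config.n_links_target:
        attempts += 1
        if attempts > 200 * config.n_links_target:
            raise RuntimeError("link sampling failed to reach the target pair count")
        o = int(rng.integers(n))
        w = (in_links + 0.5) * decay[o] * market
        w[o] = 0.0
        total = w.sum()
        if total <= 0:
            continue
        d = int(rng.choice(n, p=w / total))
        if (o, d) in seen:
            continue
        seen.add((o, d))
        in_links[d] += 1.0
        links.append((ids[o], ids[d]))
    return links


def _draw_active_months(
    cls: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple:
    """Active months consistent with a persistence class.

    Occasional links concentrate in the Tabaski regime and intermediate
    links in the routine regime (each month lands in the preferred regime
    with probability ``class_month_concentration``); frequent links draw
    uniformly across the year; backbone links take all twelve months.
    """
    lo, hi = _CLASS_MONTH_RANGE[cls]
    k = int(rng.integers(lo, hi + 1))
    if cls == "backbone":
        return tuple(range(1, 13))
    preferred: list[int] | None = None
    if cls == "occasional":
        preferred = config.regime_months(1)
    elif cls == "intermediate":
        preferred = config.regime_months(0)
    months: set[int] = set()
    while len(months) < k:
        if preferred is not None and rng.random() < config.class_month_concentration:
            pool = [m for m in preferred if m not in months]
        else:
            pool = [m for m in range(1, 13) if m not in months]
        if not pool:
            pool = [m for m in range(1, 13) if m not in months]
        months.add(int(pool[int(rng.integers(len(pool)))]))
    return tuple(sorted(months))


def generate_movements(
    gazetteer: Gazetteer,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic movement year plus its ground truth.

    Every planned active link-month emits at least one record, so the
    realized active-month set of each link equals the planned one and the
    persistence classes are recoverable exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    links = _draw_links(gazetteer, config, rng)

    classes = [
        LINK_CLASSES[int(c)]
        for c in rng.choice(
            len(LINK_CLASSES), size=len(links), p=list(config.persistence_class_mix)
        )
    ]
    active = {
        link: _draw_active_months(cls, config, rng)
        for link, cls in zip(links, classes)
    }

    rows = []
    for link, cls in zip(links, classes):
        o, d = link
        dest_acts = gazetteer[d].activities
        orig_acts = gazetteer[o].activities
        origin_activity = "zone_elevage" if "zone_elevage" in orig_acts else sorted(orig_acts)[0]
        # Persistent link capacity: one latent size quantile per (link, regime),
        # so a link carries similar volumes in adjacent months of the same
        # regime but is re-scaled when the mobility regime changes.
        capacity_z = {r: float(rng.standard_normal()) for r in (0, 1)}
        for month in active[link]:
            regime = config.regime_of(month)
            n_rec = 1 + int(rng.poisson(config.records_extra_per_link_month))
            for _ in range(n_rec):
                species = SPECIES[
                    int(rng.choice(len(SPECIES), p=list(config.species_mix_by_regime[regime])))
                ]
                transport = (
                    "truck" if rng.random() < config.truck_prob_by_regime[regime] else "foot"
                )
                mu, sigma = config.herd_size_lognormal[species]
                head = max(
                    1,
                    int(round(
                        np.exp(
                            mu
                            + sigma * capacity_z[regime]
                            + rng.normal(0.0, config.record_noise_sigma)
                        )
                        * config.monthly_volume_multiplier[month - 1]
                        / n_rec
                    )),
                )
                if (
                    "market" in dest_acts
                    and rng.random() < config.market_dest_prob_by_regime[regime]
                ):
                    destination_activity = "market"
                elif "zone_elevage" in dest_acts:
                    destination_activity = "zone_elevage"
                else:
                    destination_activity = sorted(dest_acts)[0]
                rows.append(
                    (o, d, month, species, head, transport, origin_activity, destination_activity)
                )

    table = pd.DataFrame(rows, columns=list(MOVEMENT_COLUMNS))
    table = table.sort_values(
        ["month", "origin_id", "destination_id", "species", "transport", "head_count"],
        kind="mergesort",
    ).reset_index(drop=True)
    table["scope"] = derive_scope(table, gazetteer, config.focal_country)

    realized = {}
    for regime in (0, 1):
        sub = table[table["month"].isin(config.regime_months(regime))]
        share = {
            "n_records": int(len(sub)),
            "truck_share": float((sub["transport"] == "truck").mean()) if len(sub) else float("nan"),
        }
        for sp in SPECIES:
            share[f"{sp}_share"] = (
                float((sub["species"] == sp).mean()) if len(sub) else float("nan")
            )
        realized[f"regime_{regime}"] = share

    in_counts: dict[str, int] = {}
    for _, d in links:
        in_counts[d] = in_counts.get(d, 0) + 1
    dominant = [
        n for n, _ in sorted(in_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    ]

    truth = GroundTruth(
        link_class=dict(zip(links, classes)),
        active_months=active,
        period_partition=[
            (1, config.regime_change_month - 1),
            (config.regime_change_month, 12),
        ],
        dominant_nodes=dominant,
        realized_shares=realized,
    )
    return table, truth


def generate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[Gazetteer, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: gazetteer + movement table + ground truth.

    The gazetteer and the movements are drawn from two decorrelated
    sub-seeds of the root seed, so either half can be regenerated alone.
    """
    config = config or SimulationConfig()
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root).spawn(2)
    gaz_seed = int(ss[0].generate_state(1)[0] % (2**31 - 1))
    mov_seed = int(ss[1].generate_state(1)[0] % (2**31 - 1))
    gazetteer = generate_locations(config, seed=gaz_seed)
    table, truth = generate_movements(gazetteer, config, seed=mov_seed)
    return gazetteer, table, truth
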