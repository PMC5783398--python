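"""Jaccard indices, period detection and link persistence classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdflow import (
    activity_raster,
    build_network,
    class_subnetwork,
    classify_links,
    detect_periods,
    jaccard_series,
    jaccard_sets,
    jaccard_weighted,
    monthly_snapshots,
    persistence_class,
)
from herdflow.simulate import SimulationConfig, generate_dataset
from herdflow.temporal import LINK_CLASSES

from conftest import movement_row, net_from_volumes


class TestJaccardSets:
    def test_identity_and_disjoint(self):
        assert jaccard_sets({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_sets({"a"}, {"b"}) == 0.0

    def test_hand_enumeration(self):
        assert jaccard_sets({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_convention(self):
        assert jaccard_sets(set(), set()) == 1.0


class TestJaccardWeighted:
    def test_identity(self):
        w = {"e1": 3.0, "e2": 7.0}
        assert jaccard_weighted(w, w) == 1.0

    def test_hand_computation(self):
        a = {"e1": 2.0, "e2": 4.0}
        b = {"e1": 6.0, "e3": 1.0}
        assert jaccard_weighted(a, b) == pytest.approx(2 / 11)

    def test_one_empty_side(self):
        assert jaccard_weighted({}, {"e": 1.0}) == 0.0
        assert jaccard_weighted({}, {}) == 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            jaccard_weighted({"e": 0.0}, {"e": 1.0})

    weight_maps = st.dictionaries(
        st.sampled_from(["e1", "e2", "e3", "e4", "e5"]),
        st.floats(0.1, 100.0, allow_nan=False),
        max_size=5,
    )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=weight_maps, b=weight_maps)
    def test_symmetry_and_bounds(self, a, b):
        jab = jaccard_weighted(a, b)
        assert jab == pytest.approx(jaccard_weighted(b, a))
        assert 0.0 <= jab <= 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.sets(st.sampled_from("abcdefgh"), max_size=8),
        b=st.sets(st.sampled_from("abcdefgh"), max_size=8),
    )
    def test_reduces_to_plain_jaccard_on_equal_weights(self, a, b):
        wa = {k: 5.0 for k in a}
        wb = {k: 5.0 for k in b}
        assert jaccard_weighted(wa, wb) == pytest.approx(jaccard_sets(a, b))


class TestJaccardSeries:
    def _snapshots_from_tables(self, monthly_rows):
        rows = []
        for month, links in enumerate(monthly_rows, start=1):
            rows.extend(
                movement_row(origin=o, destination=d, month=month, head_count=h)
                for (o, d), h in links.items()
            )
        return monthly_snapshots(pd.DataFrame(rows))

    def test_identical_snapshots_all_one(self):
        snaps = self._snapshots_from_tables([{("a", "b"): 5}] * 12)
        series = jaccard_series(snaps)
        assert set(series.j_nodes) == {1.0}
        assert set(series.j_links) == {1.0}
        assert set(series.j_weights) == {1.0}
        assert len(series.pairs) == 11

    def test_alternating_disjoint_link_sets(self):
        monthly = [
            {("a", "b"): 5} if m % 2 else {("c", "d"): 5} for m in range(1, 13)
        ]
        series = jaccard_series(self._snapshots_from_tables(monthly))
        assert set(series.j_links) == {0.0}

    def test_matches_per_pair_base_operations(self):
        rng = np.random.default_rng(11)
        monthly = []
        pool = [("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")]
        for _ in range(12):
            monthly.append(
                {
                    link: int(rng.integers(1, 50))
                    for link in pool
                    if rng.random() < 0.6
                }
                or {pool[0]: 1}
            )
        snaps = self._snapshots_from_tables(monthly)
        series = jaccard_series(snaps)
        for idx, (a, b) in enumerate(zip(snaps, snaps[1:])):
            assert series.j_nodes[idx] == pytest.approx(jaccard_sets(a.nodes, b.nodes))
            assert series.j_links[idx] == pytest.approx(
                jaccard_sets(set(a.links), set(b.links))
            )
            assert series.j_weights[idx] == pytest.approx(
                jaccard_weighted(a.weight_map(), b.weight_map())
            )

    def test_too_few_snapshots_rejected(self):
        with pytest.raises(ValueError, match="2 snapshots"):
            jaccard_series([net_from_volumes({})])


class TestDetectPeriods:
    def test_identical_snapshots_single_period(self):
        rows = [movement_row(month=m, head_count=5) for m in range(1, 13)]
        snaps = monthly_snapshots(pd.DataFrame(rows))
        partition = detect_periods(snaps)
        assert partition.periods == ((1, 12),)

    def test_forced_n_periods_12(self):
        rows = [movement_row(month=m, head_count=m * 7) for m in range(1, 13)]
        snaps = monthly_snapshots(pd.DataFrame(rows))
        partition = detect_periods(snaps, n_periods=12)
        assert partition.periods == tuple((m, m) for m in range(1, 13))

    def test_n_periods_above_snapshot_count_rejected(self):
        rows = [movement_row(month=m) for m in range(1, 13)]
        snaps = monthly_snapshots(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="n_periods"):
            detect_periods(snaps, n_periods=13)

    def test_two_regime_boundary_recovered_on_one_seed(self):
        _, table, truth = generate_dataset(SimulationConfig(), seed=5)
        partition = detect_periods(monthly_snapshots(table))
        assert partition.periods == tuple(truth.period_partition)

    def test_shuffling_months_destroys_recovery(self):
        _, table, _ = generate_dataset(SimulationConfig(), seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(np.arange(1, 13))
        shuffled = table.assign(month=table["month"].map({m: int(p) for m, p in zip(range(1, 13), perm)}))
        partition = detect_periods(monthly_snapshots(shuffled))
        assert partition.periods != ((1, 8), (9, 12))


class TestLinkClasses:
    @pytest.mark.parametrize(
        "months, expected",
        [
            (range(1, 13), "backbone"),
            ({2, 5, 9, 11, 12}, "intermediate"),
            ({10}, "occasional"),
            ({1, 2}, "occasional"),
            ({1, 2, 3}, "intermediate"),
            (range(1, 8), "frequent"),
            (range(1, 12), "frequent"),
        ],
    )
    def test_class_boundaries(self, months, expected):
        assert persistence_class(len(set(months))) == expected
        rows = [movement_row(month=m) for m in months]
        annual = build_network(pd.DataFrame(rows))
        assert classify_links(annual).classes[("a", "b")] == expected

    def test_subnetworks_partition_annual_network(self, default_dataset):
        _, table, _ = default_dataset
        annual = build_network(table)
        cmap = classify_links(annual)
        union = {}
        total = 0
        for cls in LINK_CLASSES:
            sub = class_subnetwork(annual, cmap, cls)
            assert set(sub.links) == cmap.links_of(cls)
            for key, attrs in sub.links.items():
                assert key not in union
                union[key] = attrs
            total += sub.total_volume
        assert union == annual.links
        assert total == annual.total_volume

    def test_backbone_of_constant_data_is_whole_network(self):
        rows = [
            movement_row(month=m, head_count=4) for m in range(1, 13)
        ] + [
            movement_row(origin="b", destination="c", month=m) for m in range(1, 13)
        ]
        annual = build_network(pd.DataFrame(rows))
        cmap = classify_links(annual)
        sub = class_subnetwork(annual, cmap, "backbone")
        assert sub.links == annual.links


class TestActivityRaster:
    def test_row_sums_and_backbone_rows(self, default_dataset):
        _, table, truth = default_dataset
        annual = build_network(table)
        raster = activity_raster(annual)
        month_cols = [f"m{m}" for m in range(1, 13)]
        assert (raster[month_cols].sum(axis=1) == raster["n_months"]).all()
        backbone = raster[raster["link_class"] == "backbone"]
        assert backbone[month_cols].all(axis=None)

    def test_matches_recomputation_from_raw_records(self, default_dataset):
        _, table, _ = default_dataset
        annual = build_network(table)
        raster = activity_raster(annual).set_index(["origin_id", "destination_id"])
        for (o, d), group in table.groupby(["origin_id", "destination_id"]):
            months = set(group["month"])
            row = raster.loc[(o, d)]
            for m in range(1, 13):
                assert bool(row[f"m{m}"]) == (m in months)
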