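"""Descriptive topology: degrees, power laws, components, geometry, tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdflow import (
    Gazetteer,
    Location,
    clustering_and_diameter,
    component_summary,
    degree_distribution,
    distance_profile,
    fit_power_law,
    haversine_km,
    round_half_up,
    summarize_flows,
)
from herdflow.describe import EARTH_RADIUS_KM

from conftest import movement_row, net_from_volumes


class TestDegreeDistribution:
    def test_directed_triangle_symmetry(self):
        net = net_from_volumes({("a", "b"): 1, ("b", "c"): 1, ("c", "a"): 1})
        for direction in ("in", "out"):
            summary = degree_distribution(net, direction)
            assert summary.hist == {1: 3}

    def test_star_concentrates_in_degree(self):
        net = net_from_volumes({(f"s{i}", "hub"): 1 for i in range(5)})
        summary = degree_distribution(net, "in")
        assert summary.max == 5
        assert summary.hist[0] == 5  # the spokes

    def test_handshake_identity_on_random_graph(self):
        rng = np.random.default_rng(3)
        vols = {
            (f"n{i}", f"n{j}"): 1
            for i in range(8)
            for j in range(8)
            if i != j and rng.random() < 0.4
        }
        net = net_from_volumes(vols)
        s_in = sum(k * c for k, c in degree_distribution(net, "in").hist.items())
        s_out = sum(k * c for k, c in degree_distribution(net, "out").hist.items())
        assert s_in == s_out == len(vols)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            degree_distribution(net_from_volumes({}))


class TestPowerLawFit:
    def test_recovers_known_discrete_exponent(self):
        x = stats.zipf.rvs(1.7, size=10_000, random_state=np.random.default_rng(0))
        fit = fit_power_law(x, discrete=True)
        assert abs(fit.alpha - 1.7) <= 0.1
        assert not fit.poor_fit()

    def test_continuous_fit_is_scale_invariant(self):
        rng = np.random.default_rng(1)
        x = (1.0 - rng.random(5000)) ** (-1.0 / 0.7)  # inverse-CDF, alpha=1.7
        f1 = fit_power_law(x, discrete=False)
        f2 = fit_power_law(10.0 * x, discrete=False)
        assert math.isclose(f1.alpha, f2.alpha, rel_tol=1e-9)

    def test_uniform_values_flag_poor_fit(self):
        zipf_ks = fit_power_law(
            stats.zipf.rvs(1.7, size=5000, random_state=np.random.default_rng(2)),
            discrete=True,
        ).ks
        uniform_fit = fit_power_law(np.arange(1, 101), discrete=True)
        assert uniform_fit.poor_fit()
        assert uniform_fit.ks > 3 * zipf_ks

    def test_least_squares_agrees_roughly_with_mle(self):
        rng = np.random.default_rng(4)
        x = (1.0 - rng.random(5000)) ** (-1.0 / 0.7)
        mle = fit_power_law(x, discrete=False, method="mle")
        ls = fit_power_law(x, discrete=False, method="least_squares")
        assert abs(mle.alpha - ls.alpha) < 0.2

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_power_law([3, 3, 3, 3])


class TestComponents:
    def test_chain_weak3_strong1_connected(self):
        summary = component_summary(net_from_volumes({("a", "b"): 1, ("b", "c"): 1}))
        assert summary.largest_weak == 3
        assert summary.largest_strong == 1
        assert summary.is_connected

    def test_two_disjoint_dyads_disconnected(self):
        summary = component_summary(
            net_from_volumes({("a", "b"): 1, ("c", "d"): 1})
        )
        assert not summary.is_connected
        assert summary.largest_weak == 2
        assert summary.n_components == 2

    def test_directed_cycle_is_strongly_connected(self):
        cyc = {(f"n{i}", f"n{(i + 1) % 6}"): 1 for i in range(6)}
        assert component_summary(net_from_volumes(cyc)).largest_strong == 6


class TestClusteringDiameter:
    def test_triangle_fully_clustered(self):
        net = net_from_volumes({("a", "b"): 1, ("b", "c"): 1, ("c", "a"): 1})
        clustering, _ = clustering_and_diameter(net)
        assert clustering == 1.0

    def test_path_diameter_by_construction(self):
        path = {(f"n{i}", f"n{i + 1}"): 1 for i in range(7)}
        _, diameter = clustering_and_diameter(net_from_volumes(path))
        assert diameter == 7


class TestHaversine:
    def test_zero_iff_identical(self):
        assert haversine_km((0.0, 0.0), (0.0, 0.0)) == 0.0
        assert haversine_km((10.0, 5.0), (10.0, 5.0)) == 0.0

    def test_one_degree_meridian_arc(self):
        expected = 2 * math.pi * EARTH_RADIUS_KM / 360
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(expected, rel=1e-9)

    def test_antipodal_half_circumference(self):
        assert haversine_km((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9
        )

    def test_symmetry(self):
        a, b = (-10.0, 17.0), (-12.5, 14.2)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            haversine_km((0.0, 95.0), (0.0, 0.0))


class TestDistanceProfile:
    def _gazetteer(self):
        return Gazetteer(
            [
                Location("a", "A", "MR", 0.0, 0.0, frozenset({"zone_elevage"})),
                # ~150 km north of a
                Location("b", "B", "MR", 0.0, 1.35, frozenset({"market"})),
            ]
        )

    def test_single_pair_occupies_one_bin(self):
        table = pd.DataFrame([movement_row() for _ in range(4)])
        profile = distance_profile(table, self._gazetteer(), bin_km=100.0)
        assert len(profile) == 1
        assert profile.iloc[0]["bin_lo"] == 100.0
        assert profile.iloc[0]["n_movements"] == 4

    def test_bin_sums_conserve_totals(self):
        rng = np.random.default_rng(5)
        gaz = Gazetteer(
            [
                Location(f"p{i}", f"P{i}", "MR", float(rng.uniform(-15, -5)),
                         float(rng.uniform(15, 25)), frozenset({"zone_elevage", "market"}))
                for i in range(6)
            ]
        )
        rows = [
            movement_row(
                origin=f"p{rng.integers(6)}",
                destination=f"p{rng.integers(6)}",
                head_count=int(rng.integers(1, 50)),
                destination_activity=str(rng.choice(["market", "zone_elevage"])),
            )
            for _ in range(50)
        ]
        table = pd.DataFrame(rows)
        profile = distance_profile(table, gaz)
        assert profile["n_movements"].sum() == len(table)
        assert profile["volume"].sum() == table["head_count"].sum()

    def test_missing_coordinates_listed(self):
        table = pd.DataFrame([movement_row(destination="nowhere")])
        with pytest.raises(ValueError, match="nowhere"):
            distance_profile(table, self._gazetteer())


class TestSummarizeFlows:
    def test_single_record_gets_full_share(self):
        table = pd.DataFrame([movement_row()])
        out = summarize_flows(table, "species")
        assert out.iloc[0]["pct_movements"] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            [
                movement_row(
                    species=str(rng.choice(["cattle", "dromedaries"])),
                    transport=str(rng.choice(["foot", "truck"])),
                    head_count=int(rng.integers(1, 30)),
                )
                for _ in range(40)
            ]
        )
        out = summarize_flows(table, ["species", "transport"])
        assert out["pct_movements"].sum() == pytest.approx(100.0)
        assert out["pct_volume"].sum() == pytest.approx(100.0)
        assert out["n_movements"].sum() == 40

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_flows(pd.DataFrame(columns=["species", "head_count"]), "species")

    def test_round_half_up(self):
        assert round_half_up(92.5) == 93.0
        assert round_half_up(5.115, 2) == 5.12
        assert round_half_up(2.5) == 3.0
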