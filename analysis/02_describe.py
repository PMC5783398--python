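"""Descriptive topology of the annual mobility network.

Builds the year-aggregated network from the simulated records, fits the
degree and link-volume power laws, summarises connectivity, and writes the
activity-pair flow table and the distance profile. Run 01_simulate.py first.
"""

import json
from pathlib import Path

from herdflow import (
    build_network,
    degree_weight_summary,
    distance_profile,
    read_gazetteer,
    read_movements,
    summarize_flows,
    write_edge_list,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gazetteer = read_gazetteer(OUT / "gazetteer.csv")
    table, report = read_movements(OUT / "movements.csv", gazetteer)
    print(f"records: {report.n_records} (duplicates dropped: {report.n_dropped_duplicates})")

    annual = build_network(table)
    write_edge_list(annual, OUT / "annual_network.graphml", fmt="graphml")
    write_edge_list(annual, OUT / "annual_network_edges.csv", fmt="csv")

    summary = degree_weight_summary(annual)
    (OUT / "network_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"annual network: {summary['n_nodes']} nodes, {summary['n_links']} links, "
        f"volume {summary['total_volume']}"
    )
    print(
        f"degree exponent gamma ~ {summary['gamma_hat']:.2f}, "
        f"volume exponent eta ~ {summary['eta_hat']:.2f}"
    )
    print(
        f"clustering {100 * summary['clustering']:.1f}%, diameter {summary['diameter']}, "
        f"weak/strong component {summary['largest_weak']}/{summary['largest_strong']}"
    )

    flows = summarize_flows(table, ["origin_activity", "destination_activity"])
    flows.to_csv(OUT / "flows_by_activity.csv", index=False)
    zone = flows[flows["origin_activity"] == "zone_elevage"]
    print(
        "zone-d'elevage origins carry "
        f"{zone['pct_movements'].sum():.0f}% of movements"
    )

    profile = distance_profile(table, gazetteer, bin_km=100.0)
    profile.to_csv(OUT / "distance_profile.csv", index=False)
    modal = profile.groupby("bin_lo")["n_movements"].sum().idxmax()
    print(f"modal movement distance bin: [{modal:.0f}, {modal + 100:.0f}) km")


if __name__ == "__main__":
    main()
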