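"""QAP correlation among the four persistence-class networks.

Splits the annual network into backbone / frequent / intermediate /
occasional subnetworks and tests every pair for product-moment correlation
under 1000 node-label permutations. Largely uncorrelated class networks
indicate that the classes connect different location sets at different
times of the year. Run 01_simulate.py first.
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from herdflow import (
    build_network,
    class_subnetwork,
    classify_links,
    qap_test,
    read_gazetteer,
    read_movements,
)
from herdflow.temporal import LINK_CLASSES

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    gazetteer = read_gazetteer(OUT / "gazetteer.csv")
    table, _ = read_movements(OUT / "movements.csv", gazetteer)
    annual = build_network(table)
    cmap = classify_links(annual)
    nets = {cls: class_subnetwork(annual, cmap, cls) for cls in LINK_CLASSES}

    rows = []
    for cls_a, cls_b in combinations(LINK_CLASSES, 2):
        result = qap_test(nets[cls_a], nets[cls_b], n_perm=1000, seed=SEED)
        rows.append(
            {
                "network_a": cls_a,
                "network_b": cls_b,
                "r_obs": result.r_obs,
                "p_value": result.p_value,
                "perm_mean": result.perm_mean,
                "perm_sd": result.perm_sd,
            }
        )
        flag = "significant" if result.significant() else "not significant"
        print(f"{cls_a} vs {cls_b}: r = {result.r_obs:+.3f}, p = {result.p_value:.3f} ({flag})")

    pd.DataFrame(rows).to_csv(OUT / "qap_class_networks.csv", index=False)


if __name__ == "__main__":
    main()
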