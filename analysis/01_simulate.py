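"""Generate the default synthetic movement year.

Writes the location gazetteer, the cleaned movement table and the
generator's ground-truth labels under results/, and reports the headline
sizes: with the default configuration the year comprises ~87 locations,
~150 aggregated O-D links and ~2,300 movement records split into a routine
(Jan-Aug) and a Tabaski (Sep-Dec) regime.
"""

from pathlib import Path

from herdflow import SimulationConfig, generate_dataset, write_gazetteer, write_movements

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = SimulationConfig()
    gazetteer, table, truth = generate_dataset(config, seed=SEED)

    write_gazetteer(gazetteer, OUT / "gazetteer.csv")
    write_movements(table, OUT / "movements.csv")
    truth.to_json(OUT / "ground_truth.json")

    n_focal = sum(1 for loc in gazetteer if loc.country == config.focal_country)
    print(f"locations: {len(gazetteer)} ({n_focal} in {config.focal_country})")
    print(f"movement records: {len(table)}")
    print(f"aggregated O-D links: {len(truth.link_class)}")
    for regime, label in ((0, "routine Jan-Aug"), (1, "Tabaski Sep-Dec")):
        share = truth.realized_shares[f"regime_{regime}"]
        print(
            f"{label}: {share['n_records']} records, "
            f"truck share {100 * share['truck_share']:.1f}%, "
            f"small-ruminant share {100 * share['small_ruminants_share']:.1f}%"
        )


if __name__ == "__main__":
    main()
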