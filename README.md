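# herdflow

Network analysis of livestock mobility from origin–destination movement
records, aimed at veterinary epidemiologists and animal-health analysts
working with survey or certificate data in settings where seasonal herd
movements (transhumance, market trade, Tabaski provisioning) shape the
risk of transboundary disease spread.

Movement records — origin, destination, month, species, head count,
transport mode, endpoint activity types — are aggregated into a directed
weighted network G = (V, E, w), with one link per O-D pair and twelve
monthly snapshots. On top of that, the package provides:

- **Descriptive topology**: degree and link-volume distributions with
  maximum-likelihood power-law fits P(k) ∝ k^(−γ), P(w) ∝ w^(−η);
  weak/strong components; clustering and diameter on the undirected
  projection; great-circle distance profiles; grouped flow tables with
  percentage shares.
- **Dominant flows / nodal regions**: after pruning outgoing links
  carrying ≤ 20% of their origin's out-volume, a link i→j is dominant iff
  j receives i's largest outflow and in(j) > in(i); dominant links form a
  forest of influence areas around hub (dominant) nodes.
- **Temporal dynamics**: month-to-month Jaccard indices
  J = |A∩B|/|A∪B| and weighted J′ = Σmin(w_A, w_B)/Σmax(w_A, w_B);
  contiguity-constrained clustering of snapshots into mobility periods;
  link persistence classes — backbone (12 active months), frequent
  (7–11), intermediate (3–6), occasional (1–2).
- **QAP correlation**: Pearson correlation between two networks'
  off-diagonal weight matrices, with significance from joint row/column
  node-label permutations, p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1).
- **Synthetic generator**: a ground-truthed two-regime movement year
  (routine January–August, Tabaski September–December) with heavy-tailed
  hub structure, so the whole pipeline is testable without any external
  data.

## Worked example

```python
from herdflow import (
    SimulationConfig, generate_dataset, build_network, monthly_snapshots,
    detect_periods, classify_links, nodal_regions, degree_weight_summary,
)

gazetteer, table, truth = generate_dataset(SimulationConfig(), seed=1)
annual = build_network(table)

print(degree_weight_summary(annual))
print(detect_periods(monthly_snapshots(table)).periods)
print(nodal_regions(annual).coverage)
```

With seed 1 this generates 87 locations (73 national) and 2,346 records
on 150 aggregated links, and prints (abridged):

```
{'n_nodes': 83, 'n_links': 150, 'degree_max': 23, 'largest_weak': 83,
 'clustering': 0.12, 'diameter': 6, 'gamma_hat': 1.72, 'eta_hat': 1.24, ...}
((1, 8), (9, 12))
Coverage(n_nodes=83, n_links=72, volume_fraction=0.719...)
```

The degree distribution is heavy-tailed (γ̂ ≈ 1.7: a few hub markets
receive most links), the detected mobility periods recover the generator's
January–August / September–December regime split exactly, and the
dominant-flow forest retains 72 links carrying ~72% of the annual animal
volume around a handful of hub locations.

The same steps are available as a CLI (`herdflow simulate / validate /
build / describe / table1 / dominant / temporal / qap`) and as narrative
drivers under `analysis/` (run in numbered order; outputs land in
`results/`).

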