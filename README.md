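# chimpfs

Binary wrapper feature selection for high-dimensional biomedical
(microarray-like) classification data, driven by two chimp-style swarm
optimizers:

* **CHoA** (`chimpfs.choa`) — the baseline optimizer: four leader roles
  (attacker, barrier, chaser, driver) guide every candidate; each
  generation an individual moves to the mean of the four leader-guided
  targets or is relocated chaotically within bounds.
* **SOSCHoA** (`chimpfs.soschoa`) — the baseline move sharpened by a
  social-coevolution term (pull toward the attacker relative to the
  midpoint of an individual and its ring predecessor, benefit factor
  R ∈ {1, 2}) plus a dimension-wise sine-chaotic opposition sweep inside
  dynamic population bounds with greedy replacement.

The wrapper layer (`chimpfs.feature_selection`) thresholds continuous
positions at 0.5 into feature masks and scores them with
`alpha * knn_error + (1 - alpha) * selected_fraction` (alpha = 0.99,
KNN with k = 5 on a stratified 70/30 split). `chimpfs.synthetic`
generates seeded microarray-like datasets with planted informative,
redundant, and noise features; `chimpfs.metrics` provides repeated-run
summaries, population diversity, and Wilcoxon rank-sum comparisons;
`chimpfs.io` reads/writes CSV (label column last) and X/Y `.mat`
datasets.

## CLI

```sh
# emit a seeded synthetic dataset (plus a .meta.json sidecar)
chimpfs simulate --out data.csv --seed 1

# one feature-selection experiment (soschoa by default)
chimpfs run --data data.csv --seed 1 --outdir results

# repeated-run choa-vs-soschoa comparison with a rank-sum table
chimpfs benchmark --data data.csv --runs 30 --seed 1 --outdir results

# summarize a saved benchmark (optionally --plots)
chimpfs report --infile results/benchmark_seed1.json
```

Defaults follow the reference protocol: population 10, 100 iterations,
30 runs, alpha 0.99, k 5, 70/30 split. Any option can come from a YAML
file via `--config`; explicit flags override it. Every artifact embeds
its resolved configuration and seed.

## Library

```python
import numpy as np
from chimpfs import soschoa
from chimpfs.choa import SearchSpace
from chimpfs.feature_selection import FitnessConfig, run_feature_selection, split_dataset
from chimpfs.synthetic import SyntheticSpec, generate_dataset

dataset, truth = generate_dataset(SyntheticSpec(seed=0))
split = split_dataset(dataset, 0.7, np.random.default_rng(0))
result = run_feature_selection(split, optimizer="soschoa", seed=0)
print(result.mask_string, result.accuracy, result.selected_indices)
```

Both optimizers share one contract: `optimize(objective, space, ...)`
minimizes an objective over a bounded box and returns the elitist best
position/fitness, the per-generation best-fitness and diversity curves,
and instrumented per-generation evaluation/coordinate counters.

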