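# netweave

Seasonal dynamics of plant-pollinator networks via motif-role network
alignment.

Plant-pollinator communities reassemble every season: species enter, swap
interaction partners week by week, and leave. Static network snapshots
hide this, and single-species analyses drown in idiosyncrasy. `netweave`
works at an intermediate scale — the *position* a species occupies in its
weekly interaction network — and provides the full analysis chain for
seasonal time series of weekly weighted bipartite networks:

1. **Motif roles.** Each species' structural role in a weekly network is
   the vector counting its appearances in every position (node orbit) of
   the 3-5-species bipartite motifs — 44 positions in all — optionally
   weighted by interaction strength.
2. **Network alignment.** Two networks are aligned by a guild-respecting
   one-to-one species pairing λ minimizing
   `C_λ = Σ_pairs (1 − c_ij) + penalty · #unpaired`, where `c_ij` is the
   Pearson correlation of the paired species' role vectors. Optimization
   is simulated annealing, repeated from many restarts because optimal
   pairings are frequently degenerate.
3. **Position statistics.** Repeated self-alignments give each species a
   *uniqueness* score (share of runs pairing it to itself); alignments
   between different weeks give a *variability* score (share of runs in
   which its position changed); fixing an i-i pairing and re-aligning
   measures the cost of forcing a species to keep its position.
4. **Position groups.** All pairings are compiled into an alignment
   matrix `M` over (network, species) occurrences — pairing frequency ×
   pairing quality — and walktrap community detection partitions each
   guild's block into groups of recurring positions (e.g. specialists
   attached to generalists vs. generalists attached to generalists).
5. **Structural dynamics.** Weekly group memberships become state
   trajectories over the groups plus `pre` (not yet entered) and `post`
   (exited, absorbing). A Bayesian multinomial logistic model with
   softmax-linked scores linear in relative time `t = week / W`,
   `s_k(y_i, t) = α_k + β_k t` per free (origin, destination) cell and
   N(0, 10) priors, yields posterior transition-probability curves;
   time-dependent, constant, and season-replicate forms are compared by
   WAIC.

A synthetic-data generator with known ground truth (planted groups,
transition law, phenologies, abundance-coupled degrees) makes every stage
testable without field data.

## Worked example

```python
from netweave import (SyntheticConfig, generate_series, PipelineConfig,
                      run_study)
from netweave.position_stats import threshold_fraction

series, truth = generate_series(
    SyntheticConfig(weeks=(8, 9), n_plants=12, n_pollinators=20, seed=11))
res = run_study(series,
                PipelineConfig(seed=3, n_alignments=25, anneal_sweeps=200),
                fit_guilds=("pollinator",))

print("uniqueness > 0.9:", threshold_fraction(res.uniqueness))
print("variability > 0.9:", threshold_fraction(res.variability))
print("pollinator groups:", len(res.grouping.groups("pollinator")))
print("WAIC:", {k: round(v, 1) for k, v in res.waic["pollinator"].items()})
```

Output from this exact snippet:

```
uniqueness > 0.9: {'plant': 1.0, 'pollinator': 0.8653846153846154}
variability > 0.9: {'plant': 0.47058823529411764, 'pollinator': 0.391304347826087}
pollinator groups: 8
WAIC: {'time_dependent': 508.0, 'constant': 511.7}
```

Reading it: almost every species occupies a structurally unique position
within a week (uniqueness ≈ 1 for all plants, 87% of pollinator
occurrences), yet a large share of species change position from week to
week; the alignment matrix resolves recurring position groups (more than
the three planted latent groups at this small scale — weekly realization
noise makes occurrence-level positions finer than latent memberships, see
`docs/methods.md`); and the two model forms here have near-identical
WAIC, i.e. this small synthetic community shows no strong evidence for a
time trend in its group-to-group transition rates.

The same pipeline runs from the shell:

```bash
netweave synth --config synth.yaml --out data/
netweave run --records data/records.csv --out results/ --n 100 --seed 1
```

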