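# cofluct

Edge co-fluctuation analysis of parcellated neural time series: decompose
signals into edge (co-fluctuation) time series, detect high-amplitude
network events against circular-shift surrogates, cluster event patterns
hierarchically with Lin's concordance and consensus modularity maximization,
and test whether the bipartition implied by an event cluster corresponds to
a modular subgraph of a directed weighted structural connectome. A
synthetic-data module with planted structure makes every stage verifiable
offline at desk scale.

## Modules

| module | purpose |
|---|---|
| `cofluct.synth` | planted-structure generators: modular directed connectome, AR(1) block-covariance time series with injected events, rank-1 pattern libraries |
| `cofluct.edges` | standardization, edge time series, static FC, per-frame patterns, RMS amplitude |
| `cofluct.events` | RMS peak detection, circular-shift null, BH-FDR event calls, frame categories, FC-reconstruction and amplitude-binning reports |
| `cofluct.clustering` | Lin's concordance, signed-matrix Louvain + consensus, recursive pruned hierarchy, centroids |
| `cofluct.structure` | bipartition extraction, induced modularity on a directed connectome, independent / rotation / variogram permutation nulls, structure-function coupling |
| `cofluct.io` / `cofluct.cli` | TSV/JSON readers and writers, pipeline driver, command-line interface |

## CLI

```sh
cofluct simulate --out sim --seed 7                 # synthetic dataset + ground truth
cofluct ets --ts sim/timeseries.tsv --out ets       # edge series, FC, RMS
cofluct detect --ts sim/timeseries.tsv --n-runs 100 --q 0.05 --seed 7 --out det
cofluct cluster --patterns patterns_dir --n-iter 1000 --n-perm 1000 --alpha 0.05 --seed 7 --out clus
cofluct bipartition --centroid clus/centroid0.tsv --sc sim/connectome.tsv \
    --coords coords.tsv --gamma 1.0 --n-perm 1000 --null rotation --seed 7 --out bip
cofluct coupling --ts sim/timeseries.tsv --sc sim/connectome.tsv --out coup
cofluct run --config analysis.json                  # full pipeline from a config JSON
```

`cofluct run` takes an analysis config JSON (see `cofluct.io.AnalysisConfig`)
that either points at per-subject time-series TSVs (plus optional connectome
and coordinates) or embeds a `synthetic` block; it writes every intermediate
artifact, a manifest, and a summary report.

## Conventions

- Standardization uses sample SD (denominator T−1) and FC is the 1/(T−1)
  temporal sum of edge products, so the temporal mean of every edge series
  equals the Pearson correlation of the raw rows exactly.
- Edges are ordered row-major over the upper triangle, 0-based indices.
- Pattern diagonals are exactly zero and excluded from all similarity
  statistics.
- All files are plain TSV/JSON; one config seed deterministically derives
  per-stage seeds, so reruns are byte-identical.
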