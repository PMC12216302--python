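# thalamap

Analysis pipeline for mouse anterior-thalamic-nuclei connectomics and
dendritic morphology, built around three quantitative cores:

1. **Connectivity-domain detection** — tracer label (anterograde pixel
   coverage, retrograde cell counts) tabulated into square pixel grids
   (default 105 × 105 px at 0.6 µm/px ≈ 63 µm per side), aggregated into a
   per-row max-scaled injection × grid matrix, and partitioned by Louvain
   modularity maximization on the weighted bipartite graph (resolution
   γ = 0.75), with block-diagonal reordering and per-grid domain maps.
2. **Projection-profile normalization** — per-case connectivity fractions
   (`f = count / Σ counts`) and densities (`d = (f/area) / max(f/area)`),
   plus 2D agglomerative clustering of case × ROI density tables.
3. **SWC morphometrics and center-tropism** — parsing/validation/resampling
   of 7-column SWC reconstructions; total length, branch count, height,
   max path distance, average branch order, partition asymmetry, Sholl
   profiles (50 µm shells); per-compartment angular deviation from the local
   center vector, proportion of wiring closer to the center than the soma,
   edge/non-edge soma classification, and the distance–deviation Pearson
   correlation; two-cluster K-means typing and the associated statistics
   (rank-sum, pooled t, BH-FDR).

A first-class synthetic-data module generates every input the stages
consume — center-tropic neuron trees (vMF-like directional sampling with
concentration κ; κ = 0 is isotropic), planted-block injection × grid
matrices, two-component feature mixtures, and ROI count tables — so the
whole pipeline runs and is testable without imaging data.

## CLI

```sh
thalamap simulate cohort --preset amd-edge-study --seed 1 --out sim/
thalamap domains --gamma 0.75 --seed 1 --out results/
thalamap morpho --preset amd-edge-study --seed 1 --out results/
thalamap tropism --swc-dir sim/swc --geometry sim/geometry.json
thalamap profiles --input density.csv --linkage average --distance correlation
thalamap type --features features.csv --seed 1
```

`domains` and `morpho` run end-to-end workflows (simulated inputs by
default; `--no-simulate` with `--input-dir` / `--swc-dir` + `--geometry`
for real data) and write CSV/JSON outputs plus a `manifest.json` with all
parameters, the seed, and SHA-256 digests of the outputs.

## Layout

```
src/thalamap/
  swc.py          SWC I/O, validation, ~1 µm arc-length resampling
  morphometry.py  per-neuron dendritic features and Sholl profiles
  tropism.py      center-tropism statistics and edge classification
  domains.py      grid tabulation, matrix aggregation, Louvain domains
  profiles.py     fraction/density normalization, 2D clustering
  stats.py        K-means typing, rank-sum, pooled t, BH-FDR, Pearson
  synthetic.py    generators for neurons, cohorts, matrices, count tables
  pipeline.py     end-to-end workflows with reproducibility manifests
  cli.py          thalamap command-line interface
tests/            pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
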