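# seamod

Dissects microbial community count data into **co-occurrence modules**,
classifies pairwise **community-assembly mechanisms** with phylogenetic and
compositional null models, and links module mixing to **surface-current
accumulation** via a drifter-derived transport-matrix tracer simulation.
Everything runs end-to-end on synthetic data with planted latitudinal
structure, so no external downloads are needed.

## Stages

| module | what it does |
|---|---|
| `seamod.synthdata` | synthetic metadata, counts, ultrametric phylogeny and drifter trajectories with planted niche modules and convergence zones at ±30° |
| `seamod.preprocess` | abundance/prevalence filter, rarefaction, richness & inverse-Simpson ENS, normalized weighted UniFrac + WPGMA, abundance-weighted niche summaries |
| `seamod.sparcc` | compositional correlations (log-ratio variance / basis-variance approximation with pair exclusion), permutation bootstrap p-values, BH adjustment, positive-edge selection |
| `seamod.netmodules` | merge per-subset edge lists, edge-betweenness (divisive) module detection cut at maximum modularity, rewiring null test |
| `seamod.localstruct` | per-sample subnetworks and local modularity, module abundance profiles, module–richness coupling, cross-dataset module tracking, two-phase module-ratio test |
| `seamod.assembly` | βMNTD / βNTI (tip-shuffle null) and abundance-adjusted Raup–Crick, five-way mechanism classification, per-group fractions |
| `seamod.transport` | 0.5°-style gridding of drifter fixes, row-stochastic transport matrix from 30-day subtrajectories, multi-year tracer advection, mean velocity fields, station read-out |
| `seamod.pipeline` | one-config orchestration with a checksummed manifest; identical config + seed ⇒ bit-identical outputs |

## CLI

One entry point with per-stage groups:

```sh
seamod run --seed 1 --outdir out/                 # full pipeline, default toy config
seamod synth --seed 1 --outdir data/              # synthetic inputs only
seamod prep filter data/counts.tsv --out filtered.tsv
seamod prep rarefy filtered.tsv --depth 8000 --seed 1 --out rarefied.tsv
seamod net sparcc data/counts.tsv data/metadata.csv \
    --subset ocean=atlantic,fraction=0.2-3,layer=upper --nboot 999 --seed 1 --out edges.tsv
seamod net cluster edges.tsv --out membership.tsv
seamod local modularity edges.tsv membership.tsv rarefied.tsv --out local.tsv
seamod assembly classify rarefied.tsv data/tree.nwk data/metadata.csv --nnull 999 --seed 1 --out calls.tsv
seamod transport build data/trajectories.csv --dx 0.5 --dy 0.5 --dt 30 --out P.tsv
```

All artifacts are plain text (TSV/CSV/Newick/JSON), so any stage can be run
standalone. A YAML config (`seamod run --config run.yaml`) controls every
parameter; defaults are sized for a single CPU (full toy pipeline ≈ 30 s).

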