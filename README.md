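# phytoassay

Tools for scoring plant–microbe infection bioassays and for meta-analyzing
literature reports of host-associated microbiomes.

The package covers four analysis areas plus a synthetic-data generator:

- **`assay_scoring`** — weighted 0–4 disease indices from leaf-category
  counts, standardized 10-day indices via through-origin regression (with
  late-day and post-death exclusion rules), seedling growth rates, 0–1
  mature-leaf lesion means, and pathogenicity classification on both scales.
- **`comparative_stats`** — paired t-tests, Bonferroni correction,
  Bray–Curtis dissimilarity, one-way permutational MANOVA, and a
  betadisper-style group-dispersion check. All statistics are implemented
  directly and verified against independent oracles in the test suite.
- **`literature_db`** — a microbe-report data model with host-lineage
  assignment rules (geography + collection era), free-text tissue
  normalization to a closed vocabulary, culture-dependence / minimum-isolate
  community filters, taxon-overlap lattices, species-level subsetting, and
  collection-coverage fractions.
- **`trophic`** — predicted trophic modes from a local guild lookup table
  (confidence- and rank-filtered) and experimentally supported
  Pathogen/Endophyte/Saprophyte classes derived from the three bioassays via
  a swappable precedence policy; normalized P:E:S ratios.
- **`barcode`** — screening of identification hits by coverage/identity
  thresholds, WPGMA clustering with deterministic tie-breaking and Newick
  export, monospecific-clade extraction, and single-linkage clustering at a
  fixed dissimilarity threshold. Consumes precomputed similarity data only.
- **`simulate`** — seed-deterministic generators for all of the above input
  schemas, with ground-truth tables for round-trip testing.

## Command line

The console script `phytoassay` exposes each stage:

```sh
phytoassay simulate --preset seedling --seed 1 --out sim/
phytoassay score-seedling sim/seedling_observations.csv --out scored.csv
phytoassay classify scored.csv --thresholds thresholds.yaml --out classified.csv
phytoassay litdb-filter reports.tsv --min-isolates 10 --out communities.tsv
phytoassay litdb-overlap reports.tsv --by continent --out overlap.json
phytoassay permanova --dist dist.tsv --metadata meta.tsv --factor continent \
    --permutations 999 --seed 1 --out permanova.json
phytoassay trophic reports.tsv --guild-table guild.tsv --out modes.json
phytoassay run-all --config run.yaml --seed 1 --out out/
```

`run-all` reads a YAML config naming the input tables (seedling, mature,
saprophyte, literature reports, guild table) and writes scored TSVs plus a
schema-validated `summary.json`.

Classification thresholds (pathogen cut 2.0, strong cut 4.1 on the seedling
scale; 0.2 / 0.5 / 0.8 bands on the mature scale; day cutoff 16; symptom
floor 0.03) live in one `ClassificationThresholds` object and can be
overridden from a YAML file via `--thresholds`.

## Layout

```
src/phytoassay/      package modules (one per analysis area)
data/                published per-isolate index values used by acceptance
tests/               pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
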