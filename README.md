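# ki67grid

Grid-based whole-slide Ki67 scoring and recurrence-score concordance tools.

The package takes per-grid cell-detection exports from tile-based image
analysis (one row per square grid with a tumor-cell count and a
Ki67-positive count) and provides:

* **scoring** — QC filtering (grids with fewer than 100 tumor cells excluded)
  and the three whole-slide scores: the pooled **average** score
  (sum positive / sum tumor over all valid grids), the **hotspot** score
  (mean labeling index of the top five grids), and the **hottest-spot**
  score (the maximum grid labeling index);
* **ikwg_sim** — a Monte-Carlo simulation of the IKWG manual scoring
  protocol: grids are partitioned into zero/low/medium/high staining levels
  at thirds of the labeling-index range, four fields are sampled across the
  levels, and global and weighted average scores are summarized over 1000
  replicates (median plus 2.5/97.5 percentile interval);
* **cohort** — RS categories (0–15 / 16–19 / 20–25 / >25), Ki67 decade
  bins, the combined risk rule (low iff grade 1 or hotspot < 20),
  age-dependent chemotherapy indication by RS, contingency tables, and
  misclassification accounting.  A bundled reference cross-tabulation of a
  240-case cohort (`src/ki67grid/data/reference_tabulations.tsv`) can be
  expanded into per-case records to exercise every classifier offline;
* **stats** — Pearson chi-square (no continuity correction), Pearson
  correlation, and quartile summaries;
* **synthetic** — a generator of slides (negative-binomial cell counts,
  Gaussian hotspot bumps, binomial positives) and cohorts (lognormal
  baseline labeling index, saturating square-root RS link) with the spatial
  and statistical structure the pipeline expects, plus `regrid` for
  emulating coarser grid sizes;
* **grid_io** — TSV/CSV readers and writers with configurable column maps.

## CLI

A single `ki67grid` entry point with subcommands:

```sh
# generate a synthetic cohort of grid tables + metadata
ki67grid synth -o cohort/ --n-cases 10 --seed 1

# score slides (QC min-cells 100, hotspot top-5 by default)
ki67grid score cohort/case*.tsv -o scores.tsv --metadata cohort/metadata.tsv

# simulate the IKWG field-sampling protocol (1000 replicates by default)
ki67grid ikwg cohort/case*.tsv -o ikwg.json --seed 1

# contingency tables, chi-square, misclassification accounting
ki67grid concordance --scores scores.tsv -o report.json

# re-derive the bundled reference tabulations through the classifiers
ki67grid reproduce-tables
```

Custom input schemas are handled with a YAML config containing a
`column_map`, e.g.

```yaml
column_map:
  grid_id: tile
  tumor_cells: ncells
  positive_cells: npos
```

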