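# ringpta

Partial triadic analysis (PTA) of space-time tree-ring datacubes.

A ring dataset is a three-way array: trees × ring descriptors × years.
`ringpta` decomposes it with the classic three-step PTA:

1. **Interstructure** — pairwise vectorial correlations between the K
   standardized two-way slices of the cube, eigen-analyzed without centering
   to produce a typology of the tables and nonnegative compromise weights.
2. **Compromise** — the weights-weighted mean of the standardized tables,
   analyzed by PCA (inertia split, correlation-circle loadings, row scores).
3. **Intrastructure** — each original table projected as a supplementary
   element onto the compromise axes, with a 95% quantile envelope flagging
   the rows that depart from the common model.

Both orientations are supported: `by-year` (one trees × descriptors table
per year → the temporal evolution of spatial structures) and `by-tree`
(one years × descriptors table per tree → the spatial structure of temporal
dynamics). The `by-year` analysis can additionally test the axis-1 tree
scores for spatial structure with a permutation-based Moran's I correlogram,
Holm-corrected across distance classes.

A simulator (`ringpta.synthetic_data`) generates datacubes with planted
spatially autocorrelated tree factors, pulse years, and monotone trends,
plus recovery metrics for benchmarking the whole pipeline.

## CLI

```sh
# simulate a cube with a pulse year and a trend, write it as TSVs
ringpta simulate --out sim/ --seed 7 --n-trees 60 --n-years 30

# full analysis in one orientation; exports TSVs, JSON and plots
ringpta fit --input sim/rings.tsv --coords sim/coords.tsv \
    --mode by-year --r-method mean-cor --out results/by_year \
    --seed 1 --n-perm 1000

ringpta fit --input sim/rings.tsv --mode by-tree --out results/by_tree

# Moran's I permutation correlogram of any per-point variable
ringpta correlogram --values scores.tsv --coords coords.tsv \
    --out corr.json --seed 1 --n-perm 1000

# print the summary of an exported bundle
ringpta report --bundle results/by_year
```

Input is a delimited long-format text file, one row per tree-year, with
tree/year (and optionally x/y) columns plus one column per descriptor; the
default descriptor set is the 11 ring codes (RW, LW, RD, ED, LD, MID, MAD,
Co, RSD, ESD, LSD). Column names are remappable with a schema config.

## Python API

```python
import ringpta as rp

cube, truth = rp.simulate_cube(rp.SimConfig(seed=1, pulse_years={1985: 3.0}))
bundle = rp.run_analysis(cube, "by-year", rp.AnalysisConfig(n_perm=1000, seed=1))
bundle.interstructure.inertia_pct   # per-component inertia %
bundle.compromise.row_scores        # tree scores on the compromise axes
bundle.intrastructure.outlier_counts
bundle.correlogram.globally_significant
rp.export_bundle(bundle, "out/")
```

## Reference dataset

The reproduction tests in `tests/test_acceptance.py` and the report script
`scripts/acceptance.py` validate the pipeline against a published reference
ring dataset (149 georeferenced larch trees, 11 descriptors, years
1967–2007) that is **not redistributable** with this repository. To run
them, place the long-format ring file at `data/dataset_s1.txt` (optionally
with a `data/dataset_s1_schema.json` column mapping), or set the
`RINGPTA_DATASET_S1` environment variable to its path. Without the file
those tests fail with an explanatory message and the report script writes an
empty JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All remaining acceptance criteria (matrix invariants, rank-one limits,
planted-factor recovery at SNR 2, permutation-test calibration, and
brute-force oracle equivalence) are self-contained and run in the normal
test suite.

## Numeric conventions

Pinned defaults, all exposed as flags/config and echoed into provenance:

- per-table column standardization with the population (1/n) denominator;
- inter-table coefficient `mean_cor` (mean of per-descriptor Pearson
  correlations; `rv` — normalized Frobenius inner product — is equivalent
  under the 1/n standardization and available as an option);
- quantile envelopes by linear interpolation of order statistics (type 7);
- two-sided permutation p-values with add-one correction, one shared
  permutation stream across distance classes;
- PCA axis signs fixed so the largest-magnitude loading on each axis is
  positive.
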