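# geiblock

Block-additive modeling of genotype-by-environment interaction (GEI) from a
two-way table of phenotype means with arbitrary missing cells.

The idea: partition genotypes (rows) and environments (columns) into an
`n x m` grid of cells such that, inside every cell, the interaction is
constant and the phenotype follows a plain no-interaction model
`value = mu + G_i + E~_j + error`, where `E~_j` is the environment effect
local to the cell. The partition is found by biclustering a transformed
response (by default the double-centered interaction expression) with an
alternating minimization that tolerates missing values — no imputation
anywhere. The quality of a partition is measured two ways:

* **SSEbc** — within-cell sum of squared deviations from cell means of the
  clustered response (the biclustering objective), and
* **SSEni** — the total error of separate no-interaction fits on the raw
  phenotype inside each cell.

Classical benchmarks (additive, cell-means, Finlay–Wilkinson regression on
the mean, and AMMI with Gollob degrees of freedom) are provided with
sequential df/SS ANOVA tables, along with a synthetic-data generator with
planted block structure and cluster-driven missing-not-at-random masks.

## Library quick tour

```python
import geiblock as gb

table = gb.read_table("phenotypes.csv", layout="wide")   # or layout="long"
print(gb.summarize(table))

# transform and bicluster with 30 random restarts
y = gb.transform(table, gb.ResponseKind.DOUBLE_CENTERED)
result = gb.best_of(y, n=3, m=3, trials=30, base_seed=0)

# no-interaction models inside every cell, on the raw phenotype
model = gb.fit_blockwise(table, result.partition)
print(model.sse_ni, model.predict("g17", "e4"))

# classical benchmarks
report = gb.render_anova_report([
    gb.fit_additive(table).anova,
    gb.fit_cell_means(table),
    gb.fit_finlay_wilkinson(table).anova,
    gb.fit_ammi(table, 2).anova,
])
print(report)

# sweep cluster-count pairs
grid = gb.grid_search(table, 2, row_range=range(2, 5), col_range=range(2, 5),
                      trials=30, base_seed=0)
print(gb.suggest_pair(grid))
```

`gb.exhaustive_bicluster` enumerates every partition pair on tiny instances
and serves as a ground-truth oracle for the heuristic search.

## Command line

Each stage of the pipeline is a subcommand of `geiblock`:

```sh
geiblock simulate --spec spec.yaml --out table.csv --truth truth.json
geiblock summary table.csv
geiblock transform table.csv --response 2 --out y.csv
geiblock bicluster table.csv --rows 3 --cols 3 --response 2 --trials 30 \
    --seed 0 --out-prefix run
geiblock blockwise table.csv --partition run_rows.csv,run_cols.csv --out bw.json
geiblock fit-benchmarks table.csv --models additive,cellmeans,fw,ammi --ammi-k 2
geiblock grid table.csv --rows 2:5 --cols 2:4 --response 2 --trials 30 \
    --seed 0 --out-prefix grid --heatmap grid.png
```

Wide tables have a header of environment labels and one genotype per row;
empty fields are missing. Long tables have `genotype,environment,value`
columns; replicate records are averaged. Comma and tab delimiters are
accepted.

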