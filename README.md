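# regwire

Condition-specific gene co-expression networks from two-condition
expression data. From a genes × samples matrix (raw counts or normalized
expression), a two-condition design and a transcription-factor catalog,
`regwire`:

1. **adjusts the data** — per-column scaling to a fixed total of 10⁶
   (no transcript-length correction), a half-of-means gene filter, and a
   log2(x+1) transform (pre-normalized input only gets the filter);
2. **scores differential expression** — the gene-wise difference of
   condition means, z-standardized across genes (cutoff 1.96 by default);
3. **scores TF regulatory impact** — two per-TF metrics (RIF1/RIF2)
   summarizing how the TF's co-expression with the DE-gene set changes
   between conditions; TFs with |score| > 1.96 are significant;
4. **filters edges with the partial-correlation trio test** — every node
   trio's partial correlations and tolerance decide which pairwise
   associations survive, per condition;
5. **assembles networks** — undirected, per-condition, with a
   high-regulatory-impact TF table joining impact scores to each TF's
   degree difference between conditions, plus TSV/SIF/GraphML exports.

A synthetic-data module plants a differentially wired TF, a DE module and
null genes with known ground truth, so the whole pipeline is testable
without any external download.

## CLI

```sh
# generate a synthetic dataset with planted ground truth
regwire simulate --outdir sim/ --seed 1

# full pipeline
regwire run --input sim/matrix.tsv --design sim/design.tsv \
    --tf-catalog sim/tfs.txt --outdir out/ --kind counts --reference cond1

# individual stages
regwire diffexp --input sim/matrix.tsv --design sim/design.tsv --out diff.tsv
regwire rif --input sim/matrix.tsv --design sim/design.tsv \
    --tf-catalog sim/tfs.txt --out rif.tsv
regwire pcit --corr corr.tsv --out edges.tsv
```

`regwire run` also accepts a YAML config (`--config cfg.yaml`) with any
flag overriding it. Outputs: filtered/normalized matrix, filter report,
differential-expression tables, RIF table, significant-TF list,
per-condition edge lists (TSV + SIF), the HRi table and a JSON manifest
that reproduces the run.

Input formats: TSV/CSV (first column gene ids, header of sample ids) or
MatrixMarket MTX with `--row-names`/`--col-names` sidecars. Whether the
matrix holds counts or normalized expression is always declared with
`--kind`, never guessed.

## Python API

```python
import regwire as rw

spec = rw.SimSpec(seed=1)
matrix, design, tfs, truth = rw.sim_counts(spec)

from regwire.pipeline import analyze
res = analyze(matrix, design, tfs)
res.rif            # per-TF impact scores
res.hri            # significant TFs ranked by degree difference
res.net_ref.graph  # networkx graph for the reference condition
```

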