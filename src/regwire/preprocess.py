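"""Expression ingestion, per-column TPM scaling, gene filtering, log transform.

The normalization chain for count input is: column scaling to a fixed total
of 10**6 (no transcript-length correction), the half-of-means gene filter,
then log2(x + 1). Pre-normalized input only goes through the filter.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, FilterReport

log = logging.getLogger(__name__)

TPM_TOTAL = 1_000_000.0


def read_expression(
    path: str | Path,
    fmt: str = "tsv",
    kind: str = "counts",
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV or a MatrixMarket triplet.

    TSV/CSV layout: header row of sample ids, first column gene ids.
    The ``mtx`` format requires ``row_names`` and ``col_names`` sidecar
    files (one identifier per line). ``kind`` is declared by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        # locate non-numeric cells before the cast so the error names them
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-numeric value {df.iat[r, c]!r} at gene {gene_ids[r]!r}, "
                f"sample {sample_ids[c]!r}"
            )
        if numeric.isna().to_numpy().any():
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(f"missing value at gene {gene_ids[r]!r}, sample {sample_ids[c]!r}")
        values = numeric.to_numpy(dtype=float)
    elif fmt == "mtx":
        if row_names is None or col_names is None:
            raise ValueError("mtx format requires row_names and col_names sidecar files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        gene_ids = [l.strip() for l in Path(row_names).read_text().splitlines() if l.strip()]
        sample_ids = [l.strip() for l in Path(col_names).read_text().splitlines() if l.strip()]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected tsv, csv or mtx")
    return ExpressionMatrix(values, gene_ids, sample_ids, kind)


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each column so it sums to 10**6.

    Pure per-column total-count scaling; transcript lengths are deliberately
    not involved. Column proportions are preserved exactly.
    """
    if m.kind != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        names = ", ".join(m.sample_ids[i] for i in zero)
        raise ValueError(f"all-zero column(s), cannot scale: {names}")
    values = m.values * (TPM_TOTAL / colsums)
    return ExpressionMatrix(values, list(m.gene_ids), list(m.sample_ids), "normalized")


def filter_genes(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes whose mean exceeds half of two global averages.

    The two global scalars are the mean of all nonzero entries and the mean
    of all entries; a gene survives iff its row mean is strictly above half
    of BOTH. Both thresholds are recorded in the report so the decision can
    be audited. Ties at the boundary are dropped.
    """
    vals = m.values
    nonzero = vals[vals != 0]
    t1 = float(nonzero.mean()) if nonzero.size else 0.0
    t2 = float(vals.mean())
    gene_means = vals.mean(axis=1)
    keep = (gene_means > 0.5 * t1) & (gene_means > 0.5 * t2)
    kept = [g for g, k in zip(m.gene_ids, keep) if k]
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    if not kept:
        raise ValueError(
            "no genes survive the half-of-means filter; review the expression "
            f"scale (thresholds: nonzero-mean {t1:.4g}, overall-mean {t2:.4g})"
        )
    report = FilterReport(kept, dropped, t1, t2)
    log.info("gene filter kept %d / %d genes", len(kept), m.n_genes)
    return m.subset_genes(kept), report


def log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every entry x to log2(x + 1). Strictly monotone; order-preserving."""
    if (m.values < 0).any():
        raise ValueError("log_normalize requires nonnegative entries")
    return ExpressionMatrix(
        np.log2(m.values + 1.0), list(m.gene_ids), list(m.sample_ids), "normalized"
    )


def preprocess(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Full adjustment chain dispatching on input kind.

    counts: TPM scaling -> filter -> log2(x+1).
    normalized: the gene filter only.
    """
    if m.kind == "counts":
        tpm = tpm_normalize(m)
        filtered, report = filter_genes(tpm)
        return log_normalize(filtered), report
    filtered, report = filter_genes(m)
    return filtered, report
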