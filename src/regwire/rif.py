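"""Regulatory impact scores for transcription factors.

Two per-TF metrics summarize how a TF's co-expression with the
differentially expressed (DE) gene set changes between conditions:

* metric 1 weights the squared change in TF-gene correlation by each DE
  gene's phenotype impact (average abundance x differential-expression
  z-score), so TFs rewired against abundant, strongly DE genes score high;
* metric 2 contrasts the TF's squared ability to predict DE-gene abundance
  (condition mean x correlation) between the two conditions.

Raw scores are z-standardized across TFs; a TF is significant when either
standardized score exceeds 1.96 in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import pearson_rows
from .diffexp import DEClassification
from .types import ConditionDesign, ExpressionMatrix, TFCatalog

__all__ = ["RIFInput", "build_rif_input", "rif_scores", "significant_tfs", "SIG_THRESHOLD"]

SIG_THRESHOLD = 1.96


@dataclass
class RIFInput:
    """Per-condition TF/DE-gene correlations plus the abundance terms.

    ``r_ref`` and ``r_alt`` are (n_tf, n_de) Pearson matrices computed on
    each condition's samples; ``e_ref``/``e_alt`` are DE-gene condition
    means, ``a`` the DE-gene all-sample means, ``diff`` their DE z-scores,
    and ``tf_avgexpr`` the TF all-sample means.
    """

    tf_ids: list[str]
    de_ids: list[str]
    r_ref: np.ndarray
    r_alt: np.ndarray
    e_ref: np.ndarray
    e_alt: np.ndarray
    a: np.ndarray
    diff: np.ndarray
    tf_avgexpr: np.ndarray

    def swapped(self) -> "RIFInput":
        """View with the two conditions exchanged (diff changes sign)."""
        return RIFInput(
            self.tf_ids,
            self.de_ids,
            self.r_alt,
            self.r_ref,
            self.e_alt,
            self.e_ref,
            self.a,
            -self.diff,
            self.tf_avgexpr,
        )


def build_rif_input(
    m: ExpressionMatrix,
    de: DEClassification,
    tfs: TFCatalog,
    design: ConditionDesign,
) -> RIFInput:
    """Correlate every catalog TF with every DE gene, per condition.

    TFs absent from the matrix are reported via the catalog helper and
    skipped here; constant profiles within a condition correlate as 0 with
    a logged warning. Each condition needs at least 3 samples.
    """
    de_ids = de.de_genes
    if not de_ids:
        raise ValueError("no DE genes; cannot build the TF correlation input")
    tf_ids, absent = tfs.present_in(m)
    if not tf_ids:
        raise ValueError("no catalog TF is present in the expression matrix")
    design.check_covers(m.sample_ids)
    for cond in (design.reference, design.alternate):
        n = sum(1 for s in m.sample_ids if design.assignments[s] == cond)
        if n < 3:
            raise ValueError(f"condition {cond!r} has {n} samples; >= 3 required for correlation")

    tf_idx = m.gene_index(tf_ids)
    de_idx = m.gene_index(de_ids)
    ref_cols = m.sample_index([s for s in m.sample_ids if design.assignments[s] == design.reference])
    alt_cols = m.sample_index([s for s in m.sample_ids if design.assignments[s] == design.alternate])

    r_ref = pearson_rows(m.values[np.ix_(tf_idx, ref_cols)], m.values[np.ix_(de_idx, ref_cols)])
    r_alt = pearson_rows(m.values[np.ix_(tf_idx, alt_cols)], m.values[np.ix_(de_idx, alt_cols)])

    de_vals = m.values[de_idx]
    return RIFInput(
        tf_ids=tf_ids,
        de_ids=de_ids,
        r_ref=r_ref,
        r_alt=r_alt,
        e_ref=de_vals[:, ref_cols].mean(axis=1),
        e_alt=de_vals[:, alt_cols].mean(axis=1),
        a=de_vals.mean(axis=1),
        diff=de.frame.loc[de_ids, "diff"].to_numpy(),
        tf_avgexpr=m.values[tf_idx].mean(axis=1),
    )


def rif_scores(rif_in: RIFInput) -> pd.DataFrame:
    """Raw and standardized regulatory-impact metrics per TF.

    For TF i over the n_de DE genes j, with pif_j = a_j * diff_j:

        raw1_i = (1/n_de) sum_j pif_j * (r_ref_ij - r_alt_ij)**2
        raw2_i = (1/n_de) sum_j [(e_ref_j * r_ref_ij)**2 - (e_alt_j * r_alt_ij)**2]

    Both raw vectors are z-standardized across TFs (n-1 sd) into ``RIF1``
    and ``RIF2``; ``sig1``/``sig2`` flag |score| > 1.96.
    """
    n_tf = len(rif_in.tf_ids)
    if len(rif_in.de_ids) == 0:
        raise ValueError("no DE genes in the input")
    if n_tf < 2:
        raise ValueError("at least 2 TFs are required to standardize the scores")
    pif = rif_in.a * rif_in.diff
    raw1 = (pif[None, :] * (rif_in.r_ref - rif_in.r_alt) ** 2).mean(axis=1)
    raw2 = (
        (rif_in.e_ref[None, :] * rif_in.r_ref) ** 2
        - (rif_in.e_alt[None, :] * rif_in.r_alt) ** 2
    ).mean(axis=1)

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    rif1 = zscore(raw1)
    rif2 = zscore(raw2)
    return pd.DataFrame(
        {
            "avgexpr": rif_in.tf_avgexpr,
            "rif1_raw": raw1,
            "rif2_raw": raw2,
            "RIF1": rif1,
            "RIF2": rif2,
            "sig1": np.abs(rif1) > SIG_THRESHOLD,
            "sig2": np.abs(rif2) > SIG_THRESHOLD,
        },
        index=pd.Index(rif_in.tf_ids, name="TF"),
    )


def significant_tfs(table: pd.DataFrame, threshold: float = SIG_THRESHOLD) -> list[str]:
    """TFs with |RIF1| or |RIF2| strictly above ``threshold``.

    Ordered by max(|RIF1|, |RIF2|) descending, ties broken by id.
    """
    score = np.maximum(table["RIF1"].abs(), table["RIF2"].abs())
    hits = table.index[score > threshold]
    return sorted(hits, key=lambda t: (-score[t], t))
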