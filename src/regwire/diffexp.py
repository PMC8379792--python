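"""Two-condition differential expression as a standardized mean contrast.

For every gene, the difference of condition means is computed and the
resulting vector is z-standardized across genes (sample variance, n-1).
Genes are then called up/down/not-DE against a cutoff on that z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ConditionDesign, ExpressionMatrix, TFCatalog

__all__ = ["reverter_diff", "classify_de", "DEClassification"]


def reverter_diff(m: ExpressionMatrix, design: ConditionDesign) -> pd.DataFrame:
    """Standardized mean-difference score per gene.

    Returns a DataFrame indexed by gene id with columns ``mean_ref``,
    ``mean_alt``, ``s`` (mean_ref - mean_alt), ``diff`` (the across-gene
    z-score of ``s``) and ``avgexpr`` (mean over all samples).

    Raises ``ValueError`` for a degenerate contrast (zero variance of ``s``
    across genes).
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to standardize the contrast")
    design.check_covers(m.sample_ids)
    ref_idx = m.sample_index([s for s in m.sample_ids if design.assignments[s] == design.reference])
    alt_idx = m.sample_index([s for s in m.sample_ids if design.assignments[s] == design.alternate])
    mean_ref = m.values[:, ref_idx].mean(axis=1)
    mean_alt = m.values[:, alt_idx].mean(axis=1)
    s = mean_ref - mean_alt
    var = s.var(ddof=1)
    if var == 0:
        raise ValueError("degenerate contrast: every gene has the identical condition difference")
    diff = (s - s.mean()) / np.sqrt(var)
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "s": s,
            "diff": diff,
            "avgexpr": m.values.mean(axis=1),
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )


@dataclass
class DEClassification:
    """Three-way DE call per gene plus TF membership.

    ``frame`` is indexed by gene id with columns ``diff``, ``avgexpr``,
    ``status`` (up/down/ns) and ``is_tf``.
    """

    frame: pd.DataFrame
    cutoff: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["status"] != "ns"])

    def counts(self) -> dict[str, int]:
        c = self.frame["status"].value_counts()
        tf = self.frame[self.frame["is_tf"]]["status"].value_counts()
        return {
            "up": int(c.get("up", 0)),
            "down": int(c.get("down", 0)),
            "ns": int(c.get("ns", 0)),
            "tf_up": int(tf.get("up", 0)),
            "tf_down": int(tf.get("down", 0)),
            "tf_ns": int(tf.get("ns", 0)),
        }


def classify_de(table: pd.DataFrame, cutoff: float, tfs: TFCatalog | None = None) -> DEClassification:
    """Call genes up/down/ns by comparing |diff| to ``cutoff`` (strict).

    A gene exactly at the boundary is not significant. ``tfs`` flags
    catalog membership; None marks every gene as non-TF.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = table["diff"]
    status = np.where(diff > cutoff, "up", np.where(diff < -cutoff, "down", "ns"))
    tf_ids = set(tfs.ids) if tfs is not None else set()
    frame = pd.DataFrame(
        {
            "diff": diff,
            "avgexpr": table["avgexpr"],
            "status": status,
            "is_tf": [g in tf_ids for g in table.index],
        },
        index=table.index,
    )
    return DEClassification(frame, cutoff)
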