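"""Trio-based partial-correlation filtering of a correlation matrix.

Every unordered trio of nodes {x, y, z} is examined: the three first-order
partial correlations are computed, their average ratio to the direct
correlations gives a per-trio tolerance, and a pair whose direct
correlation is dominated (in absolute value) by the tolerance-scaled
correlations of BOTH flanking pairs is discarded. A pair discarded in any
trio is non-significant in the result.

The main loop is vectorized over the third node z for each pair (x, y):
O(n^3) time, O(n^2) memory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import pearson_rows
from .types import ConditionDesign, CorrelationMatrix, ExpressionMatrix

__all__ = [
    "partial_correlation",
    "tolerance",
    "pcit",
    "pcit_per_condition",
    "correlation_matrix",
    "PCITResult",
]

log = logging.getLogger(__name__)

_CLAMP = 1.0 - 1e-12


def correlation_matrix(m: ExpressionMatrix, samples: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation of genes across a sample subset.

    Zero-variance genes get 0 off-diagonal with a logged warning.
    """
    sub = m if samples is None else m.subset_samples(samples)
    if sub.n_samples < 3:
        raise ValueError(f"need >= 3 samples for a correlation matrix, got {sub.n_samples}")
    if sub.n_genes < 2:
        raise ValueError("need >= 2 genes")
    return CorrelationMatrix(pearson_rows(sub.values), list(sub.gene_ids))


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z.

        (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))
    """
    for r in (r_xy, r_xz, r_yz):
        if abs(r) > 1:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r_xz) == 1 or abs(r_yz) == 1:
        raise ValueError("collinear trio: conditioning correlation has |r| = 1")
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def tolerance(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Per-trio tolerance: mean ratio of partial to direct correlation.

        (1/3) * (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz)

    Returns ``nan`` when any direct correlation is exactly 0 (the trio is
    non-informative and must issue no discards); symmetric in the trio.
    """
    if r_xy == 0 or r_xz == 0 or r_yz == 0:
        log.warning("non-informative trio (zero direct correlation); tolerance undefined")
        return float("nan")
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    return (p_xy / r_xy + p_xz / r_xz + p_yz / r_yz) / 3.0


@dataclass
class PCITResult:
    """Significant-association adjacency plus the underlying correlations."""

    significant: np.ndarray  # boolean, symmetric, False diagonal
    weights: np.ndarray  # the input correlation matrix
    node_ids: list[str]

    def edges(self) -> list[tuple[str, str, float]]:
        """Sorted list of significant (node_a, node_b, correlation) with a < b."""
        out = []
        n = len(self.node_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.significant[i, j]:
                    out.append((self.node_ids[i], self.node_ids[j], float(self.weights[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["node_a", "node_b", "correlation"])


def pcit(c: CorrelationMatrix, variant: str = "corrected") -> PCITResult:
    """Run the trio filter on a correlation matrix.

    ``variant='corrected'`` (default) discards pair (x, y) in trio
    {x, y, z} when |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|.
    ``variant='as_printed'`` reproduces a published variant whose first
    inequality degenerates to |eps| >= 1 (kept for audit only).

    Off-diagonal entries with |r| = 1 are clamped to +/-(1 - 1e-12) with a
    warning so trios never divide by zero. With fewer than 3 nodes no trio
    exists and every pair stays significant. Trios containing a zero
    direct correlation issue no discards.
    """
    if variant not in ("corrected", "as_printed"):
        raise ValueError(f"unknown variant {variant!r}")
    n = c.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    r = c.values.copy()
    off = ~np.eye(n, dtype=bool)
    saturated = off & (np.abs(r) >= 1.0)
    if saturated.any():
        log.warning("clamping %d |r|=1 off-diagonal entries", int(saturated.sum() // 2))
        r[saturated] = np.sign(r[saturated]) * _CLAMP

    significant = off.copy()
    if n < 3:
        return PCITResult(significant, c.values.copy(), list(c.node_ids))

    absr = np.abs(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        for x in range(n - 1):
            rx = r[x]  # r[x, :]
            for y in range(x + 1, n):
                rxy = r[x, y]
                rxz = rx  # vector over z
                ryz = r[y]
                denom_xy = 1.0 - rxy * rxy
                denom_xz = 1.0 - rxz * rxz
                denom_yz = 1.0 - ryz * ryz
                p_xy = (rxy - rxz * ryz) / np.sqrt(denom_xz * denom_yz)
                p_xz = (rxz - rxy * ryz) / np.sqrt(denom_xy * denom_yz)
                p_yz = (ryz - rxy * rxz) / np.sqrt(denom_xy * denom_xz)
                eps = (p_xy / rxy + p_xz / rxz + p_yz / ryz) / 3.0

                informative = (rxz != 0) & (ryz != 0) & (rxy != 0)
                informative[x] = False
                informative[y] = False
                abseps = np.abs(eps)
                if variant == "corrected":
                    discard = (
                        (absr[x, y] <= abseps * absr[x])
                        & (absr[x, y] <= abseps * absr[y])
                        & informative
                    )
                else:  # as printed: |r_xz| <= |eps r_xz| and |r_xy| <= |eps r_yz|
                    discard = (
                        (absr[x] <= abseps * absr[x])
                        & (absr[x, y] <= abseps * absr[y])
                        & informative
                    )
                if discard.any():
                    significant[x, y] = False
                    significant[y, x] = False
    return PCITResult(significant, c.values.copy(), list(c.node_ids))


def pcit_per_condition(
    m: ExpressionMatrix,
    design: ConditionDesign,
    nodes: list[str] | None = None,
    variant: str = "corrected",
) -> tuple[PCITResult, PCITResult]:
    """Run the trio filter separately on each condition's samples.

    ``nodes`` restricts the matrix to a gene/TF subset (default: all
    genes). Returns (reference_result, alternate_result).
    """
    design.check_covers(m.sample_ids)
    sub = m if nodes is None else m.subset_genes(nodes)
    results = []
    for cond in (design.reference, design.alternate):
        samples = [s for s in sub.sample_ids if design.assignments[s] == cond]
        if len(samples) < 3:
            raise ValueError(f"condition {cond!r} has {len(samples)} samples; >= 3 required")
        corr = correlation_matrix(sub, samples)
        results.append(pcit(corr, variant=variant))
    return results[0], results[1]
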