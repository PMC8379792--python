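"""Shared fixtures and the independent naive trio-filter oracle."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from regwire.types import ConditionDesign, ExpressionMatrix, TFCatalog

_CLAMP = 1.0 - 1e-12


def naive_pcit(r: np.ndarray) -> np.ndarray:
    """Brute-force trio filter, written independently of the production path.

    Enumerates every unordered trio with scalar arithmetic straight from the
    defining formulas; returns the boolean significance matrix.
    """
    r = np.array(r, dtype=float)
    n = r.shape[0]
    off = ~np.eye(n, dtype=bool)
    sat = off & (np.abs(r) >= 1.0)
    r[sat] = np.sign(r[sat]) * _CLAMP
    sig = off.copy()
    for x, y, z in combinations(range(n), 3):
        rxy, rxz, ryz = r[x, y], r[x, z], r[y, z]
        if rxy == 0 or rxz == 0 or ryz == 0:
            continue  # non-informative trio
        pxy = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        pxz = (rxz - rxy * ryz) / math.sqrt((1 - rxy**2) * (1 - ryz**2))
        pyz = (ryz - rxy * rxz) / math.sqrt((1 - rxy**2) * (1 - rxz**2))
        eps = abs((pxy / rxy + pxz / rxz + pyz / ryz) / 3.0)
        if abs(rxy) <= eps * abs(rxz) and abs(rxy) <= eps * abs(ryz):
            sig[x, y] = sig[y, x] = False
        if abs(rxz) <= eps * abs(rxy) and abs(rxz) <= eps * abs(ryz):
            sig[x, z] = sig[z, x] = False
        if abs(ryz) <= eps * abs(rxy) and abs(ryz) <= eps * abs(rxz):
            sig[y, z] = sig[z, y] = False
    return sig


def random_correlation(n: int, rng: np.random.Generator, n_obs: int | None = None) -> np.ndarray:
    """Empirical correlation matrix of random Gaussian data (always valid)."""
    data = rng.standard_normal((n, n_obs or n + 5))
    r = np.corrcoef(data)
    np.fill_diagonal(r, 1.0)
    return r


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples, hand-written values, counts."""
    values = np.array(
        [
            [10, 12, 11, 30, 31, 29],
            [5, 6, 5, 5, 6, 5],
            [0, 0, 0, 0, 0, 0],
            [100, 110, 105, 20, 22, 21],
        ],
        dtype=float,
    )
    return ExpressionMatrix(values, ["G1", "G2", "G3", "G4"], [f"S{i}" for i in range(1, 7)], "counts")


@pytest.fixture
def two_condition_design() -> ConditionDesign:
    return ConditionDesign(
        {f"S{i}": ("A" if i <= 3 else "B") for i in range(1, 7)},
        reference="A",
    )


@pytest.fixture
def tf_catalog() -> TFCatalog:
    return TFCatalog(("G4", "TFX"))
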