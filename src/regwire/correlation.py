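"""Pearson correlation helpers tolerant of constant profiles.

Zero-variance rows cannot carry a correlation; rather than aborting on
large real matrices their correlations are set to 0 and the event is
logged once per call.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows to unit norm; returns (z, zero_variance_mask)."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return centered / safe[:, None], zero


def pearson_rows(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between rows of ``x`` and rows of ``y``.

    With ``y=None`` returns the square row-correlation matrix of ``x`` with
    an exact unit diagonal. Rows with zero variance get correlation 0
    (off-diagonal) and a warning in the log.
    """
    zx, zerox = _standardize_rows(x)
    if y is None:
        r = zx @ zx.T
        np.clip(r, -1.0, 1.0, out=r)
        if zerox.any():
            log.warning("%d zero-variance profile(s); their correlations set to 0", zerox.sum())
            r[zerox, :] = 0.0
            r[:, zerox] = 0.0
        np.fill_diagonal(r, 1.0)
        return r
    zy, zeroy = _standardize_rows(y)
    r = zx @ zy.T
    np.clip(r, -1.0, 1.0, out=r)
    if zerox.any() or zeroy.any():
        log.warning(
            "%d zero-variance profile(s); their correlations set to 0",
            int(zerox.sum() + zeroy.sum()),
        )
        r[zerox, :] = 0.0
        r[:, zeroy] = 0.0
    return r
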