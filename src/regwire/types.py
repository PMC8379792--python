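"""Core value types shared across the pipeline.

All tabular results are plain :class:`pandas.DataFrame` objects; the classes
here are the small number of structures that carry invariants worth
enforcing at construction time (expression matrices, condition designs,
transcription-factor catalogs, correlation matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ConditionDesign",
    "TFCatalog",
    "FilterReport",
    "CorrelationMatrix",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicated {what}: {', '.join(dups)}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``kind`` declares whether values are raw counts or already-normalized
    expression; it is always set explicitly by the caller (never guessed
    from the values themselves).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    kind: str  # "counts" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.kind not in ("counts", "normalized"):
            raise ValueError(f"kind must be 'counts' or 'normalized', got {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids):
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_g} matrix rows")
        if n_s != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n_s} matrix columns")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite entries")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"gene ids not in matrix: {', '.join(sorted(missing))}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"sample ids not in matrix: {', '.join(sorted(missing))}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(ids)
        return ExpressionMatrix(self.values[idx], list(ids), list(self.sample_ids), self.kind)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(ids)
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(ids), self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ConditionDesign:
    """Sample-to-condition assignment for a two-condition contrast."""

    assignments: dict[str, str]
    reference: str

    alternate: str = field(init=False)

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"design must have exactly two conditions, found {labels}")
        if self.reference not in labels:
            raise ValueError(
                f"reference condition {self.reference!r} not among design labels {labels}"
            )
        self.alternate = next(c for c in labels if c != self.reference)
        for label in labels:
            n = sum(1 for c in self.assignments.values() if c == label)
            if n < 2:
                raise ValueError(f"condition {label!r} has {n} sample(s); at least 2 required")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == condition]

    def check_covers(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples missing from design: {', '.join(missing)}")

    def swapped(self) -> "ConditionDesign":
        """Same assignments with reference and alternate exchanged."""
        return ConditionDesign(dict(self.assignments), self.alternate)

    @classmethod
    def from_file(cls, path: str | Path, reference: str | None = None) -> "ConditionDesign":
        """Read a two-column (sample, condition) TSV; header optional.

        When ``reference`` is None the lexicographically smaller label is
        taken as reference.
        """
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"design file {path} needs two columns (sample, condition)")
        first = df.iloc[0]
        if str(first[0]).lower() in ("sample", "sample_id") or str(first[1]).lower() in (
            "condition",
            "group",
        ):
            df = df.iloc[1:]
        assignments = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if reference is None:
            reference = sorted(set(assignments.values()))[0]
        return cls(assignments, reference)


@dataclass
class TFCatalog:
    """Set of gene identifiers designated transcription factors."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("TF catalog is empty")
        self.ids = tuple(sorted(set(str(i) for i in self.ids)))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.ids)

    def present_in(self, matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
        """Split the catalog into (present, absent) relative to a matrix."""
        genes = set(matrix.gene_ids)
        present = [t for t in self.ids if t in genes]
        absent = [t for t in self.ids if t not in genes]
        return present, absent

    @classmethod
    def from_file(cls, path: str | Path) -> "TFCatalog":
        ids = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(tuple(ids))


@dataclass
class FilterReport:
    """Outcome of the half-of-means gene filter."""

    kept: list[str]
    dropped: list[str]
    threshold_nonzero_mean: float
    threshold_overall_mean: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "kept") for g in self.kept] + [(g, "dropped") for g in self.dropped]
        return pd.DataFrame(rows, columns=["gene", "status"])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold_nonzero_mean\t{self.threshold_nonzero_mean!r}\n")
            fh.write(f"# threshold_overall_mean\t{self.threshold_overall_mean!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with node labels."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = [str(n) for n in self.node_ids]
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"correlation matrix shape {self.values.shape} != ({n}, {n})")
        _check_unique(self.node_ids, "node ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_ids, columns=self.node_ids)
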