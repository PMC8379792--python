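"""Synthetic two-condition expression data with known ground truth.

A latent-factor construction plants a TF whose correlation with a block of
module genes differs between conditions (differential wiring), shifts the
module genes' abundance in the second condition (differential expression),
and surrounds them with independent null genes and null TFs. Both a
negative-binomial count emitter and a Gaussian log-scale emitter are
provided; every draw flows through one seeded generator so a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ConditionDesign, ExpressionMatrix, TFCatalog

__all__ = ["SimSpec", "GroundTruth", "sim_counts", "sim_norm", "write_simulation"]

# latent log2 spread of every gene around its baseline
_LATENT_SD = 1.0


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the planted-structure simulation.

    ``planted_tf_rho`` gives the target pairwise correlation between the
    planted TF and each module gene in (condition 1, condition 2).
    ``de_effect`` is the log2 shift applied to the module (DE) genes in
    condition 2. The negative-binomial emitter uses a mean-dispersion
    parameterization with variance mu + mu**2 / dispersion. ``noise_sd``
    scales the idiosyncratic part of factor-loaded genes (1.0 keeps unit
    latent variance; 0 makes module rows exact affine images of the
    factor).
    """

    n_genes: int = 300
    n_tfs: int = 20
    n_samples_per_condition: int = 50
    planted_tf_rho: tuple[float, float] = (0.8, 0.0)
    planted_module_size: int = 20
    de_effect: float = 2.0
    nb_dispersion: float = 50.0
    base_mean: float = 500.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than the gene pool")
        for rho in self.planted_tf_rho:
            if not abs(rho) < 1:
                raise ValueError(f"planted correlation {rho} must satisfy |rho| < 1")
        if self.n_tfs < 1 or self.n_genes < 1 or self.n_samples_per_condition < 2:
            raise ValueError("need >= 1 gene, >= 1 TF and >= 2 samples per condition")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")


@dataclass
class GroundTruth:
    """What was planted: the wired TF, its module, the DE genes, labels."""

    planted_tf: str
    module_genes: list[str]
    de_genes: list[str]
    conditions: tuple[str, str]


def _ids(spec: SimSpec) -> tuple[list[str], list[str], list[str]]:
    genes = [f"G{i+1:04d}" for i in range(spec.n_genes)]
    tfs = [f"TF{i+1:03d}" for i in range(spec.n_tfs)]
    n_total = 2 * spec.n_samples_per_condition
    samples = [f"S{i+1:03d}" for i in range(n_total)]
    return genes, tfs, samples


def _latent(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Latent standardized expression, rows = genes then TFs.

    Module genes and the planted TF share a per-condition factor with
    loading sqrt(|rho|), so any loaded pair correlates at |rho|; a negative
    rho flips the TF loading sign, making TF-module correlation rho while
    module-module stays |rho|.
    """
    n_s = spec.n_samples_per_condition
    n_rows = spec.n_genes + spec.n_tfs
    z = np.empty((n_rows, 2 * n_s))
    module = np.arange(spec.planted_module_size)
    tf_row = spec.n_genes  # first TF is the planted one
    for c, rho in enumerate(spec.planted_tf_rho):
        cols = slice(c * n_s, (c + 1) * n_s)
        factor = rng.standard_normal(n_s)
        eps = rng.standard_normal((n_rows, n_s))
        block = np.zeros(n_rows)
        block[module] = math.sqrt(abs(rho))
        block[tf_row] = math.copysign(math.sqrt(abs(rho)), rho) if rho != 0 else 0.0
        resid = spec.noise_sd * np.sqrt(1.0 - block**2)
        z[:, cols] = block[:, None] * factor[None, :] + resid[:, None] * eps
    return z


def _assemble(
    spec: SimSpec, values: np.ndarray, kind: str
) -> tuple[ExpressionMatrix, ConditionDesign, TFCatalog, GroundTruth]:
    genes, tfs, samples = _ids(spec)
    n_s = spec.n_samples_per_condition
    assignments = {s: ("cond1" if i < n_s else "cond2") for i, s in enumerate(samples)}
    design = ConditionDesign(assignments, reference="cond1")
    matrix = ExpressionMatrix(values, genes + tfs, samples, kind)
    truth = GroundTruth(
        planted_tf=tfs[0],
        module_genes=genes[: spec.planted_module_size],
        de_genes=genes[: spec.planted_module_size],
        conditions=("cond1", "cond2"),
    )
    return matrix, design, TFCatalog(tuple(tfs)), truth


def _de_shift(spec: SimSpec, log2_means: np.ndarray) -> None:
    """Shift module genes by de_effect log2 units in condition 2, in place."""
    n_s = spec.n_samples_per_condition
    log2_means[: spec.planted_module_size, n_s:] += spec.de_effect


def sim_counts(spec: SimSpec) -> tuple[ExpressionMatrix, ConditionDesign, TFCatalog, GroundTruth]:
    """Negative-binomial counts around exponentiated latent log2 means."""
    rng = np.random.default_rng(spec.seed)
    log2_means = math.log2(spec.base_mean) + _LATENT_SD * _latent(spec, rng)
    _de_shift(spec, log2_means)
    mu = np.exp2(log2_means)
    p = spec.nb_dispersion / (spec.nb_dispersion + mu)
    counts = rng.negative_binomial(spec.nb_dispersion, p).astype(float)
    return _assemble(spec, counts, "counts")


def sim_norm(spec: SimSpec) -> tuple[ExpressionMatrix, ConditionDesign, TFCatalog, GroundTruth]:
    """Gaussian log-scale expression emitted directly (no count sampling).

    Null-gene values center on ``base_mean``; negative draws are clipped at
    0 to respect the nonnegativity contract (negligible for sensible
    base_mean).
    """
    rng = np.random.default_rng(spec.seed)
    values = spec.base_mean + _LATENT_SD * _latent(spec, rng)
    _de_shift(spec, values)
    np.clip(values, 0.0, None, out=values)
    return _assemble(spec, values, "normalized")


def write_simulation(
    spec: SimSpec,
    outdir: str | Path,
    kind: str = "counts",
) -> dict[str, Path]:
    """Write matrix, design, TF list and ground-truth TSVs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_counts if kind == "counts" else sim_norm
    matrix, design, tfs, truth = sim(spec)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "design": outdir / "design.tsv",
        "tfs": outdir / "tfs.txt",
        "truth": outdir / "ground_truth.tsv",
    }
    with open(paths["matrix"], "w") as fh:
        fh.write(f"# seed\t{spec.seed}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": list(design.assignments), "condition": list(design.assignments.values())}
    ).to_csv(paths["design"], sep="\t", index=False, header=False)
    Path(paths["tfs"]).write_text("\n".join(tfs.ids) + "\n")
    rows = (
        [("planted_tf", truth.planted_tf)]
        + [("module_gene", g) for g in truth.module_genes]
        + [("de_gene", g) for g in truth.de_genes]
        + [("condition", c) for c in truth.conditions]
    )
    pd.DataFrame(rows, columns=["role", "id"]).to_csv(paths["truth"], sep="\t", index=False)
    return paths
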