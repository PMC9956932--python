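"""Preprocessing: zero-gene filtering, log transform, per-strain aggregation.

The method never normalises for library size or applies a variance
stabiliser; genes containing any zero are removed outright (no pseudocount
by default) so that the logarithm is defined everywhere, and each surviving
gene is reduced to four numbers: the mean and the sample standard deviation
of its log expression within each strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DesignError, PipelineError
from .expression_io import LOG, RAW, ExpressionMatrix, StrainDesign

logger = logging.getLogger(__name__)


@dataclass
class AggregatedProfile:
    """Per-gene (mean, std) of log expression for each of the two strains.

    ``strain_order`` fixes which strain is axis 1 vs axis 2 for the whole
    run; standard deviations use the n-1 denominator.
    """

    gene_ids: list[str]
    mean_1: np.ndarray
    mean_2: np.ndarray
    std_1: np.ndarray
    std_2: np.ndarray
    strain_order: tuple[str, str]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("mean_1", "mean_2", "std_1", "std_2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.std_1 < 0) or np.any(self.std_2 < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def mean_points(self) -> np.ndarray:
        """n x 2 matrix of (mean_1, mean_2) — the mean-stage clustering space."""
        return np.column_stack([self.mean_1, self.mean_2])

    def std_points(self) -> np.ndarray:
        """n x 2 matrix of (std_1, std_2) — the std-stage space."""
        return np.column_stack([self.std_1, self.std_2])


def filter_zero_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene with a zero (or non-positive) value in any sample.

    Gene order is preserved. Raises :class:`PipelineError` if nothing
    survives.
    """
    if X.scale != RAW:
        raise ValueError("filter_zero_genes expects a raw-scale matrix")
    keep = np.flatnonzero(np.all(X.values > 0, axis=1))
    removed = X.n_genes - keep.size
    if keep.size == 0:
        raise PipelineError("no genes survive zero filter")
    if removed:
        logger.info("zero filter removed %d of %d genes", removed, X.n_genes)
    return X.subset_genes(keep)


def log_transform(
    X: ExpressionMatrix, base: float = 2.0, pseudocount: float = 0.0
) -> ExpressionMatrix:
    """Replace values by log_base(value + pseudocount); scale becomes ``log``.

    With the default pseudocount of 0 every value must be strictly positive
    (run :func:`filter_zero_genes` first); a value <= 0 raises naming the gene.
    """
    if X.scale != RAW:
        raise ValueError("log_transform expects a raw-scale matrix")
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    shifted = X.values + pseudocount
    if np.any(shifted <= 0):
        g = np.argwhere(shifted <= 0)[0][0]
        raise ValueError(
            f"gene {X.gene_ids[g]!r} has a non-positive value; apply the zero "
            "filter (or a pseudocount) before the log transform"
        )
    values = np.log(shifted) / np.log(base)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), values, scale=LOG)


def aggregate(X: ExpressionMatrix, design: StrainDesign) -> AggregatedProfile:
    """Per-gene, per-strain mean and sample std (n-1) of log expression.

    The strain order of the profile follows the order of first appearance in
    the design. Invariant to sample-column permutation.
    """
    if X.scale != LOG:
        raise ValueError("aggregate expects a log-scale matrix")
    missing = [s for s in X.sample_ids if s not in design.assignment]
    if missing:
        raise DesignError(f"samples missing from design: {missing}")
    col_index = {s: j for j, s in enumerate(X.sample_ids)}
    stats = []
    for strain in design.strains:
        cols = [col_index[s] for s in design.samples_of(strain) if s in col_index]
        if len(cols) < 2:
            raise DesignError(
                f"strain {strain!r} has {len(cols)} sample(s) in the matrix; "
                "need at least 2"
            )
        block = X.values[:, cols]
        stats.append((block.mean(axis=1), block.std(axis=1, ddof=1)))
    (m1, s1), (m2, s2) = stats
    return AggregatedProfile(
        gene_ids=list(X.gene_ids),
        mean_1=m1,
        mean_2=m2,
        std_1=s1,
        std_2=s2,
        strain_order=design.strains,
    )
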