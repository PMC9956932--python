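"""Two-strain count simulator with known DE truth.

The generator emulates the shape of a bulk RNA-seq comparison of two inbred
mouse strains with ~10 and ~11 replicates: a few thousand genes with
log-normally distributed baselines, negative-binomial counts with a common
overdispersion, a small minority of genes whose mean expression is shifted
between strains (planted log2 fold change), a second minority whose strain
means agree but whose within-strain dispersion is inflated in one strain,
and a few genes forced to contain a zero so the zero filter has work to do.

Geometrically this creates exactly what the method exploits: a dense cloud
along the equivalence line of mean-space with off-line outliers (mean-DE
genes), and off-diagonal points in std-space (variance-DE genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, StrainDesign

CLASS_NULL = "null"
CLASS_MEAN_DE = "mean_de"
CLASS_STD_DE = "std_de"
CLASS_ZEROED = "zeroed"

STRAIN_1 = "C57BL/6J"
STRAIN_2 = "DBA/2J"


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Defaults: 2000 genes, 10 + 11 samples, 2.5% mean-DE genes at |log2 FC|
    = 2, 1.5% variance-DE genes with 4x dispersion in one strain, NB
    dispersion 0.1, baselines log2-normal(5, 1.5), 2% of genes forced to
    contain a zero.
    """

    n_genes: int = 2000
    n_samples_1: int = 10
    n_samples_2: int = 11
    frac_mean_de: float = 0.025
    mean_lfc: float = 2.0
    frac_std_de: float = 0.015
    dispersion_ratio: float = 4.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.1
    zero_gene_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_mean_de", "frac_std_de", "zero_gene_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_mean_de + self.frac_std_de + self.zero_gene_frac > 1.0:
            raise ValueError("class fractions must sum to <= 1")
        if self.n_samples_1 < 2 or self.n_samples_2 < 2:
            raise ValueError("each strain needs at least 2 samples")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.dispersion_ratio < 1:
            raise ValueError("dispersion_ratio must be >= 1")
        if self.mean_lfc < 0:
            raise ValueError("mean_lfc must be >= 0")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be > 0")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with mean mu and variance mu + phi*mu^2 (gamma-Poisson)."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mu)
    return rng.poisson(lam).astype(float)


def simulate_counts(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, StrainDesign, pd.DataFrame]:
    """Draw a count matrix, its design and a per-gene truth table.

    The truth table has columns ``gene_id``, ``class`` (null / mean_de /
    std_de / zeroed), ``signed_lfc`` (log2 shift applied to strain 2; 0 for
    non-mean-DE genes) and ``inflated_strain`` (strain label whose
    dispersion was multiplied; empty otherwise). Bit-identical for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n1, n2 = spec.n_samples_1, spec.n_samples_2

    n_mean = int(round(spec.frac_mean_de * n))
    n_std = int(round(spec.frac_std_de * n))
    n_zero = int(round(spec.zero_gene_frac * n))
    perm = rng.permutation(n)
    idx_mean = perm[:n_mean]
    idx_std = perm[n_mean : n_mean + n_std]
    idx_zero = perm[n_mean + n_std : n_mean + n_std + n_zero]

    classes = np.full(n, CLASS_NULL, dtype=object)
    classes[idx_mean] = CLASS_MEAN_DE
    classes[idx_std] = CLASS_STD_DE
    classes[idx_zero] = CLASS_ZEROED

    base_log2 = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    mu1 = 2.0**base_log2
    mu2 = mu1.copy()
    signed_lfc = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_mean)
    signed_lfc[idx_mean] = signs * spec.mean_lfc
    mu2 = mu1 * 2.0 ** signed_lfc

    phi1 = np.full(n, spec.nb_dispersion)
    phi2 = np.full(n, spec.nb_dispersion)
    inflated = np.full(n, "", dtype=object)
    inflate_in_2 = rng.random(n_std) < 0.5
    phi2[idx_std[inflate_in_2]] *= spec.dispersion_ratio
    phi1[idx_std[~inflate_in_2]] *= spec.dispersion_ratio
    inflated[idx_std[inflate_in_2]] = STRAIN_2
    inflated[idx_std[~inflate_in_2]] = STRAIN_1

    counts1 = _nb_counts(rng, np.repeat(mu1[:, None], n1, axis=1), phi1[:, None])
    counts2 = _nb_counts(rng, np.repeat(mu2[:, None], n2, axis=1), phi2[:, None])
    values = np.hstack([counts1, counts2])

    # force a zero into each designated gene
    zero_cols = rng.integers(0, n1 + n2, size=n_zero)
    values[idx_zero, zero_cols] = 0.0

    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    sample_ids = [f"B6_{j + 1:02d}" for j in range(n1)] + [
        f"D2_{j + 1:02d}" for j in range(n2)
    ]
    X = ExpressionMatrix(gene_ids, sample_ids, values, scale="raw")
    design = StrainDesign(
        {s: STRAIN_1 for s in sample_ids[:n1]} | {s: STRAIN_2 for s in sample_ids[n1:]}
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "signed_lfc": signed_lfc,
            "inflated_strain": inflated,
        }
    )
    return X, design, truth


@dataclass
class TruthMetrics:
    sensitivity: float
    false_positive_rate: float
    per_class: pd.DataFrame  # columns: class, n, n_flagged


def truth_metrics(
    calls,
    truth: pd.DataFrame,
    surviving_genes: set[str] | None = None,
) -> TruthMetrics:
    """Sensitivity and FPR of a call set against the generator's truth.

    True-effect genes are the mean_de and std_de classes. When
    ``surviving_genes`` is given (the gene ids left after the zero filter),
    rates are computed among those genes only, since filtered genes were
    never candidates.
    """
    called = calls.gene_ids() if hasattr(calls, "gene_ids") else set(calls)
    universe = set(truth["gene_id"])
    unknown = called - universe
    if unknown:
        raise ValueError(f"calls contain gene ids absent from the truth table: {sorted(unknown)[:5]}")
    t = truth
    if surviving_genes is not None:
        t = truth[truth["gene_id"].isin(surviving_genes)]

    rows = []
    for cls, grp in t.groupby("class"):
        genes = set(grp["gene_id"])
        rows.append({"class": cls, "n": len(genes), "n_flagged": len(genes & called)})
    per_class = pd.DataFrame(rows, columns=["class", "n", "n_flagged"])

    true_effect = set(t.loc[t["class"].isin([CLASS_MEAN_DE, CLASS_STD_DE]), "gene_id"])
    nulls = set(t.loc[t["class"] == CLASS_NULL, "gene_id"])
    sensitivity = len(true_effect & called) / len(true_effect) if true_effect else float("nan")
    fpr = len(nulls & called) / len(nulls) if nulls else float("nan")
    return TruthMetrics(sensitivity=sensitivity, false_positive_rate=fpr, per_class=per_class)
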