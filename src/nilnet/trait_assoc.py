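"""Gene-trait association: normalized expression, genotype-class means,
Pearson correlation with the exact small-n t-based significance rule, and
UPGMA clustering for heatmap ordering.

With only 4 genotype classes the correlation significance rule is exact and
closed-form: r is significant at level alpha iff |r| exceeds

    r* = t* / sqrt(t*^2 + n - 2),   t* = two-sided t quantile, n - 2 df,

the inversion of t = r sqrt((n-2)/(1-r^2)).  At n = 4, alpha = 0.05 this
gives r* = 0.95 (to 4 decimal places), the study's working cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .data_io import CountMatrix, SampleDesign, TraitTable, GENOTYPE_CLASSES
from .de_stepwise import NormalizationFactors, tmm_factors


@dataclass
class ExpressionMatrix:
    """Gene x unit normalized log expression; units are samples or classes."""

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return ExpressionMatrix(list(gene_ids), list(self.unit_ids),
                                self.values[[idx[g] for g in gene_ids]])


def log_cpm(cm: CountMatrix, norm: NormalizationFactors | None = None,
            pseudo: float = 0.5, base: float = 2.0) -> ExpressionMatrix:
    """log CPM on TMM effective library sizes with a pseudo-count.

    ``base=2`` for analysis; natural log (``base=np.e``) matches the display
    scale commonly used for expression heatmaps.
    """
    if norm is None:
        norm = tmm_factors(cm)
    eff = norm.effective_library_sizes
    vals = np.log((cm.counts + pseudo) / eff[None, :] * 1e6) / np.log(base)
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), vals)


def genotype_means(expr: ExpressionMatrix, design: list[SampleDesign]) -> ExpressionMatrix:
    """Arithmetic mean within each genotype class, canonical class order."""
    by_sample = {d.sample_id: d.genotype_class for d in design}
    if set(expr.unit_ids) - set(by_sample):
        raise ValueError("expression matrix has samples absent from design")
    cols = []
    for cls in GENOTYPE_CLASSES:
        members = [i for i, s in enumerate(expr.unit_ids) if by_sample.get(s) == cls]
        if not members:
            raise ValueError(f"genotype class {cls} has no samples")
        cols.append(expr.values[:, members].mean(axis=1))
    return ExpressionMatrix(list(expr.gene_ids), list(GENOTYPE_CLASSES),
                            np.column_stack(cols))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Critical |Pearson r| for two-sided significance at level alpha with
    n paired observations (t distribution, n - 2 df)."""
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tstar = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(tstar / np.sqrt(tstar**2 + n - 2))


@dataclass
class CorrelationRecord:
    gene_id: str
    trait: str
    r: float
    t: float
    n: int
    alpha: float
    critical_r: float
    significant: bool


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, clamped to [-1, 1]; NaN if either vector is
    constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def correlate_genes_traits(expr_means: ExpressionMatrix, traits: TraitTable,
                           alpha: float = 0.05) -> list[CorrelationRecord]:
    """One record per (gene, trait) over the 4 genotype classes.

    A zero-variance gene or trait vector has undefined correlation; the record
    is flagged not-significant with r set to 0 and a warning is emitted.
    """
    if list(expr_means.unit_ids) != list(GENOTYPE_CLASSES):
        raise ValueError("expression means must be over the 4 genotype classes")
    n = len(GENOTYPE_CLASSES)
    rc = critical_r(n, alpha)
    records = []
    for gi, gene in enumerate(expr_means.gene_ids):
        x = expr_means.values[gi]
        for trait in traits.traits:
            y = traits.trait_vector(trait)
            r = pearson_r(x, y)
            if np.isnan(r):
                warnings.warn(f"zero-variance vector for ({gene}, {trait}); r undefined")
                records.append(CorrelationRecord(gene, trait, 0.0, 0.0, n, alpha, rc, False))
                continue
            t = np.inf * np.sign(r) if abs(r) >= 1 else r / np.sqrt((1 - r * r) / (n - 2))
            records.append(CorrelationRecord(
                gene, trait, r, float(t), n, alpha, rc, bool(abs(r) > rc)
            ))
    return records


@dataclass
class ClusterResult:
    merge_tree: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]


def hcluster(matrix: np.ndarray) -> ClusterResult:
    """UPGMA (average linkage on Euclidean distances) with the leaf order used
    for heatmap export."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite values in clustering input")
    Z = linkage(matrix, method="average", metric="euclidean")
    return ClusterResult(Z, [int(i) for i in leaves_list(Z)])
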