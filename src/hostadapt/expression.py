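"""Expression filtering, a two-group DE contrast and gene-class enrichment.

Counts are filtered on counts-per-million (CPM), differential expression
between two groups is assessed with a Welch t-test on log2(CPM + 0.5) with
Benjamini-Hochberg FDR control (a deliberately simple, documented contrast;
externally produced DE tables in the same column format are accepted
anywhere a DETable is), and over-representation of a labelled gene class
(e.g., cytochrome P450s) among DE genes is tested with binomial sampling —
or its Poisson large-universe limit when only the expected count is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DETable",
    "EnrichmentResult",
    "cpm",
    "cpm_filter",
    "de_contrast",
    "class_enrichment",
    "class_enrichment_from_expected",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with sample metadata."""

    counts: pd.DataFrame  # index: gene IDs, columns: sample IDs
    samples: pd.DataFrame | None = None  # index: sample IDs; e.g. line, host

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every library must have positive total count")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class DETable:
    """Per-gene differential-expression results at a fixed FDR."""

    table: pd.DataFrame  # columns: log2fc, p, p_adj, significant
    fdr: float


@dataclass
class EnrichmentResult:
    """Gene-class enrichment among DE genes."""

    class_name: str
    observed: int
    expected: float
    p: float
    tail: str


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per library."""
    return counts / counts.sum(axis=0) * 1e6


def cpm_filter(
    cm: CountMatrix, threshold: float = 0.5, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM > ``threshold`` in at least ``min_samples`` samples.

    Idempotent: refiltering the result removes nothing further (library
    sizes are taken from the filtered matrix, so this holds only
    approximately for aggressive thresholds; the default is mild).
    """
    keep = (cpm(cm.counts) > threshold).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("CPM filter removed every gene", stacklevel=2)
    return CountMatrix(counts=cm.counts.loc[keep], samples=cm.samples)


def de_contrast(
    cm: CountMatrix, groups: np.ndarray | pd.Series, fdr: float = 0.05
) -> DETable:
    """Two-group DE contrast: Welch t on log2(CPM + 0.5), BH correction.

    ``groups`` assigns each sample (column) to one of exactly two groups.
    log2 fold change is group2 minus group1 mean log2-CPM.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g1 = groups == labels[0]
    g2 = groups == labels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    log_cpm = np.log2(cpm(cm.counts).to_numpy() + 0.5)
    x1, x2 = log_cpm[:, g1], log_cpm[:, g2]
    t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    sig, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": x2.mean(axis=1) - x1.mean(axis=1),
            "p": p,
            "p_adj": p_adj,
            "significant": sig,
        },
        index=cm.counts.index,
    )
    return DETable(table=table, fdr=fdr)


def class_enrichment(
    de_genes: set | list,
    class_genes: set | list,
    universe: set | list,
    class_name: str = "",
) -> EnrichmentResult:
    """Binomial test for over/under-representation of a gene class among DE genes.

    With n = |DE|, p_class = |class| / |universe| and k = |DE ∩ class|, the
    expected count is lambda = n * p_class and the reported tail probability
    is Pr(X >= k) under Binomial(n, p_class) when k >= lambda, else
    Pr(X <= k).
    """
    universe = set(universe)
    de = set(de_genes) & universe
    cls = set(class_genes)
    if not cls <= universe:
        raise ValueError("class genes must be a subset of the universe")
    n = len(de)
    k = len(de & cls)
    if n == 0:
        return EnrichmentResult(class_name, 0, 0.0, 1.0, "upper")
    p_class = len(cls) / len(universe)
    lam = n * p_class
    if k >= lam:
        p = float(stats.binom.sf(k - 1, n, p_class))
        tail = "upper"
    else:
        p = float(stats.binom.cdf(k, n, p_class))
        tail = "lower"
    return EnrichmentResult(class_name, k, lam, min(p, 1.0), tail)


def class_enrichment_from_expected(k: int, lam: float) -> float:
    """Tail probability of observing ``k`` class genes given expectation ``lam``.

    Poisson large-universe limit of :func:`class_enrichment`, for use when
    only the observed and expected counts are known: Pr(X >= k) under
    Poisson(lam) when k >= lam, else Pr(X <= k).
    """
    if k < 0 or lam < 0:
        raise ValueError("k and lam must be non-negative")
    if k > 0 and lam == 0:
        raise ValueError("observed a positive count with zero expectation")
    if k >= lam:
        return float(stats.poisson.sf(k - 1, lam))
    return float(stats.poisson.cdf(k, lam))
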