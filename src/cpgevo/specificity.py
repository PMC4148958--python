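"""Tissue specificity score (TSPS).

TSPS is the relative entropy of a gene's expression fractions across n
tissues against the uniform distribution p_i = 1/n:

    TSPS = sum_i f_i * log2(f_i / p_i),    f_i = x_i / sum_j x_j

computed on linear-scale expression. TSPS = 0 means perfectly uniform
expression (housekeeping-like); the maximum, log2(n), is reached when a
gene is expressed in a single tissue. Terms with f_i = 0 contribute 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HOUSEKEEPING_CUTOFF = 0.25
SPECIFIC_CUTOFF = 2.0


def tsps(expression: np.ndarray) -> float:
    """TSPS of one gene's linear expression vector; NaN when total is 0."""
    x = np.asarray(expression, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    total = x.sum()
    if total == 0 or not np.isfinite(total):
        return math.nan
    f = x / total
    nz = f > 0
    return float(np.sum(f[nz] * np.log2(f[nz] * x.size)))


def tsps_table(expr: pd.DataFrame) -> pd.Series:
    """Per-gene TSPS for a genes x tissues linear expression table."""
    x = expr.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = x / totals[:, None]
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) * n), 0.0)
    scores = terms.sum(axis=1)
    scores[totals == 0] = np.nan
    return pd.Series(scores, index=expr.index, name="tsps")


@dataclass
class TSPSComparison:
    """HCP-vs-LCP contrast of tissue specificity."""

    mean_hcp: float
    mean_lcp: float
    p_value: float  # two-sided Wilcoxon rank-sum; NaN if a class has < 2 genes
    frac_housekeeping_hcp: float  # TSPS < 0.25
    frac_housekeeping_lcp: float
    frac_specific_hcp: float  # TSPS > 2
    frac_specific_lcp: float
    n_hcp: int
    n_lcp: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Tissue specificity by promoter class",
                "=" * 44,
                f"{'':<24}{'HCP':>10}{'LCP':>10}",
                f"{'n genes':<24}{self.n_hcp:>10}{self.n_lcp:>10}",
                f"{'mean TSPS':<24}{self.mean_hcp:>10.3f}{self.mean_lcp:>10.3f}",
                f"{'frac TSPS < 0.25':<24}{self.frac_housekeeping_hcp:>10.3f}{self.frac_housekeeping_lcp:>10.3f}",
                f"{'frac TSPS > 2':<24}{self.frac_specific_hcp:>10.3f}{self.frac_specific_lcp:>10.3f}",
                f"Wilcoxon rank-sum p = {self.p_value:.3g}",
            ]
        )


def compare_tsps_by_class(scores: pd.Series, labels: pd.Series) -> TSPSComparison:
    """Compare TSPS distributions of HCP and LCP genes.

    Reports class means, the fractions below the housekeeping cutoff
    (0.25) and above the tissue-specific cutoff (2), and a two-sided
    Wilcoxon rank-sum p-value.
    """
    labels = labels.reindex(scores.index)
    hcp = scores[(labels == "HCP") & scores.notna()].to_numpy()
    lcp = scores[(labels == "LCP") & scores.notna()].to_numpy()
    if hcp.size == 0 or lcp.size == 0:
        raise ValueError("both classes must be non-empty")
    if hcp.size >= 2 and lcp.size >= 2:
        p = float(stats.ranksums(hcp, lcp).pvalue)
    else:
        p = math.nan
    return TSPSComparison(
        mean_hcp=float(hcp.mean()),
        mean_lcp=float(lcp.mean()),
        p_value=p,
        frac_housekeeping_hcp=float((hcp < HOUSEKEEPING_CUTOFF).mean()),
        frac_housekeeping_lcp=float((lcp < HOUSEKEEPING_CUTOFF).mean()),
        frac_specific_hcp=float((hcp > SPECIFIC_CUTOFF).mean()),
        frac_specific_lcp=float((lcp > SPECIFIC_CUTOFF).mean()),
        n_hcp=int(hcp.size),
        n_lcp=int(lcp.size),
    )
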