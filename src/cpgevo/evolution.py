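"""Cross-species comparisons of nCpG content and gene expression.

Covers: Spearman correlations with Fisher-z significance, conservation
of nCpG across ortholog pairs (and the TSS/TTS conservation contrast),
conservation of the HCP/LCP category with a chi-square test, the sliding
window trend of expression divergence against nCpG divergence (dCpG),
and the dCpG contrast between differentially expressed gene groups.

dCpG is always organism A minus organism B, and expression divergence is
log2(expression_A / expression_B), so a positive association means gains
in CpG content accompany up-regulation in A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW_SIZE = 400
DEFAULT_FOLD_THRESHOLD = 2.0
_MIN_P = 5e-324  # smallest subnormal double; underflow-safe floor


@dataclass
class CorrelationResult:
    """Spearman correlation with optional Fisher-z significance."""

    r: float
    n: int
    z: float | None = None
    p: float | None = None
    p_flagged: bool = False  # True when |r|=1 forced the underflow floor

    def with_significance(self) -> "CorrelationResult":
        z, p, flagged = fisher_z_pvalue(self.r, self.n, _return_flag=True)
        return CorrelationResult(self.r, self.n, z, p, flagged)


def spearman_correlation(x, y) -> CorrelationResult:
    """Rank correlation (average ranks for ties) over pairwise-complete values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise ValueError(f"need at least 4 paired values, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, n)
    r = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(r, n)


def fisher_z_pvalue(r: float, n: int, _return_flag: bool = False):
    """Fisher-z significance of a correlation: z = arctanh(r) * sqrt(n-3).

    The two-sided p comes from the standard normal. |r| = 1 cannot be
    transformed; it is reported as the smallest positive double and
    flagged.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher z test")
    if abs(r) >= 1.0:
        z = math.copysign(math.inf, r)
        return (z, _MIN_P, True) if _return_flag else (z, _MIN_P)
    z = math.atanh(r) * math.sqrt(n - 3)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, _MIN_P)
    return (z, p, False) if _return_flag else (z, p)


# ---------------------------------------------------------------------------
# Conservation of nCpG across orthologs


def align_orthologs(
    table_a: pd.Series,
    table_b: pd.Series,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-gene values of two organisms on an ortholog pair list.

    ``pairs`` needs columns ``gene_a`` and ``gene_b``. Pairs with a
    missing value on either side are dropped.
    """
    out = pd.DataFrame(
        {
            "gene_a": pairs["gene_a"].to_numpy(),
            "gene_b": pairs["gene_b"].to_numpy(),
            "value_a": pairs["gene_a"].map(table_a).to_numpy(),
            "value_b": pairs["gene_b"].map(table_b).to_numpy(),
        }
    )
    return out.dropna(subset=["value_a", "value_b"]).reset_index(drop=True)


def pairwise_ncpg_conservation(
    ncpg_a: pd.Series,
    ncpg_b: pd.Series,
    pairs: pd.DataFrame,
) -> CorrelationResult:
    """Cross-organism Spearman correlation of nCpG over ortholog pairs."""
    aligned = align_orthologs(ncpg_a, ncpg_b, pairs)
    return spearman_correlation(aligned["value_a"], aligned["value_b"]).with_significance()


def tss_tts_conservation_ratio(r_tss: float, r_tts: float) -> float:
    """log2(r_tss / r_tts); NaN (flagged by the caller) when r_tts <= 0."""
    if r_tts <= 0 or r_tss <= 0 or not (np.isfinite(r_tss) and np.isfinite(r_tts)):
        return math.nan
    return float(np.log2(r_tss / r_tts))


# ---------------------------------------------------------------------------
# Conservation of the HCP/LCP category


@dataclass
class ConservationTable:
    """2x2 table of promoter classes across an ortholog pair list."""

    hh: int
    hl: int
    lh: int
    ll: int

    @property
    def total(self) -> int:
        return self.hh + self.hl + self.lh + self.ll

    @property
    def conserved_fraction(self) -> float:
        return (self.hh + self.ll) / self.total


@dataclass
class ClassConservationResult:
    table: ConservationTable
    conserved_fraction: float
    chi2: float
    p_value: float
    p_reliable: bool  # False when an expected cell count is < 1

    def summary(self) -> str:
        t = self.table
        return "\n".join(
            [
                "HCP/LCP category conservation",
                "=" * 44,
                f"{'':<6}{'B=HCP':>8}{'B=LCP':>8}",
                f"{'A=HCP':<6}{t.hh:>8}{t.hl:>8}",
                f"{'A=LCP':<6}{t.lh:>8}{t.ll:>8}",
                f"conserved fraction  {self.conserved_fraction:.4f}",
                f"chi2 = {self.chi2:.2f}, p = {self.p_value:.3g}"
                + ("" if self.p_reliable else " (unreliable: expected cell < 1)"),
            ]
        )


def conservation_table(labels_a, labels_b) -> ConservationTable:
    """Cross-tabulate aligned HCP/LCP labels of ortholog pairs."""
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    ok = np.isin(a, ("HCP", "LCP")) & np.isin(b, ("HCP", "LCP"))
    a, b = a[ok], b[ok]
    return ConservationTable(
        hh=int(np.sum((a == "HCP") & (b == "HCP"))),
        hl=int(np.sum((a == "HCP") & (b == "LCP"))),
        lh=int(np.sum((a == "LCP") & (b == "HCP"))),
        ll=int(np.sum((a == "LCP") & (b == "LCP"))),
    )


def class_conservation(
    labels_a,
    labels_b=None,
    yates: bool = False,
) -> ClassConservationResult:
    """Conserved fraction and chi-square independence test for a 2x2 class table.

    ``labels_a``/``labels_b`` are the aligned HCP/LCP labels of ortholog
    pairs (conventionally restricted to genes with a single TSS in both
    organisms, so a gene's class is unambiguous); alternatively pass a
    prebuilt :class:`ConservationTable` as the only argument. The
    chi-square test uses 1 df and, by default, no continuity correction.
    """
    if isinstance(labels_a, ConservationTable):
        table = labels_a
    else:
        if labels_b is None:
            raise ValueError("labels_b required unless a ConservationTable is given")
        table = conservation_table(labels_a, labels_b)
    if table.total == 0:
        raise ValueError("no ortholog pairs with labels in both organisms")
    observed = np.array([[table.hh, table.hl], [table.lh, table.ll]], dtype=float)
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        chi2, p, expected = 0.0, 1.0, observed
    else:
        chi2, p, _, expected = stats.chi2_contingency(observed, correction=yates)
    return ClassConservationResult(
        table=table,
        conserved_fraction=table.conserved_fraction,
        chi2=float(chi2),
        p_value=float(p),
        p_reliable=bool((expected >= 1).all()),
    )


# ---------------------------------------------------------------------------
# Expression divergence versus nCpG divergence


def ortholog_comparisons(
    ncpg_tss_a: pd.Series,
    ncpg_tss_b: pd.Series,
    ncpg_tts_a: pd.Series,
    ncpg_tts_b: pd.Series,
    log2_expr_a: pd.DataFrame,
    log2_expr_b: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Per ortholog pair: dCpG at TSS and TTS plus per-tissue log2 expression ratios.

    Expression tables are genes x tissues log2 values with shared tissue
    columns; ratios are log2_expr_A - log2_expr_B per tissue. Pairs missing
    nCpG on either side are dropped; missing expression propagates as NaN
    per tissue (excluded pairwise by downstream analyses).
    """
    shared = [t for t in log2_expr_a.columns if t in log2_expr_b.columns]
    if not shared:
        raise ValueError("expression tables share no tissue columns")
    ga, gb = pairs["gene_a"], pairs["gene_b"]
    out = pd.DataFrame(
        {
            "gene_a": ga.to_numpy(),
            "gene_b": gb.to_numpy(),
            "dcpg_tss": ga.map(ncpg_tss_a).to_numpy() - gb.map(ncpg_tss_b).to_numpy(),
            "dcpg_tts": ga.map(ncpg_tts_a).to_numpy() - gb.map(ncpg_tts_b).to_numpy(),
        }
    )
    for t in shared:
        out[f"log2_ratio_{t}"] = (
            ga.map(log2_expr_a[t]).to_numpy() - gb.map(log2_expr_b[t]).to_numpy()
        )
    return out


def dcpg_sliding_trend(
    dcpg,
    log2_ratio,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = 1,
) -> pd.DataFrame:
    """Sliding-window trend of expression divergence along sorted dCpG.

    Pairs are sorted by increasing dCpG; each window of ``window_size``
    consecutive pairs (advanced by ``step``) contributes the arithmetic
    means of its dCpG and its log2 expression ratio.
    """
    dcpg = np.asarray(dcpg, dtype=float)
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    ok = np.isfinite(dcpg) & np.isfinite(log2_ratio)
    dcpg, log2_ratio = dcpg[ok], log2_ratio[ok]
    n = dcpg.size
    if n < window_size:
        raise ValueError(
            f"only {n} usable pairs but window_size={window_size}; use a smaller window"
        )
    order = np.argsort(dcpg, kind="stable")
    d, e = dcpg[order], log2_ratio[order]
    # O(n) window means via cumulative sums
    cd = np.concatenate([[0.0], np.cumsum(d)])
    ce = np.concatenate([[0.0], np.cumsum(e)])
    starts = np.arange(0, n - window_size + 1, step)
    return pd.DataFrame(
        {
            "mean_dcpg": (cd[starts + window_size] - cd[starts]) / window_size,
            "mean_log2_ratio": (ce[starts + window_size] - ce[starts]) / window_size,
        }
    )


def trend_slope(trend: pd.DataFrame) -> float:
    """OLS slope of mean log2 ratio on mean dCpG over the sliding windows."""
    return float(np.polyfit(trend["mean_dcpg"], trend["mean_log2_ratio"], 1)[0])


@dataclass
class DiffExpressionDCpG:
    """dCpG contrast between up- and down-regulated ortholog pairs."""

    n_up: int
    n_down: int
    mean_dcpg_tss_up: float
    mean_dcpg_tss_down: float
    mean_dcpg_tts_up: float
    mean_dcpg_tts_down: float
    p_tss: float
    p_tts: float


def diff_expression_dcpg(
    comparisons: pd.DataFrame,
    tissue: str,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> DiffExpressionDCpG:
    """Compare dCpG between differentially expressed gene groups.

    Pairs with |log2 ratio| >= log2(fold_threshold) in ``tissue`` form the
    up (A-high) and down (A-low) groups; reports each group's mean dCpG at
    TSS and TTS and two-sided rank-sum p-values for the contrasts.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    ratio = comparisons[f"log2_ratio_{tissue}"]
    cut = math.log2(fold_threshold)
    up = comparisons[ratio >= cut]
    down = comparisons[ratio <= -cut]

    def _p(col: str) -> float:
        a = up[col].dropna().to_numpy()
        b = down[col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            return math.nan
        return float(stats.ranksums(a, b).pvalue)

    return DiffExpressionDCpG(
        n_up=int(len(up)),
        n_down=int(len(down)),
        mean_dcpg_tss_up=float(up["dcpg_tss"].mean()),
        mean_dcpg_tss_down=float(down["dcpg_tss"].mean()),
        mean_dcpg_tts_up=float(up["dcpg_tts"].mean()),
        mean_dcpg_tts_down=float(down["dcpg_tts"].mean()),
        p_tss=_p("dcpg_tss"),
        p_tts=_p("dcpg_tts"),
    )
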