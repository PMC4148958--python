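"""Loading RPKM expression tables and replicate handling.

Expression levels are RPKM per gene per sample; samples map to tissues
via a sidecar configuration (sample id -> tissue label). Replicates of a
tissue are combined by averaging at the log scale: the final level is the
mean of log2(RPKM + pseudocount) over replicates. A gene counts as
expressed in a tissue when at least one replicate has raw RPKM > 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.01


def average_replicates_log2(values: Sequence[float], pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Mean over replicates of log2(RPKM + pseudocount); NaNs dropped."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    if (arr < 0).any():
        raise ValueError("negative RPKM value")
    return float(np.mean(np.log2(arr + pseudocount)))


@dataclass
class ExpressionMatrix:
    """Genes x tissues log2-RPKM matrix with replicate provenance.

    ``log2_rpkm``: DataFrame (genes x tissues), replicate-averaged on the
    log scale. ``n_replicates``: matching DataFrame of non-missing
    replicate counts. ``raw``: the original genes x samples RPKM table.
    ``sample_tissues``: sample id -> tissue label.
    """

    log2_rpkm: pd.DataFrame
    n_replicates: pd.DataFrame
    raw: pd.DataFrame
    sample_tissues: dict[str, str]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2_rpkm.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.log2_rpkm.columns)

    def tissue_means_linear(self) -> pd.DataFrame:
        """Mean raw RPKM per tissue (linear scale, for specificity scores)."""
        groups = pd.Series(self.sample_tissues)
        return self.raw.T.groupby(groups).mean().T[self.tissue_ids]

    def expressed_mask(self, tissue: str) -> pd.Series:
        """True for genes with RPKM > 0 in at least one replicate of ``tissue``."""
        if tissue not in self.tissue_ids:
            raise KeyError(f"tissue {tissue!r} not in matrix")
        samples = [s for s, t in self.sample_tissues.items() if t == tissue]
        return (self.raw[samples] > 0).any(axis=1)


def build_expression_matrix(
    raw: pd.DataFrame,
    sample_tissues: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from a raw genes x samples table."""
    if raw.index.duplicated().any():
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids: {dups}")
    missing = [s for s in raw.columns if s not in sample_tissues]
    if missing:
        raise ValueError(f"samples without a tissue mapping: {missing}")
    if (raw < 0).any().any():
        raise ValueError("negative RPKM values in expression table")
    groups = pd.Series({s: sample_tissues[s] for s in raw.columns})
    with np.errstate(divide="ignore"):  # pseudocount 0 + RPKM 0 -> -inf is intended
        log2 = np.log2(raw + pseudocount)
    log2_rpkm = log2.T.groupby(groups).mean().T
    n_replicates = raw.notna().T.groupby(groups).sum().T.astype(int)
    tissues = list(dict.fromkeys(groups))  # preserve sample order
    return ExpressionMatrix(
        log2_rpkm=log2_rpkm[tissues],
        n_replicates=n_replicates[tissues],
        raw=raw,
        sample_tissues=dict(sample_tissues),
        pseudocount=pseudocount,
    )


def load_expression(
    tsv_path: str | Path,
    sample_map: str | Path | Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionMatrix:
    """Load a TSV of RPKM (gene rows, sample columns) plus its sample->tissue map.

    ``sample_map`` is either a mapping or the path of a JSON file holding
    one. Missing cells stay missing — they are never zero-filled.
    """
    raw = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if not isinstance(sample_map, Mapping):
        with open(sample_map) as fh:
            sample_map = json.load(fh)
    return build_expression_matrix(raw, sample_map, pseudocount)
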