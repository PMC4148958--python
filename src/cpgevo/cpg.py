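"""Normalized CpG content (nCpG).

nCpG is the ratio of the observed CpG dinucleotide count in a window to
the count expected from its GC composition, with the expected per-position
CpG rate taken as (GC/2)^2:

    nCpG = observed_CpG / (L * (GC/2)^2)

where L is the number of unambiguous bases in the window. For an iid
sequence with equal C and G fractions the expectation is 1; vertebrate
genomes sit far below 1 because methylated CpG deaminates to TpG, and
CpG-island promoters stand out as a high-nCpG mode.

Expected counts use L positions rather than L-1 dinucleotide starts; at
the default 3 kb window the difference is 0.03% and the convention keeps
nCpG("CG" * k) = 2 exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .windows import SequenceWindow

logger = logging.getLogger(__name__)

MIN_EFFECTIVE_LENGTH = 500

Reason = Literal["ok", "too_short", "zero_gc"]


@dataclass(frozen=True)
class NCpGRecord:
    """Per-window CpG statistics for one transcript site."""

    transcript_id: str
    site_type: str
    observed_cpg: int
    gc_fraction: float  # NaN when no unambiguous bases
    effective_length: int
    ncpg: float  # NaN when undefined
    reason: Reason = "ok"


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotides (positions i with C at i, G at i+1).

    CG cannot overlap itself, so a plain substring count is exact; any
    dinucleotide containing an ambiguous base simply never matches.
    """
    return sequence.upper().count("CG")


def gc_fraction(sequence: str) -> tuple[float, int]:
    """GC fraction over unambiguous bases and the unambiguous-base count."""
    s = sequence.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    effective_length = a + c + g + t
    if effective_length == 0:
        return math.nan, 0
    return (c + g) / effective_length, effective_length


def ncpg(
    sequence: str,
    transcript_id: str = "",
    site_type: str = "TSS",
    min_length: int = MIN_EFFECTIVE_LENGTH,
) -> NCpGRecord:
    """Normalized CpG content of one window.

    Returns NaN (with a reason code) when the window has fewer than
    ``min_length`` unambiguous bases, or when GC is zero — observed is
    then necessarily zero too and 0/0 has no defined limit.
    """
    obs = count_cpg(sequence)
    gc, eff_len = gc_fraction(sequence)
    if eff_len < min_length:
        return NCpGRecord(transcript_id, site_type, obs, gc, eff_len, math.nan, "too_short")
    if gc == 0.0:
        return NCpGRecord(transcript_id, site_type, obs, gc, eff_len, math.nan, "zero_gc")
    value = obs / (eff_len * (gc / 2.0) ** 2)
    return NCpGRecord(transcript_id, site_type, obs, gc, eff_len, value, "ok")


def ncpg_value(sequence: str, min_length: int = MIN_EFFECTIVE_LENGTH) -> float:
    """Shorthand: just the nCpG number (NaN when undefined)."""
    return ncpg(sequence, min_length=min_length).ncpg


def records_from_windows(
    windows: Iterable[SequenceWindow], min_length: int = MIN_EFFECTIVE_LENGTH
) -> pd.DataFrame:
    """Score a batch of windows; one row per window."""
    rows = []
    for w in windows:
        rec = ncpg(w.sequence, w.transcript_id, w.site_type, min_length=min_length)
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "site_type": rec.site_type,
                "observed_cpg": rec.observed_cpg,
                "gc_fraction": rec.gc_fraction,
                "effective_length": rec.effective_length,
                "ncpg": rec.ncpg,
                "reason": rec.reason,
                "complete": w.complete,
            }
        )
    return pd.DataFrame(rows)


def aggregate_gene_ncpg(
    records: pd.DataFrame,
    transcript_to_gene: pd.Series | dict[str, str],
    mode: str = "mean",
) -> pd.DataFrame:
    """Aggregate transcript-level nCpG to genes, per site type.

    Genes with several annotated transcripts get the mean (default) or the
    maximum of their non-missing transcript values; both are reported. Genes
    whose transcripts are all missing are omitted (and logged).

    Parameters
    ----------
    records : output of :func:`records_from_windows` (needs columns
        transcript_id, site_type, ncpg).
    transcript_to_gene : mapping transcript_id -> gene_id.
    mode : 'mean' or 'max'; selects which aggregate fills the ``ncpg``
        convenience column.
    """
    if mode not in ("mean", "max"):
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    df = records.copy()
    t2g = pd.Series(transcript_to_gene) if isinstance(transcript_to_gene, dict) else transcript_to_gene
    df["gene_id"] = df["transcript_id"].map(t2g)
    n_all = df.groupby(["gene_id", "site_type"], sort=True).size()
    df = df.dropna(subset=["ncpg"])
    grouped = df.groupby(["gene_id", "site_type"], sort=True)["ncpg"]
    out = grouped.agg(ncpg_mean="mean", ncpg_max="max", n_transcripts="size").reset_index()
    n_dropped = len(n_all) - len(out)
    if n_dropped:
        logger.info("omitted %d gene/site groups with no usable transcript nCpG", n_dropped)
    out["ncpg"] = out["ncpg_mean"] if mode == "mean" else out["ncpg_max"]
    return out
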