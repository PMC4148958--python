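"""Extraction of fixed-width sequence windows around TSS and TTS.

Coordinates are 0-based half-open internally. GTF input is 1-based
inclusive; the transcription start site (TSS) is the 5' end of the
transcript in transcription direction and the transcription termination
site (TTS) is the 3' end, so on the minus strand TSS > TTS.

Windows are taken on the forward strand only: every downstream quantity
(CpG count, GC fraction, normalized CpG) is invariant under reverse
complement because CG is its own reverse complement, so reverse
complementing minus-strand windows would be wasted work.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 1500

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript: ids, chromosome, strand and its TSS/TTS positions."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based
    tts: int  # 0-based

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.tss < 0 or self.tts < 0:
            raise ValueError("negative coordinate")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError("plus-strand transcript with tss > tts")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError("minus-strand transcript with tss < tts")


@dataclass(frozen=True)
class SequenceWindow:
    """A forward-strand window centered on a TSS or TTS."""

    site_type: str  # 'TSS' or 'TTS'
    transcript_id: str
    chrom: str
    start: int  # 0-based, clipped
    end: int  # half-open, clipped
    sequence: str
    complete: bool  # False when clipped at a chromosome edge or empty

    def __len__(self) -> int:
        return len(self.sequence)


def parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_annotation(path: str | Path, feature: str = "transcript") -> tuple[list[TranscriptAnnotation], int]:
    """Parse a GTF-like file into transcript annotations.

    Returns ``(annotations, n_rejected)``. Records missing a strand,
    gene_id or transcript_id are rejected with a logged warning rather
    than aborting the whole parse.
    """
    annotations: list[TranscriptAnnotation] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attributes = parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            transcript_id = attributes.get("transcript_id")
            if strand not in ("+", "-") or not gene_id or not transcript_id:
                logger.warning(
                    "rejecting %s line %d: missing strand/gene_id/transcript_id",
                    path, lineno,
                )
                n_rejected += 1
                continue
            start0, end0 = int(start) - 1, int(end) - 1  # 1-based incl -> 0-based
            if strand == "+":
                tss, tts = start0, end0
            else:
                tss, tts = end0, start0
            annotations.append(
                TranscriptAnnotation(transcript_id, gene_id, chrom, strand, tss, tts)
            )
    return annotations, n_rejected


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an uppercase in-memory dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_window(
    genome: Mapping[str, str],
    chrom: str,
    center: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    site_type: str = "TSS",
    transcript_id: str = "",
) -> SequenceWindow:
    """Extract the forward-strand window [center-half_width, center+half_width).

    ``genome`` may be any mapping from chromosome name to a sliceable
    sequence (a plain dict of strings or a ``pyfaidx.Fasta``). Windows
    clipped at a chromosome edge — or centered outside the chromosome —
    are returned flagged ``complete=False`` rather than dropped.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from None
    chrom_len = len(seq)
    if center < 0 or center >= chrom_len:
        return SequenceWindow(site_type, transcript_id, chrom, 0, 0, "", False)
    start = max(0, center - half_width)
    end = min(chrom_len, center + half_width)
    subseq = str(seq[start:end]).upper()
    complete = (end - start) == 2 * half_width
    return SequenceWindow(site_type, transcript_id, chrom, start, end, subseq, complete)


def windows_for_transcripts(
    genome: Mapping[str, str],
    annotations: Iterable[TranscriptAnnotation],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[SequenceWindow]:
    """TSS and TTS windows for every transcript, in annotation order."""
    out: list[SequenceWindow] = []
    for ann in annotations:
        out.append(extract_window(genome, ann.chrom, ann.tss, half_width, "TSS", ann.transcript_id))
        out.append(extract_window(genome, ann.chrom, ann.tts, half_width, "TTS", ann.transcript_id))
    return out


def windows_manifest(windows: Iterable[SequenceWindow]) -> pd.DataFrame:
    """TSV-ready manifest of extracted windows."""
    return pd.DataFrame(
        [
            {
                "transcript_id": w.transcript_id,
                "site_type": w.site_type,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "complete": w.complete,
            }
            for w in windows
        ]
    )


def write_windows_fasta(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.transcript_id}|{w.site_type}|{w.chrom}:{w.start}-{w.end}\n")
            for i in range(0, len(w.sequence), 80):
                fh.write(w.sequence[i : i + 80] + "\n")
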