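"""Transcript gene models: sequences, CDS boundaries, regulatory regions.

Transcripts are mature mRNA sequences (5'->3') over the RNA alphabet with a
single CDS given in 0-based half-open coordinates; the 5'UTR, CDS and 3'UTR
partition the sequence.  When a gene has several isoforms the longest one
represents the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA = frozenset("ACGU")


class RegionKind(str, Enum):
    """A regulatory region of a transcript."""

    FIVE_PRIME_UTR = "five_prime_utr"
    CDS = "cds"
    THREE_PRIME_UTR = "three_prime_utr"
    WHOLE_TRANSCRIPT = "whole_transcript"


@dataclass(frozen=True)
class TranscriptRecord:
    """A mature mRNA with CDS boundaries.

    ``cds_start``/``cds_end`` are 0-based half-open indices into ``sequence``;
    the 5'UTR is ``[0, cds_start)``, the CDS ``[cds_start, cds_end)`` and the
    3'UTR ``[cds_end, len)``.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"invalid for sequence of length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _RNA - {"N"}
        if bad:
            raise ValueError(
                f"{self.transcript_id}: unnormalized characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_alphabet(raw_sequence: str) -> str:
    """Uppercase, map T->U, and map anything outside {A,C,G,U} to N.

    N never matches any motif position, so unknown characters are inert
    rather than fatal.
    """
    if not raw_sequence:
        raise ValueError("empty sequence")
    s = raw_sequence.upper().replace("T", "U")
    return "".join(c if c in _RNA else "N" for c in s)


def read_transcripts(fasta_source, annotation_source) -> list[TranscriptRecord]:
    """Read FASTA sequences plus a CDS annotation table into records.

    The annotation is a TSV with columns transcript_id, gene_id, cds_start,
    cds_end (0-based half-open).  FASTA entries without an annotation row are
    skipped with a warning; annotation rows without a sequence raise.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        tid = rec.id.split()[0]
        if tid in sequences:
            raise ValueError(f"duplicate transcript_id in FASTA: {tid}")
        sequences[tid] = normalize_alphabet(str(rec.seq))

    annot = pd.read_csv(annotation_source, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    if annot["transcript_id"].duplicated().any():
        dups = annot.loc[annot["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValueError(f"duplicate transcript_id in annotation: {dups}")

    records = []
    for row in annot.itertuples(index=False):
        if row.transcript_id not in sequences:
            raise KeyError(f"annotation references unknown transcript {row.transcript_id}")
        seq = sequences[row.transcript_id]
        if row.cds_end > len(seq):
            raise ValueError(
                f"{row.transcript_id}: cds_end={row.cds_end} exceeds sequence "
                f"length {len(seq)}"
            )
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence=seq,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )

    unannotated = set(sequences) - set(annot["transcript_id"])
    for tid in sorted(unannotated):
        logger.warning("transcript %s has no annotation; skipped", tid)
    return records


def select_longest_isoform(records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep, per gene, the longest isoform (ties: smallest transcript_id)."""
    best: dict[str, TranscriptRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or len(rec) > len(cur)
            or (len(rec) == len(cur) and rec.transcript_id < cur.transcript_id)
        ):
            best[rec.gene_id] = rec
    return [best[g] for g in sorted(best)]


def extract_region(record: TranscriptRecord, kind: RegionKind) -> tuple[int, str]:
    """Return (offset within transcript, subsequence) for a region.

    Empty regions come back as an empty string with the correct offset.
    """
    kind = RegionKind(kind)
    if kind is RegionKind.FIVE_PRIME_UTR:
        start, end = 0, record.cds_start
    elif kind is RegionKind.CDS:
        start, end = record.cds_start, record.cds_end
    elif kind is RegionKind.THREE_PRIME_UTR:
        start, end = record.cds_end, len(record)
    else:
        start, end = 0, len(record)
    return start, record.sequence[start:end]
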