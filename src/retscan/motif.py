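"""IUPAC motif scanning and accessibility-weighted region scoring.

A motif is a degenerate IUPAC RNA pattern (e.g. the SRSF1 site KGRWGSM,
K=G/U, R=G/A, W=A/U, S=G/C, M=A/C).  A target site is a perfect match of the
pattern at some offset; the site's score is the mean accessibility of its
bases, and a region's motif score is the sum over all (possibly overlapping)
sites, zero when the region has no match.

The per-motif feature table pairs the motif score with control features —
overlapping counts of every dinucleotide contained in the motif, plus the
region length — over the positive and negative transcript sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accessibility import AccessibilityTrack, site_accessibility
from .gene_models import RegionKind, TranscriptRecord, extract_region

logger = logging.getLogger(__name__)

# IUPAC RNA ambiguity codes -> concrete bases
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}


@dataclass(frozen=True)
class IUPACMotif:
    motif_id: str
    rbp_name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError(f"{self.motif_id}: pattern must be >= 2 nt")
        bad = [c for c in self.pattern if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"{self.motif_id}: invalid IUPAC codes {bad}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    region: RegionKind
    start: int  # transcript coordinates, 0-based
    end: int  # exclusive
    kmer: str
    site_accessibility: float = float("nan")


@dataclass
class FeatureTable:
    """Per-transcript features (rows) vs class label for one motif.

    Columns: ``motif_score``, one raw overlapping count per control
    dinucleotide, and ``region_length`` in nt.  ``labels`` is 1 for the
    positive set, 0 for the negative set.  Features are stored raw;
    standardization happens inside the penalized fit.
    """

    motif_id: str
    region: RegionKind
    features: pd.DataFrame
    labels: pd.Series
    warnings: list = field(default_factory=list)


def expand_motif(motif: IUPACMotif | str) -> set[str]:
    """All concrete k-mers matching the pattern (Cartesian product)."""
    pattern = motif.pattern if isinstance(motif, IUPACMotif) else motif
    choices = []
    for c in pattern:
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {c!r}")
        choices.append(IUPAC_CODES[c])
    return {"".join(kmer) for kmer in itertools.product(*choices)}


def motif_dinucleotides(motif: IUPACMotif | str) -> list[str]:
    """All dinucleotides contained in the motif, lexicographically sorted.

    Union over every adjacent two-code window of its expansion.
    """
    pattern = motif.pattern if isinstance(motif, IUPACMotif) else motif
    dinucs: set[str] = set()
    for i in range(len(pattern) - 1):
        dinucs |= expand_motif(pattern[i : i + 2])
    return sorted(dinucs)


def scan_region(
    sequence: str,
    region_offset: int,
    motif: IUPACMotif,
    transcript_id: str = "",
    region: RegionKind = RegionKind.WHOLE_TRANSCRIPT,
) -> list[MotifHit]:
    """All perfect-match sites of the motif in a region.

    ``sequence`` is the (normalized) region subsequence and ``region_offset``
    its start within the transcript; hit coordinates are reported in
    transcript coordinates.  Overlapping hits are all reported.  N in the
    sequence matches no motif position.
    """
    k = len(motif.pattern)
    allowed = [frozenset(IUPAC_CODES[c]) for c in motif.pattern]
    hits = []
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if all(base in ok for base, ok in zip(window, allowed)):
            hits.append(
                MotifHit(
                    transcript_id=transcript_id,
                    region=region,
                    start=region_offset + i,
                    end=region_offset + i + k,
                    kmer=window,
                )
            )
    return hits


def region_score(hits: list[MotifHit], track: AccessibilityTrack) -> float:
    """Sum of site accessibilities over all hits; 0 for no hits."""
    total = 0.0
    for hit in hits:
        if hit.end > len(track):
            raise ValueError(
                f"hit [{hit.start}, {hit.end}) outside track of length {len(track)}"
            )
        total += site_accessibility(track, hit.start, hit.end)
    return total


def count_overlapping(sequence: str, word: str) -> int:
    """Occurrences of ``word`` in ``sequence``, overlaps allowed."""
    n, k = len(sequence), len(word)
    return sum(1 for i in range(n - k + 1) if sequence[i : i + k] == word)


def build_feature_table(
    partition,
    records: dict[str, TranscriptRecord],
    region: RegionKind,
    motif: IUPACMotif,
    track_provider,
) -> FeatureTable:
    """Assemble the motif-vs-control feature table over a gene-set partition.

    ``track_provider`` is a callable ``(transcript_id, length) -> track``.
    Control dinucleotide features are raw overlapping counts in the region
    (not accessibility-weighted); region_length is the region size in nt.
    Transcripts with an empty region keep all-zero features, with a warning.
    """
    region = RegionKind(region)
    ids = list(partition.positive_ids) + list(partition.negative_ids)
    missing = [t for t in ids if t not in records]
    if missing:
        raise KeyError(f"no sequence for partition members: {missing}")

    dinucs = motif_dinucleotides(motif)
    columns = ["motif_score"] + dinucs + ["region_length"]
    rows = np.zeros((len(ids), len(columns)))
    warnings: list[str] = []
    for r, tid in enumerate(ids):
        rec = records[tid]
        offset, subseq = extract_region(rec, region)
        if not subseq:
            warnings.append(f"{tid}: empty {region.value}; all features 0")
            logger.warning("%s: empty %s; all features 0", tid, region.value)
            continue
        track = track_provider(tid, len(rec))
        hits = scan_region(subseq, offset, motif, tid, region)
        rows[r, 0] = region_score(hits, track)
        for j, dn in enumerate(dinucs, start=1):
            rows[r, j] = count_overlapping(subseq, dn)
        rows[r, -1] = len(subseq)

    features = pd.DataFrame(rows, index=pd.Index(ids, name="transcript_id"), columns=columns)
    labels = pd.Series(
        [1] * len(partition.positive_ids) + [0] * len(partition.negative_ids),
        index=features.index,
        name="label",
    )
    return FeatureTable(motif.motif_id, region, features, labels, warnings)


def read_motif_collection(source) -> list[IUPACMotif]:
    """Read a motif collection TSV (motif_id, rbp_name, iupac_pattern)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    return [
        IUPACMotif(row.motif_id, row.rbp_name, row.iupac_pattern)
        for row in df.itertuples(index=False)
    ]
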