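"""Per-base RNA accessibility (unpaired probability) tracks.

Accessibility is the probability that a base is unpaired in RNA secondary
structure, computed by a local-folding tool such as RNAplfold (run externally
on the whole transcript with W=200, L=150, U=1) and consumed here from its
``_lunp`` output.  A uniform provider (all bases fully accessible) makes
motif scores reduce to plain hit counts.

To generate tracks externally::

    RNAplfold -W 200 -L 150 -u 1 < transcript.fa
    # produces <id>_lunp in the working directory
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccessibilityTrack",
    "uniform_track",
    "load_unpaired_track",
    "write_unpaired_track",
    "site_accessibility",
    "uniform_provider",
    "directory_provider",
]


@dataclass
class AccessibilityTrack:
    """Unpaired probabilities, one per base; NaN marks missing values."""

    transcript_id: str
    p: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        present = self.p[~np.isnan(self.p)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError(f"{self.transcript_id}: probabilities outside [0, 1]")

    def __len__(self) -> int:
        return len(self.p)


def uniform_track(transcript_id: str, length: int) -> AccessibilityTrack:
    """Track with every base fully accessible (p = 1)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return AccessibilityTrack(transcript_id, np.ones(length), {"provider": "uniform"})


def load_unpaired_track(
    source, transcript_id: str, transcript_length: int, u: int = 1
) -> AccessibilityTrack:
    """Parse an RNAplfold ``_lunp`` file into a track.

    Rows are ``position value_u1 [value_u2 ...]`` with 1-based positions;
    lines starting with ``#`` are headers.  Only the ``u``-th column is read.
    Positions absent from the file, and ``NA`` entries, are missing.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh = source
        close = False
    p = np.full(transcript_length, np.nan)
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            pos = int(fields[0])  # 1-based
            if pos < 1 or pos > transcript_length:
                raise ValueError(
                    f"{transcript_id}: position {pos} outside transcript of "
                    f"length {transcript_length}"
                )
            raw = fields[u]
            if raw.upper() == "NA":
                continue
            value = float(raw)
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"{transcript_id}: probability {value} at position {pos} "
                    "outside [0, 1]"
                )
            p[pos - 1] = value
    finally:
        if close:
            fh.close()
    return AccessibilityTrack(transcript_id, p, {"provider": "file", "u": u})


def write_unpaired_track(track: AccessibilityTrack, dest) -> None:
    """Serialize a track in the ``_lunp`` dialect (1-based positions)."""
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        fh = open(dest, "w")
        close = True
    else:
        fh = dest
        close = False
    try:
        fh.write("#unpaired probabilities\n #i$\tl=1\n")
        for i, v in enumerate(track.p, start=1):
            fh.write(f"{i}\tNA\n" if np.isnan(v) else f"{i}\t{v:.8g}\n")
    finally:
        if close:
            fh.close()


def site_accessibility(track: AccessibilityTrack, start: int, end: int) -> float:
    """Mean unpaired probability over [start, end) (0-based half-open).

    Missing bases are ignored in the mean; a fully-missing window scores 0
    so the site contributes nothing.
    """
    if not (0 <= start < end <= len(track)):
        raise ValueError(f"invalid window [{start}, {end}) for track of length {len(track)}")
    window = track.p[start:end]
    present = window[~np.isnan(window)]
    if present.size == 0:
        return 0.0
    return float(present.mean())


def uniform_provider(transcript_id: str, length: int) -> AccessibilityTrack:
    """Track provider callable for the uniform fallback."""
    return uniform_track(transcript_id, length)


def directory_provider(directory):
    """Provider reading ``<dir>/<transcript_id>_lunp`` files."""
    import os

    def provide(transcript_id: str, length: int) -> AccessibilityTrack:
        path = os.path.join(directory, f"{transcript_id}_lunp")
        if not os.path.exists(path):
            raise FileNotFoundError(f"no accessibility track for {transcript_id}: {path}")
        return load_unpaired_track(path, transcript_id, length)

    return provide
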