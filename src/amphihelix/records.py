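"""Core sequence containers.

Coordinates are 1-based inclusive everywhere inside the package (matching
residue numbering conventions such as "residues 39–238"); only BED output
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .tables import AMINO_ACIDS

LOCALIZATION_LABELS = ("mitochondrial", "chloroplast", "secretory", "other")

_CANONICAL = frozenset(AMINO_ACIDS)


@dataclass
class SequenceRecord:
    """One protein sequence with optional disorder track and localization label."""

    id: str
    residues: str
    label: Optional[str] = None
    disorder_track: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in _CANONICAL]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-canonical residue {char!r} at position {pos}"
            )
        if self.label is not None and self.label not in LOCALIZATION_LABELS:
            raise ValueError(
                f"record {self.id!r}: unknown localization label {self.label!r}"
            )
        if self.disorder_track is not None:
            if len(self.disorder_track) != len(self.residues):
                raise ValueError(
                    f"record {self.id!r}: disorder track length "
                    f"{len(self.disorder_track)} != sequence length {len(self.residues)}"
                )
            if any(not (0.0 <= s <= 1.0) for s in self.disorder_track):
                raise ValueError(f"record {self.id!r}: disorder scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based inclusive)."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"interval {start}..{end} outside 1..{len(self.residues)}")
        return self.residues[start - 1 : end]


@dataclass
class ScoreTrack:
    """Per-residue score track keyed by 1-based position."""

    sequence_id: str
    positions: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.scores):
            raise ValueError("positions and scores differ in length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(
                f"track {self.sequence_id!r}: positions not strictly increasing"
            )

    def is_contiguous(self) -> bool:
        return self.positions == list(range(1, len(self.positions) + 1))
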