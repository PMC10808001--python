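"""Amphipathic 3–11 helical element detection.

The detector mirrors how continuous amphipathic helical elements are
predicted in apolipoprotein-type sequences:

1. *Helix-break segmentation* — the sequence is broken wherever a proline
   occurs, wherever glycines run continuously (≥ ``G_run_min``), or wherever
   polar/negative residues run for ``polar_run_min`` or more positions.
   Break residues are excluded from all segments.
2. *Window amphipathicity* — every 7-residue window inside a segment is
   projected on the 3–11 helical wheel (residue offset ``i`` occupies slot
   ``(3·i) mod 11``, i.e. 3 turns per 11 residues) and accepted when the
   hydrophobic-face residues are (a) between ``face_min`` and ``face_max``
   in number, (b) clustered within a wheel arc of at most ``arc_max``
   degrees, and (c) carry a window hydrophobic moment ≥ ``muH_min``.
3. *Stitching* — valid windows that overlap or abut are merged into maximal
   elements, and elements whose hydrophobic residues occupy fewer than
   ``slot_min`` or more than ``slot_max`` distinct wheel slots are dropped
   (weak amphipathic elements occupy 3–5 of the 11 projected positions).

Everything is deterministic: windows are scanned left to right and no step
draws random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .properties import DELTA_WHEEL, PropertySet, hydrophobic_moment
from .records import SequenceRecord
from .tables import ResidueTables

WINDOW = 7
"""Length of the amphipathicity test window (minimum element length)."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the detector (defaults = shipped configuration)."""

    g_run_min: int = 2        # >=2 consecutive G break ("continuous glycines")
    polar_run_min: int = 4    # >=4 consecutive polar/negative residues break
    face_min: int = 2         # min hydrophobic-face residues per 7-window
    face_max: int = 5         # max hydrophobic-face residues per 7-window
    arc_max: float = 180.0    # max wheel arc containing the face (degrees)
    muH_min: float = 0.2      # min window hydrophobic moment (scale units)
    slot_min: int = 3         # element-level distinct hydrophobic slots, low
    slot_max: int = 5         # element-level distinct hydrophobic slots, high
    slot_filter: bool = True  # apply the 3..5 slot bound to elements
    delta_deg: float = DELTA_WHEEL  # wheel angle per residue (1080/11 degrees)


@dataclass
class Segment:
    """Maximal break-free run of a sequence (1-based inclusive bounds)."""

    sequence_id: str
    start: int
    end: int
    residues: str


@dataclass
class AmphipathicElement:
    """A maximal run of merged valid windows (1-based inclusive bounds)."""

    sequence_id: str
    start: int
    end: int
    member_windows: list[int] = field(default_factory=list)
    hydrophobic_slots: frozenset[int] = frozenset()
    properties: Optional[PropertySet] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def wheel_slot(offset: int) -> int:
    """Wheel slot of residue ``offset`` (0-based) on the 11-position wheel."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    return (3 * offset) % 11


def _break_mask(residues: str, tables: ResidueTables, params: DetectionParams) -> list[bool]:
    """True at every position that belongs to a helix break."""
    n = len(residues)
    mask = [False] * n
    for i, r in enumerate(residues):
        if r == "P":
            mask[i] = True
    # runs of G of length >= g_run_min
    i = 0
    while i < n:
        if residues[i] == "G":
            j = i
            while j < n and residues[j] == "G":
                j += 1
            if j - i >= params.g_run_min:
                for k in range(i, j):
                    mask[k] = True
            i = j
        else:
            i += 1
    # runs of polar/negative residues of length >= polar_run_min
    i = 0
    while i < n:
        if residues[i] in tables.polar_set:
            j = i
            while j < n and residues[j] in tables.polar_set:
                j += 1
            if j - i >= params.polar_run_min:
                for k in range(i, j):
                    mask[k] = True
            i = j
        else:
            i += 1
    return mask


def segment_sequence(
    record: SequenceRecord, tables: ResidueTables, params: DetectionParams = DetectionParams()
) -> list[Segment]:
    """Split a sequence into maximal helix-break-free segments.

    Break-causing residues belong to no segment; concatenating segments and
    break regions in order reconstructs the input.
    """
    mask = _break_mask(record.residues, tables, params)
    segments: list[Segment] = []
    i = 0
    n = len(record.residues)
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            segments.append(Segment(record.id, i + 1, j, record.residues[i:j]))
            i = j
        else:
            i += 1
    return segments


@dataclass
class WindowDiagnostics:
    """Outcome of the three-part window test."""

    valid: bool
    n_face: int
    arc_deg: float
    muH: float
    failed: list[str] = field(default_factory=list)


def _min_arc(angles_deg: list[float]) -> float:
    """Smallest circular arc (degrees) containing all angles."""
    if len(angles_deg) <= 1:
        return 0.0
    a = sorted(x % 360.0 for x in angles_deg)
    gaps = [b - x for x, b in zip(a, a[1:])]
    gaps.append(a[0] + 360.0 - a[-1])
    return 360.0 - max(gaps)


def window_is_amphipathic(
    window_residues: str,
    tables: ResidueTables,
    params: DetectionParams = DetectionParams(),
) -> WindowDiagnostics:
    """Three-part amphipathicity test for one 7-residue window."""
    if len(window_residues) != WINDOW:
        raise ValueError(f"window must have exactly {WINDOW} residues")
    face_offsets = [i for i, r in enumerate(window_residues) if r in tables.face_set]
    n_face = len(face_offsets)
    angles = [(i * params.delta_deg) % 360.0 for i in face_offsets]
    arc = _min_arc(angles)
    muH = hydrophobic_moment(window_residues, tables, params.delta_deg)
    failed = []
    if not (params.face_min <= n_face <= params.face_max):
        failed.append("face_count")
    if n_face and arc > params.arc_max:
        failed.append("arc")
    if muH < params.muH_min:
        failed.append("muH")
    return WindowDiagnostics(not failed, n_face, arc, muH, failed)


def element_slots(residues: str, tables: ResidueTables) -> frozenset[int]:
    """Distinct wheel slots occupied by face residues, offsets from element start."""
    return frozenset(
        wheel_slot(i) for i, r in enumerate(residues) if r in tables.face_set
    )


def detect_elements(
    record: SequenceRecord,
    tables: ResidueTables,
    params: DetectionParams = DetectionParams(),
) -> list[AmphipathicElement]:
    """Detect maximal amphipathic 3–11 helical elements in one sequence.

    Within each helix-break-free segment a 7-residue window slides left to
    right; valid windows that overlap or abut are merged, and merged
    elements failing the distinct-hydrophobic-slot bound are dropped.
    """
    elements: list[AmphipathicElement] = []
    for seg in segment_sequence(record, tables, params):
        valid_starts = [
            s
            for s in range(seg.start, seg.end - WINDOW + 2)
            if window_is_amphipathic(
                record.residues[s - 1 : s - 1 + WINDOW], tables, params
            ).valid
        ]
        # merge overlapping-or-adjacent window intervals [s, s+6]
        run: list[int] = []
        for s in valid_starts + [None]:  # type: ignore[list-item]
            if run and (s is None or s > run[-1] + WINDOW):
                start, end = run[0], run[-1] + WINDOW - 1
                res = record.residues[start - 1 : end]
                slots = element_slots(res, tables)
                if not params.slot_filter or params.slot_min <= len(slots) <= params.slot_max:
                    elements.append(
                        AmphipathicElement(record.id, start, end, list(run), slots)
                    )
                run = []
            if s is not None:
                run.append(s)
    elements.sort(key=lambda e: e.start)
    return elements
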