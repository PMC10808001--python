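"""Physicochemical scoring of sequences, windows and detected elements.

Implements the four per-element parameters used to characterise weak
amphipathic helical elements: mean hydrophobicity ``H``, hydrophobic moment
``µH`` (HELIQUEST mean-moment convention, per-residue normalisation), net
charge ``z`` and the discriminant factor

    D = 0.944 · µH + 0.33 · z ,

which separates lipid-binding from non-binding amphipathic elements, plus
sliding-window charge descriptors (NCPR / FCR, window 10) and a
FoldIndex-style disorder proxy for sequences without an external disorder
track.

Two moment geometries are supported: the α-helical angle of 100° per
residue (HELIQUEST's equations; the default fed into ``D`` and group
statistics) and the 3–11 wheel angle of 1080/11° per residue (3 turns per
11 residues; used for wheel-slot/arc geometry during detection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import ScoreTrack, SequenceRecord
from .tables import ResidueTables, kyte_doolittle

DELTA_ALPHA = 100.0
"""Helical-wheel angle per residue for an ideal α-helix (degrees)."""

DELTA_WHEEL = 1080.0 / 11.0
"""Angle per residue of the 3–11 wheel: 3 turns per 11 residues (degrees)."""


@dataclass
class PropertySet:
    """Scores attached to one element.

    ``muH`` is the moment at the angle configured to feed ``D`` (100° by
    default); ``muH_wheel`` is the 3–11 wheel-angle moment, reported
    alongside.
    """

    H: float
    muH: float
    muH_wheel: float
    z: float
    D: float
    n_res: int
    mean_disorder: Optional[float] = None


def mean_hydrophobicity(residues: str, tables: ResidueTables) -> float:
    """Mean scale value ⟨h⟩ over the residue string."""
    if not residues:
        raise ValueError("empty residue string")
    return sum(tables.h(r) for r in residues) / len(residues)


def hydrophobic_moment(
    residues: str, tables: ResidueTables, delta_deg: float = DELTA_ALPHA
) -> float:
    """Mean hydrophobic moment µH at ``delta_deg`` degrees per residue.

    µH = (1/N) · | Σ_i h_i · (cos iδ, sin iδ) | with i = 0..N−1.
    """
    if not residues:
        raise ValueError("empty residue string")
    if delta_deg <= 0:
        raise ValueError("delta_deg must be positive")
    delta = math.radians(delta_deg)
    h = np.array([tables.h(r) for r in residues])
    ang = delta * np.arange(len(residues))
    return float(np.hypot((h * np.cos(ang)).sum(), (h * np.sin(ang)).sum()) / len(residues))


def net_charge(residues: str, tables: ResidueTables) -> int:
    """Total formal charge z (K/R = +1, D/E = −1 by default)."""
    if not residues:
        raise ValueError("empty residue string")
    return sum(tables.charge_of(r) for r in residues)


def discriminant_factor(muH: float, z: float) -> float:
    """D = 0.944·µH + 0.33·z."""
    return 0.944 * muH + 0.33 * z


@dataclass
class ChargeTrack:
    """Sliding-window charge descriptors; window start positions are 1-based."""

    sequence_id: str
    window: int
    starts: np.ndarray
    ncpr: np.ndarray
    fcr: np.ndarray


def windowed_charge(record: SequenceRecord, tables: ResidueTables, window: int = 10) -> ChargeTrack:
    """Net charge per residue and fraction of charged residues per window."""
    n = len(record)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    q = np.array([tables.charge_of(r) for r in record.residues], dtype=float)
    kernel = np.ones(window)
    net = np.convolve(q, kernel, mode="valid") / window
    frac = np.convolve(np.abs(q), kernel, mode="valid") / window
    starts = np.arange(1, n - window + 2)
    return ChargeTrack(record.id, window, starts, net, frac)


# FoldIndex-style disorder proxy: FI = 2.785·<H_KD,norm> − |<NCPR>| − 1.151
# over a centred window, with Kyte–Doolittle hydropathy rescaled to [0,1].
# Negative FI marks predicted disorder; the pseudo-disorder score maps FI
# onto [0,1] with 0.5 at the folded/disordered boundary.


def foldindex_track(
    record: SequenceRecord, tables: ResidueTables, window: int = 51
) -> tuple[ScoreTrack, ScoreTrack]:
    """Per-residue FoldIndex value and the derived pseudo-disorder score.

    Returns ``(fold_index, pseudo_disorder)`` tracks; the window is odd,
    centred, and clipped at the termini.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    kd = kyte_doolittle()
    n = len(record)
    h = np.array([(kd[r] + 4.5) / 9.0 for r in record.residues])
    q = np.array([tables.charge_of(r) for r in record.residues], dtype=float)
    half = window // 2
    fi = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        fi[i] = 2.785 * h[lo:hi].mean() - abs(q[lo:hi].mean()) - 1.151
    disorder = np.clip(0.5 - fi / 2.0, 0.0, 1.0)
    positions = list(range(1, n + 1))
    return (
        ScoreTrack(record.id, positions, fi.tolist()),
        ScoreTrack(record.id, positions, disorder.tolist()),
    )


def mean_disorder(
    record: SequenceRecord, start: int, end: int, tables: ResidueTables,
    source: str = "attached",
) -> Optional[float]:
    """Mean disorder over ``start..end`` from the chosen source.

    ``source`` is one of ``attached`` (use the record's track; None when
    absent), ``foldindex`` (built-in proxy) or ``none``.
    """
    if source == "none":
        return None
    if source == "attached":
        if record.disorder_track is None:
            return None
        return float(np.mean(np.asarray(record.disorder_track)[start - 1 : end]))
    if source == "foldindex":
        _, dis = foldindex_track(record, tables)
        return float(np.mean(dis.scores[start - 1 : end]))
    raise ValueError(f"unknown disorder source {source!r}")


def annotate_elements(
    elements: Iterable,
    record: SequenceRecord,
    tables: ResidueTables,
    disorder_source: str = "attached",
    d_delta_deg: float = DELTA_ALPHA,
) -> list:
    """Fill the :class:`PropertySet` of each element in place.

    ``d_delta_deg`` selects which moment geometry feeds ``D`` (100° by
    default; the wheel moment is always reported alongside).
    """
    out = []
    for el in elements:
        if el.sequence_id != record.id:
            raise ValueError(f"element {el.sequence_id!r} does not belong to {record.id!r}")
        res = record.subsequence(el.start, el.end)
        muH_alpha = hydrophobic_moment(res, tables, DELTA_ALPHA)
        muH_wheel = hydrophobic_moment(res, tables, DELTA_WHEEL)
        muH_for_d = muH_alpha if d_delta_deg == DELTA_ALPHA else hydrophobic_moment(
            res, tables, d_delta_deg
        )
        z = net_charge(res, tables)
        el.properties = PropertySet(
            H=mean_hydrophobicity(res, tables),
            muH=muH_for_d,
            muH_wheel=muH_wheel,
            z=z,
            D=discriminant_factor(muH_for_d, z),
            n_res=el.end - el.start + 1,
            mean_disorder=mean_disorder(record, el.start, el.end, tables, disorder_source),
        )
        out.append(el)
    return out


def basic_fraction(residues: str) -> float:
    """Fraction of basic residues (K, R) — the composition axis contrasted
    with hydrophobicity in localization-stratified comparisons."""
    if not residues:
        raise ValueError("empty residue string")
    return sum(r in "KR" for r in residues) / len(residues)
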