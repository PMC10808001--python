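"""Reading and writing sequences, score tracks, labels and element tables.

FASTA goes through Biopython; tabular formats are TSV via pandas. Element
tables exist in two dialects: TSV (1-based inclusive ``start``/``end`` plus
all property columns) and BED (0-based half-open, discriminant factor in
the score column). Writers emit a header comment carrying the tool version
and a hash of the active parameters so outputs are self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from . import __version__
from .detect import AmphipathicElement
from .properties import PropertySet
from .records import ScoreTrack, SequenceRecord

TSV_COLUMNS = [
    "sequence_id", "start", "end", "n_res",
    "H", "muH", "muH_wheel", "z", "D", "mean_disorder", "n_slots",
]


def read_fasta(path: str | Path, on_noncanonical: str = "reject") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``on_noncanonical`` is ``reject`` (default: any residue outside the
    20-letter alphabet is an error naming the record and position) or
    ``drop`` (non-canonical residues are removed before validation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if on_noncanonical == "drop":
            seq = "".join(c for c in seq if c in "ACDEFGHIKLMNPQRSTVWY")
        records.append(SequenceRecord(rec.id, seq))  # validates alphabet
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_score_track(
    path: str | Path,
    expected_ids: Optional[Iterable[str]] = None,
) -> dict[str, ScoreTrack]:
    """Read a TSV of columns ``id, position, score`` into tracks grouped by id.

    Scores must lie in [0, 1]; out-of-range values are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = df[(df["score"] < 0) | (df["score"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: score {row['score']} outside [0, 1] for id {row['id']!r} "
            f"position {int(row['position'])}"
        )
    tracks = {}
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        tracks[str(sid)] = ScoreTrack(
            str(sid), [int(p) for p in grp["position"]], [float(s) for s in grp["score"]]
        )
    if expected_ids is not None:
        missing = set(expected_ids) - set(tracks)
        if missing:
            raise ValueError(f"{path}: no track for ids {sorted(missing)}")
    return tracks


def attach_tracks(records: list[SequenceRecord], tracks: Mapping[str, ScoreTrack]) -> None:
    """Attach disorder tracks to records, requiring 1-based contiguity and
    exact length match."""
    for rec in records:
        track = tracks.get(rec.id)
        if track is None:
            continue
        if not track.is_contiguous():
            raise ValueError(f"track {rec.id!r}: positions are not contiguous from 1")
        if len(track.scores) != len(rec.residues):
            raise ValueError(
                f"track {rec.id!r}: length {len(track.scores)} != sequence "
                f"length {len(rec.residues)}"
            )
        rec.disorder_track = list(track.scores)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a TSV of columns ``id, label`` into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns ['id', 'label']")
    return {str(r["id"]): str(r["label"]) for _, r in df.iterrows()}


def _provenance(params: object) -> str:
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# amphihelix {__version__} params_hash={digest}"


def write_elements(
    elements: Iterable[AmphipathicElement],
    path: str | Path,
    dialect: str = "tsv",
    params: Optional[Mapping] = None,
    bed_score_scale: float = 100.0,
) -> None:
    """Write elements as TSV (1-based inclusive) or BED (0-based half-open).

    BED score column carries D scaled by ``bed_score_scale`` (rounded to int).
    """
    elements = list(elements)
    if dialect == "tsv":
        rows = []
        for el in elements:
            p = el.properties or PropertySet(
                float("nan"), float("nan"), float("nan"), float("nan"),
                float("nan"), el.length,
            )
            rows.append({
                "sequence_id": el.sequence_id, "start": el.start, "end": el.end,
                "n_res": el.length, "H": p.H, "muH": p.muH,
                "muH_wheel": p.muH_wheel, "z": p.z, "D": p.D,
                "mean_disorder": p.mean_disorder, "n_slots": len(el.hydrophobic_slots),
            })
        df = pd.DataFrame(rows, columns=TSV_COLUMNS)
        with open(path, "w") as fh:
            fh.write(_provenance(dict(params or {})) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    elif dialect == "bed":
        with open(path, "w") as fh:
            for i, el in enumerate(elements, 1):
                d = el.properties.D if el.properties else 0.0
                fh.write(
                    f"{el.sequence_id}\t{el.start - 1}\t{el.end}\t"
                    f"element_{i}\t{int(round(d * bed_score_scale))}\t+\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'bed')")


def read_elements(path: str | Path) -> list[AmphipathicElement]:
    """Read an element TSV written by :func:`write_elements` back into objects."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        el = AmphipathicElement(str(r["sequence_id"]), int(r["start"]), int(r["end"]))
        if not pd.isna(r.get("H")):
            md = r.get("mean_disorder")
            el.properties = PropertySet(
                H=float(r["H"]), muH=float(r["muH"]), muH_wheel=float(r["muH_wheel"]),
                z=float(r["z"]), D=float(r["D"]), n_res=int(r["n_res"]),
                mean_disorder=None if pd.isna(md) else float(md),
            )
        out.append(el)
    return out
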