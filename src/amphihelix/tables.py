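"""Residue property tables used throughout the package.

The default hydrophobicity scale is Fauchère–Pliška (the scale HELIQUEST
uses for mean hydrophobicity ``H`` and hydrophobic moment ``µH``); the
wheel-face set, polar/negative break set and side-chain charges live in the
same versioned data file (``data/scales.yaml``) and every entry can be
overridden through :meth:`ResidueTables.replace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from importlib import resources
from typing import Mapping

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical one-letter residue codes."""


def _load_scales() -> dict:
    with resources.files("amphihelix.data").joinpath("scales.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ResidueTables:
    """Bundle of per-residue lookup tables.

    Attributes
    ----------
    hydrophobicity : mapping residue -> scale value (kcal/mol for the
        default Fauchère–Pliška scale).
    face_set : residues counted as hydrophobic when projected on the
        helical wheel.
    polar_set : residues counted toward the polar/negative helix-break rule.
    charge : residue -> formal charge in elementary charges; residues not
        listed are neutral.
    """

    hydrophobicity: Mapping[str, float]
    face_set: frozenset[str]
    polar_set: frozenset[str]
    charge: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.hydrophobicity]
        if missing:
            raise ValueError(f"hydrophobicity table missing residues: {missing}")

    def charge_of(self, residue: str) -> int:
        return int(self.charge.get(residue, 0))

    def h(self, residue: str) -> float:
        try:
            return float(self.hydrophobicity[residue])
        except KeyError:
            raise KeyError(f"residue {residue!r} not in hydrophobicity table") from None

    def replace(self, **changes) -> "ResidueTables":
        """Return a copy with the given tables swapped out."""
        return _dc_replace(self, **changes)


def default_tables() -> ResidueTables:
    """Tables with the Fauchère–Pliška scale and shipped face/polar/charge sets."""
    data = _load_scales()
    return ResidueTables(
        hydrophobicity=dict(data["fauchere_pliska"]),
        face_set=frozenset(data["face_set"]),
        polar_set=frozenset(data["polar_set"]),
        charge=dict(data["charge"]),
    )


def kyte_doolittle() -> dict[str, float]:
    """Kyte–Doolittle hydropathy values (used by the disorder proxy)."""
    return dict(_load_scales()["kyte_doolittle"])
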