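"""Chemical-shift tables, secondary shifts and the two-state forward model.

Shift tables are long-format pandas DataFrames with columns
``residue`` (1-based), ``aa``, ``nucleus`` (CA, CB, CO, N, HN),
``observed``, ``rc`` (random-coil reference) and ``sigma``. Random-coil
references are always an input — no reference set is hard-coded.

The secondary-shift observable is

    ΔδCαβ = (δCα_obs − δCα_rc) − (δCβ_obs − δCβ_rc)   [ppm]

(glycine has no Cβ; its rows carry the Cα term only and are flagged).

Ensemble-averaged shifts use a deliberately simple two-state model:
a residue inside the helical basin contributes its full per-nucleus helix
offset Δ_helix, a coil residue contributes zero, so the predicted ensemble
average is linear in helical propensity by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .coil import EnsemblePool, ensemble_propensity

NUCLEI = ("CA", "CB", "CO", "N", "HN")


def load_shift_model() -> dict:
    with resources.files("amphihelix.data").joinpath("shift_model.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_helix_offsets() -> dict[str, float]:
    return dict(load_shift_model()["delta_helix"])


def default_sigmas() -> dict[str, float]:
    return dict(load_shift_model()["sigma"])


SHIFT_COLUMNS = ["residue", "aa", "nucleus", "observed", "rc", "sigma"]


def validate_shift_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SHIFT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"shift table missing columns {sorted(missing)}")
    if (table["sigma"] <= 0).any():
        raise ValueError("shift uncertainties sigma must be positive")
    gly_cb = table[(table["aa"] == "G") & (table["nucleus"] == "CB")]
    if len(gly_cb):
        raise ValueError(
            f"glycine rows cannot carry CB shifts (residue "
            f"{int(gly_cb.iloc[0]['residue'])})"
        )
    return table


@dataclass
class SecondaryShift:
    residue: int
    value: float
    ca_only: bool  # True for glycine rows (no Cβ term)


def delta_delta_cacb(table: pd.DataFrame) -> list[SecondaryShift]:
    """Per-residue ΔδCαβ from observed and random-coil Cα/Cβ shifts.

    Missing observations propagate as absent rows, never as zeros; a
    missing random-coil reference is an error naming the residue.
    """
    validate_shift_table(table)
    out = []
    for res, grp in table.groupby("residue", sort=True):
        by_nuc = {r["nucleus"]: r for _, r in grp.iterrows()}
        ca = by_nuc.get("CA")
        if ca is None or pd.isna(ca["observed"]):
            continue
        if pd.isna(ca["rc"]):
            raise ValueError(f"residue {res}: missing random-coil CA reference")
        d_ca = ca["observed"] - ca["rc"]
        aa = str(ca["aa"])
        cb = by_nuc.get("CB")
        if aa == "G" or cb is None or pd.isna(cb["observed"]):
            if aa == "G":
                out.append(SecondaryShift(int(res), float(d_ca), ca_only=True))
            # non-glycine without an observed CB: value is absent, skip
            continue
        if pd.isna(cb["rc"]):
            raise ValueError(f"residue {res}: missing random-coil CB reference")
        out.append(
            SecondaryShift(int(res), float(d_ca - (cb["observed"] - cb["rc"])), ca_only=False)
        )
    return out


def predict_shifts(
    pool: EnsemblePool,
    rc_table: pd.DataFrame,
    offsets: Optional[Mapping[str, float]] = None,
    indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Ensemble-averaged predicted shifts for a pool or sub-ensemble.

    δ_pred(i, nucleus) = δ_rc(i, nucleus) + p_helix(i) · Δ_helix(nucleus),
    where p_helix is the helical propensity of the (sub-)ensemble — the
    conformer average of the two-state model.
    """
    offsets = dict(offsets or default_helix_offsets())
    prop = ensemble_propensity(pool, indices)
    pred = rc_table.copy()
    dvals = np.array([offsets.get(nuc, 0.0) for nuc in pred["nucleus"]])
    pvals = prop[pred["residue"].to_numpy() - 1]
    pred["predicted"] = pred["rc"].to_numpy() + pvals * dvals
    return pred


@dataclass
class ShiftTargets:
    """Chain-aligned secondary-shift targets for the selection χ².

    ``secondary`` and ``sigma`` are (L, K) arrays over residues × nuclei;
    NaN marks missing observations (excluded from the fit).
    """

    nuclei: tuple[str, ...]
    secondary: np.ndarray
    sigma: np.ndarray
    offsets: np.ndarray  # (K,) helix offsets per nucleus

    @property
    def n_residues(self) -> int:
        return self.secondary.shape[0]


def targets_from_table(
    table: pd.DataFrame,
    n_residues: int,
    offsets: Optional[Mapping[str, float]] = None,
) -> ShiftTargets:
    """Convert a long-format shift table into chain-aligned target arrays."""
    validate_shift_table(table)
    offsets = dict(offsets or default_helix_offsets())
    nuclei = tuple(n for n in NUCLEI if n in set(table["nucleus"]))
    sec = np.full((n_residues, len(nuclei)), np.nan)
    sig = np.full((n_residues, len(nuclei)), np.nan)
    for _, row in table.iterrows():
        if row["nucleus"] not in nuclei or pd.isna(row["observed"]):
            continue
        i = int(row["residue"]) - 1
        if not (0 <= i < n_residues):
            raise ValueError(f"residue {row['residue']} outside chain 1..{n_residues}")
        k = nuclei.index(row["nucleus"])
        sec[i, k] = row["observed"] - row["rc"]
        sig[i, k] = row["sigma"]
    return ShiftTargets(
        nuclei=nuclei,
        secondary=sec,
        sigma=sig,
        offsets=np.array([offsets[n] for n in nuclei]),
    )


def chi_square(propensity: np.ndarray, targets: ShiftTargets) -> float:
    """χ² of a propensity profile against secondary-shift targets."""
    pred = propensity[:, None] * targets.offsets[None, :]
    resid = (pred - targets.secondary) / targets.sigma
    return float(np.nansum(resid**2))
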