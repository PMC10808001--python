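"""Batched backbone construction with ideal peptide geometry.

Chains are grown atom by atom (N, Cα, C per residue) from backbone
dihedrals using fixed bond lengths and angles and a trans peptide bond
(ω = 180°). All routines operate on batches of chains simultaneously so
ensembles of thousands of conformers build in vectorised numpy.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (Engh–Huber-type values), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

CA_CA_IDEAL = 3.8  # consecutive Cα–Cα distance for a trans peptide (Å)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: np.ndarray | float,
) -> np.ndarray:
    """Place atom D given A–B–C, the C–D bond length, the B–C–D angle and
    the A–B–C–D torsion (batched over leading dimensions)."""
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = (
        -np.cos(theta) * bc
        + (np.sin(theta) * np.cos(chi))[..., None] * m
        + (np.sin(theta) * np.sin(chi))[..., None] * n
    )
    return c + bond * d_local


def build_backbones(phi_deg: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """Build backbones for a batch of chains.

    Parameters
    ----------
    phi_deg, psi_deg : arrays (B, L) of backbone dihedrals in degrees.
        ``phi[:, 0]`` and ``psi[:, -1]`` are undefined for a real chain and
        ignored/used only through the standard placement rules.

    Returns
    -------
    coords : array (B, L, 3, 3) — per residue the N, Cα, C positions (Å).
    """
    phi = np.atleast_2d(phi_deg)
    psi = np.atleast_2d(psi_deg)
    B, L = phi.shape
    coords = np.zeros((B, L, 3, 3))
    # first residue in a canonical local frame
    theta0 = np.radians(ANGLE_N_CA_C)
    coords[:, 0, 0] = [0.0, 0.0, 0.0]
    coords[:, 0, 1] = [BOND_N_CA, 0.0, 0.0]
    coords[:, 0, 2] = coords[:, 0, 1] + BOND_CA_C * np.array(
        [-np.cos(theta0), np.sin(theta0), 0.0]
    )
    for i in range(1, L):
        n_prev, ca_prev, c_prev = (
            coords[:, i - 1, 0], coords[:, i - 1, 1], coords[:, i - 1, 2]
        )
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[:, i])
        coords[:, i, 0], coords[:, i, 1], coords[:, i, 2] = n_i, ca_i, c_i
    return coords


def radius_of_gyration(ca_coords: np.ndarray) -> float | np.ndarray:
    """Root-mean-square distance of Cα atoms from their centroid.

    Accepts ``(L, 3)`` for one conformer or ``(B, L, 3)`` for a batch.
    Invariant under rigid-body motion.
    """
    x = np.asarray(ca_coords, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    centred = x - x.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred**2).sum(axis=-1).mean(axis=-1))
    return float(rg[0]) if single else rg
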