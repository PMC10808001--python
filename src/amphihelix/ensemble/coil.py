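"""Statistical-coil ensemble generation.

Each residue's (φ, ψ) pair is drawn from a four-basin Gaussian mixture
(β, polyproline-II, αR, αL) with residue-type-specific weights (glycine
widened, proline φ pinned); backbones are built with ideal trans-peptide
geometry and chains are grown under an excluded-volume constraint: a newly
placed Cα closer than the clash cutoff (4.0 Å) to any Cα at sequence
separation ≥ 3 triggers a local redraw of the offending dihedrals, and a
chain that exhausts its local retries is restarted. The retained ensemble
therefore contains no clashing conformer.

All mixture parameters are calibration constants stored in
``data/coil_basins.yaml``, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .geometry import build_backbones, place_atom, radius_of_gyration
from .geometry import BOND_N_CA, BOND_CA_C, BOND_C_N
from .geometry import ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA, OMEGA

BASIN_NAMES = ("beta", "ppii", "alphaR", "alphaL")


def load_basin_params() -> dict:
    """Shipped sampler configuration (see ``data/coil_basins.yaml``)."""
    with resources.files("amphihelix.data").joinpath("coil_basins.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class Conformer:
    """One backbone conformer: dihedrals, coordinates and helical flags."""

    phi: np.ndarray                 # (L,) degrees
    psi: np.ndarray                 # (L,) degrees
    coords: np.ndarray              # (L, 3, 3): N, Cα, C per residue (Å)
    helical_flags: np.ndarray       # (L,) bool

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def rg(self) -> float:
        return radius_of_gyration(self.ca)


@dataclass
class EnsemblePool:
    """A batch of conformers stored as arrays.

    ``basin`` holds the mixture-component index each residue was drawn
    from; ``helical`` flags residues whose sampled dihedrals fall inside
    the configured helical basin box (these can differ near basin edges).
    """

    sequence: str
    phi: np.ndarray       # (n, L) degrees
    psi: np.ndarray       # (n, L) degrees
    ca: np.ndarray        # (n, L, 3) Å
    basin: np.ndarray     # (n, L) int, index into BASIN_NAMES
    helical: np.ndarray   # (n, L) bool
    rg_values: np.ndarray  # (n,)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def basin_frequencies(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Residue × basin frequency matrix (rows sum to 1)."""
        b = self.basin if indices is None else self.basin[np.asarray(indices)]
        freq = np.stack(
            [(b == k).mean(axis=0) for k in range(len(BASIN_NAMES))], axis=1
        )
        return freq

    def conformer(self, i: int) -> Conformer:
        """Rebuild conformer ``i`` with full backbone coordinates."""
        coords = build_backbones(self.phi[i][None], self.psi[i][None])[0]
        return Conformer(self.phi[i], self.psi[i], coords, self.helical[i])


def _mixture_for_sequence(sequence: str, params: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue mixture weights (L, 4) and basin means/sds (L, 4, 2)."""
    L = len(sequence)
    basins = params["basins"]
    means = np.array(
        [[basins[b]["phi_mean"], basins[b]["psi_mean"]] for b in BASIN_NAMES]
    )
    sds = np.array(
        [[basins[b]["phi_sd"], basins[b]["psi_sd"]] for b in BASIN_NAMES]
    )
    weights = np.empty((L, len(BASIN_NAMES)))
    mean_arr = np.broadcast_to(means, (L, *means.shape)).copy()
    sd_arr = np.broadcast_to(sds, (L, *sds.shape)).copy()
    wtab = params["weights"]
    for i, aa in enumerate(sequence):
        w = wtab.get(aa, wtab["generic"])
        weights[i] = [w.get(b, 0.0) for b in BASIN_NAMES]
        if aa == "G":
            sd_arr[i] *= params.get("gly_sd_scale", 1.0)
        elif aa == "P":
            mean_arr[i, :, 0] = params.get("pro_phi_mean", -65.0)
            sd_arr[i, :, 0] = params.get("pro_phi_sd", 7.0)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights, mean_arr, sd_arr


def _draw_dihedrals(
    rng: np.random.Generator,
    weights: np.ndarray, means: np.ndarray, sds: np.ndarray,
    n: int, residues: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (phi, psi, basin) for ``n`` chains at the given residues.

    ``residues`` selects a subset of positions (default: all L positions).
    Returns arrays of shape (n, len(residues)).
    """
    if residues is None:
        residues = np.arange(weights.shape[0])
    w = weights[residues]                       # (m, 4)
    cum = np.cumsum(w, axis=1)
    u = rng.random((n, len(residues), 1))
    basin = (u > cum[None]).sum(axis=2)         # (n, m)
    mu = means[residues][np.arange(len(residues))[None, :], basin]   # (n, m, 2)
    sd = sds[residues][np.arange(len(residues))[None, :], basin]
    ang = rng.normal(mu, sd)
    return ang[..., 0], ang[..., 1], basin


def helical_mask(phi: np.ndarray, psi: np.ndarray, params: dict) -> np.ndarray:
    """Boolean mask of residues inside the configured helical basin box."""
    box = params["helical_basin"]
    return (
        (phi >= box["phi"][0]) & (phi <= box["phi"][1])
        & (psi >= box["psi"][0]) & (psi <= box["psi"][1])
    )


def _grow_chains(
    phi: np.ndarray, psi: np.ndarray, basin: np.ndarray,
    rng: np.random.Generator,
    weights: np.ndarray, means: np.ndarray, sds: np.ndarray,
    params: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow chains residue by residue under the clash constraint.

    Dihedral arrays are modified in place where local redraws occur.
    Returns (ca_coords (B, L, 3), failed mask (B,)).
    """
    B, L = phi.shape
    cutoff = float(params.get("clash_cutoff", 4.0))
    min_sep = int(params.get("clash_min_separation", 3))
    ev_cutoff = float(params.get("excluded_volume_cutoff", cutoff))
    ev_min_sep = int(params.get("excluded_volume_min_sep", 5))
    max_retries = int(params.get("max_residue_retries", 100))
    coords = np.zeros((B, L, 3, 3))
    theta0 = np.radians(ANGLE_N_CA_C)
    coords[:, 0, 1] = [BOND_N_CA, 0.0, 0.0]
    coords[:, 0, 2] = coords[:, 0, 1] + BOND_CA_C * np.array(
        [-np.cos(theta0), np.sin(theta0), 0.0]
    )
    failed = np.zeros(B, dtype=bool)
    for i in range(1, L):
        active = np.flatnonzero(~failed)
        tries = 0
        while active.size:
            n_prev = coords[active, i - 1, 0]
            ca_prev = coords[active, i - 1, 1]
            c_prev = coords[active, i - 1, 2]
            n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N,
                             psi[active, i - 1])
            ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[active, i])
            coords[active, i, 0] = n_i
            coords[active, i, 1] = ca_i
            coords[active, i, 2] = c_i
            if i < min_sep:
                break
            prev_ca = coords[active, : i - min_sep + 1, 1]      # (a, i-2, 3)
            d2 = ((prev_ca - ca_i[:, None, :]) ** 2).sum(axis=2)
            # tiered excluded volume: hard core at short separations, a
            # larger soft-core diameter (side-chain bulk) at |i-j| >= 5
            sep = i - np.arange(i - min_sep + 1)
            thr2 = np.where(sep >= ev_min_sep, ev_cutoff**2, cutoff**2)
            clash = (d2 < thr2[None, :]).any(axis=1)
            if not clash.any():
                break
            tries += 1
            bad = active[clash]
            if tries > max_retries:
                failed[bad] = True
                active = np.array([], dtype=int)
                break
            # redraw the dihedrals that position this Cα: ψ(i−1) moves N(i)
            # and Cα(i); φ(i−1) moves C(i−1) hence everything after it.
            p, s, b = _draw_dihedrals(
                rng, weights, means, sds, len(bad), np.array([i - 1])
            )
            phi[bad, i - 1] = p[:, 0]
            psi[bad, i - 1] = s[:, 0]
            basin[bad, i - 1] = b[:, 0]
            if i - 1 >= 1:
                # rebuild C(i−1) for the redrawn chains
                coords[bad, i - 1, 2] = place_atom(
                    coords[bad, i - 2, 2], coords[bad, i - 1, 0],
                    coords[bad, i - 1, 1], BOND_CA_C, ANGLE_N_CA_C,
                    phi[bad, i - 1],
                )
            active = bad
    return coords[:, :, 1, :], failed


def sample_coil_ensemble(
    length_or_sequence: int | str,
    n: int,
    seed: int | np.random.Generator,
    basin_params: Optional[dict] = None,
    alpha_weight: Optional[float] = None,
) -> EnsemblePool:
    """Sample ``n`` statistical-coil conformers of a chain.

    Parameters
    ----------
    length_or_sequence : chain length (poly-alanine-like generic residues)
        or an explicit residue string (G/P special-cased).
    seed : integer seed or an existing Generator (consumed).
    basin_params : overrides for the shipped sampler configuration.
    alpha_weight : if given, the generic αR basin weight is set to this
        value (remaining weight redistributed proportionally) — degenerate
        values 0/1 give fully extended / fully helical pools.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = load_basin_params()
    if basin_params:
        params = {**params, **basin_params}
    sequence = (
        length_or_sequence if isinstance(length_or_sequence, str)
        else "A" * int(length_or_sequence)
    )
    if alpha_weight is not None:
        w = dict(params["weights"]["generic"])
        others = {b: w[b] for b in w if b != "alphaR"}
        tot = sum(others.values())
        scale = (1.0 - alpha_weight) / tot if tot > 0 else 0.0
        new_w = {b: v * scale for b, v in others.items()}
        new_w["alphaR"] = alpha_weight
        params = {**params, "weights": {**params["weights"], "generic": new_w}}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights, means, sds = _mixture_for_sequence(sequence, params)
    L = len(sequence)
    max_restarts = int(params.get("max_chain_restarts", 50))

    phi = np.empty((n, L))
    psi = np.empty((n, L))
    basin = np.empty((n, L), dtype=int)
    ca = np.empty((n, L, 3))
    todo = np.arange(n)
    for attempt in range(max_restarts + 1):
        p, s, b = _draw_dihedrals(rng, weights, means, sds, len(todo))
        coords_ca, failed = _grow_chains(p, s, b, rng, weights, means, sds, params)
        ok = ~failed
        done = todo[ok]
        phi[done], psi[done], basin[done], ca[done] = p[ok], s[ok], b[ok], coords_ca[ok]
        todo = todo[failed]
        if todo.size == 0:
            break
    else:
        pass
    if todo.size:
        raise RuntimeError(
            f"clash rejection failed for {todo.size} chains after "
            f"{max_restarts} restarts; relax clash_cutoff or basin widths"
        )
    return EnsemblePool(
        sequence=sequence,
        phi=phi, psi=psi, ca=ca, basin=basin,
        helical=helical_mask(phi, psi, params),
        rg_values=radius_of_gyration(ca),
        params=params,
    )


def resample_pool_from_frequencies(
    pool: EnsemblePool,
    freq: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> EnsemblePool:
    """Sample a new pool whose per-residue basin weights are ``freq``.

    Used by the iterative selection scheme: the biased fraction of each new
    generation is drawn from the basin frequencies of the previously
    selected conformers.
    """
    params = pool.params
    weights, means, sds = _mixture_for_sequence(pool.sequence, params)
    # replace mixture weights with the observed frequencies (regularised so
    # every basin keeps a small floor and rows sum to one)
    floor = 1e-3
    w = np.clip(freq, floor, None)
    w /= w.sum(axis=1, keepdims=True)
    L = pool.n_residues
    max_restarts = int(params.get("max_chain_restarts", 50))
    phi = np.empty((n, L))
    psi = np.empty((n, L))
    basin = np.empty((n, L), dtype=int)
    ca = np.empty((n, L, 3))
    todo = np.arange(n)
    for _ in range(max_restarts + 1):
        p, s, b = _draw_dihedrals(rng, w, means, sds, len(todo))
        coords_ca, failed = _grow_chains(p, s, b, rng, w, means, sds, params)
        ok = ~failed
        done = todo[ok]
        phi[done], psi[done], basin[done], ca[done] = p[ok], s[ok], b[ok], coords_ca[ok]
        todo = todo[failed]
        if todo.size == 0:
            break
    if todo.size:
        raise RuntimeError("clash rejection failed during pool regeneration")
    return EnsemblePool(
        sequence=pool.sequence, phi=phi, psi=psi, ca=ca, basin=basin,
        helical=helical_mask(phi, psi, params),
        rg_values=radius_of_gyration(ca), params=params,
    )


def concatenate_pools(a: EnsemblePool, b: EnsemblePool) -> EnsemblePool:
    return EnsemblePool(
        sequence=a.sequence,
        phi=np.concatenate([a.phi, b.phi]),
        psi=np.concatenate([a.psi, b.psi]),
        ca=np.concatenate([a.ca, b.ca]),
        basin=np.concatenate([a.basin, b.basin]),
        helical=np.concatenate([a.helical, b.helical]),
        rg_values=np.concatenate([a.rg_values, b.rg_values]),
        params=a.params,
    )


def write_pdb(pool: EnsemblePool, indices, path) -> None:
    """Export conformers as minimal backbone (N, CA, C) PDB MODEL records."""
    atom_names = ("N", "CA", "C")
    with open(path, "w") as fh:
        for model, idx in enumerate(indices, 1):
            conf = pool.conformer(int(idx))
            fh.write(f"MODEL     {model:4d}\n")
            serial = 1
            for i in range(len(conf.phi)):
                aa = pool.sequence[i]
                for a, name in enumerate(atom_names):
                    x, y, z = conf.coords[i, a]
                    fh.write(
                        f"ATOM  {serial:5d}  {name:<3s}{_THREE.get(aa, 'UNK'):>4s}"
                        f" A{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"  1.00  0.00\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def ensemble_propensity(
    pool: EnsemblePool, indices: Optional[Sequence[int]] = None, min_run: int = 1
) -> np.ndarray:
    """Per-residue helical propensity: fraction of conformers whose flags
    (optionally filtered to runs of ≥ ``min_run`` consecutive helical
    residues) are set."""
    flags = pool.helical if indices is None else pool.helical[np.asarray(indices)]
    if min_run > 1:
        filt = np.zeros_like(flags)
        for c in range(flags.shape[0]):
            row = flags[c]
            i = 0
            L = len(row)
            while i < L:
                if row[i]:
                    j = i
                    while j < L and row[j]:
                        j += 1
                    if j - i >= min_run:
                        filt[c, i:j] = True
                    i = j
                else:
                    i += 1
        flags = filt
    return flags.mean(axis=0)
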