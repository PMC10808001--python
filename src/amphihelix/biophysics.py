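"""Instrument-trace analyses printed as closed-form expressions.

* Langmuir monolayer compression modulus  Cs⁻¹ = −A·(dπ/dA)
* exponential relaxation decay            h = A·exp(−R·t)
* heteronuclear NOE ratio                 I/I₀
* fluorescence anisotropy                 r = (I∥ − g·I⊥)/(I∥ + 2·g·I⊥)
* DSC thermogram baseline (mean of the trailing points) and peak picking

Traces are plain ``(x, y)`` arrays with declared units; no implicit unit
conversion happens anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

DEFAULT_G_FACTOR = 1.171
"""Detector gamma correction determined with DPH in methanol."""


@dataclass
class IsothermTrace:
    """Surface pressure π (mN/m) against mean molecular area A (Å²/molecule)."""

    A: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        self.pi = np.asarray(self.pi, float)
        if self.A.shape != self.pi.shape:
            raise ValueError("A and pi differ in length")


def compression_modulus(
    trace: IsothermTrace,
    smoothing: Optional[tuple[int, int]] = None,
    sort: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cs⁻¹(A) = −A · dπ/dA along a compression isotherm.

    The derivative is taken by central differences on the (optionally
    Savitzky–Golay smoothed) trace; ``smoothing`` is ``(window, polyorder)``.
    Returns ``(pi, cs_inv)`` aligned point-for-point with the input.
    """
    A, pi = trace.A, trace.pi
    if len(A) < 5:
        raise ValueError("need at least 5 isotherm points")
    dA = np.diff(A)
    if np.any(dA > 0) and np.any(dA < 0):
        if not sort:
            raise ValueError("mean molecular area is not monotone")
        order = np.argsort(A)[::-1]
        A, pi = A[order], pi[order]
    if smoothing is not None:
        window, order = smoothing
        pi = savgol_filter(pi, window, order)
    cs_inv = -A * np.gradient(pi, A)
    return pi, cs_inv


def mean_modulus_in_band(
    pi: np.ndarray, cs_inv: np.ndarray, lo: float = 25.0, hi: float = 35.0
) -> float:
    """Mean Cs⁻¹ over a surface-pressure band (default 25–35 mN/m, the
    physiologically relevant pressure range for bilayer leaflets)."""
    mask = (pi >= lo) & (pi <= hi)
    if not mask.any():
        raise ValueError(f"no isotherm points with pi in [{lo}, {hi}] mN/m")
    return float(cs_inv[mask].mean())


@dataclass
class DecayFit:
    amplitude: float
    rate: float
    residuals: np.ndarray
    rate_stderr: float
    flagged_non_decaying: bool = False


def fit_exponential_decay(t: Sequence[float], h: Sequence[float]) -> DecayFit:
    """Nonlinear least-squares fit of h = A·exp(−R·t).

    Initialised from a log-linear regression on the positive heights; a
    non-decaying series is fitted anyway and flagged (R ≤ 0).
    """
    t = np.asarray(t, float)
    h = np.asarray(h, float)
    if len(t) < 3 or len(np.unique(t)) < 2:
        raise ValueError("need >= 3 points with >= 2 distinct delays")
    pos = h > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(h[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(h.max(initial=1.0)), 1.0)
    popt, pcov = curve_fit(
        lambda tt, a, r: a * np.exp(-r * tt), t, h, p0=p0, maxfev=10000
    )
    a, r = float(popt[0]), float(popt[1])
    resid = h - a * np.exp(-r * t)
    stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return DecayFit(a, r, resid, stderr, flagged_non_decaying=r <= 0)


def het_noe(
    I: Sequence[float], I0: Sequence[float],
    sigma_I: Optional[Sequence[float]] = None,
    sigma_I0: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Heteronuclear NOE ratio I/I₀ per residue with optional error
    propagation σ_ratio = |ratio|·sqrt((σ_I/I)² + (σ_I0/I0)²)."""
    I = np.atleast_1d(np.asarray(I, float))
    I0 = np.atleast_1d(np.asarray(I0, float))
    if np.any(I0 == 0):
        idx = int(np.flatnonzero(I0 == 0)[0])
        raise ZeroDivisionError(f"reference intensity I0 is zero at index {idx}")
    ratio = I / I0
    if sigma_I is None or sigma_I0 is None:
        return ratio, None
    sI = np.asarray(sigma_I, float)
    sI0 = np.asarray(sigma_I0, float)
    return ratio, np.abs(ratio) * np.sqrt((sI / I) ** 2 + (sI0 / I0) ** 2)


def anisotropy(
    I_par: float | np.ndarray, I_perp: float | np.ndarray, g: float = DEFAULT_G_FACTOR
) -> float | np.ndarray:
    """Fluorescence anisotropy r = (I∥ − g·I⊥) / (I∥ + 2·g·I⊥)."""
    I_par = np.asarray(I_par, float)
    I_perp = np.asarray(I_perp, float)
    if np.any(I_par < 0) or np.any(I_perp < 0):
        raise ValueError("intensities must be non-negative")
    denom = I_par + 2.0 * g * I_perp
    if np.any(denom <= 0):
        raise ValueError("I_par + 2*g*I_perp must be positive")
    r = (I_par - g * I_perp) / denom
    return float(r) if r.ndim == 0 else r


@dataclass
class ThermogramPeaks:
    Tm: float
    peak_height: float
    secondary_peaks: list[tuple[float, float]] = field(default_factory=list)
    boundary_flagged: bool = False
    corrected: np.ndarray = field(default_factory=lambda: np.empty(0))


def thermogram_peak(
    T: Sequence[float], cp: Sequence[float],
    baseline_n: int = 15,
    prominence_frac: float = 0.1,
) -> ThermogramPeaks:
    """Baseline-correct a DSC thermogram and locate its phase transitions.

    The baseline is the mean of the last ``baseline_n`` points (taken well
    beyond the transition); Tm is the temperature of the global maximum of
    the corrected signal, and additional local maxima above
    ``prominence_frac`` of the main peak height are reported as secondary
    transitions. A maximum sitting on the trace boundary is flagged
    unreliable.
    """
    T = np.asarray(T, float)
    cp = np.asarray(cp, float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if len(T) < baseline_n + 5:
        raise ValueError(f"need at least baseline_n + 5 = {baseline_n + 5} points")
    corrected = cp - cp[-baseline_n:].mean()
    imax = int(np.argmax(corrected))
    height = float(corrected[imax])
    boundary = imax in (0, len(T) - 1)
    peaks, props = find_peaks(corrected, prominence=prominence_frac * max(height, 1e-12))
    secondary = [
        (float(T[i]), float(corrected[i])) for i in peaks if i != imax
    ]
    secondary.sort(key=lambda p: -p[1])
    return ThermogramPeaks(float(T[imax]), height, secondary, boundary, corrected)
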