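"""Empirical mode decomposition by cubic-spline envelope sifting.

Standard EMD: each intrinsic mode function (IMF) is extracted by repeatedly
subtracting the mean of the upper/lower cubic-spline envelopes until the
normalized squared change between sifts drops below a threshold (Huang's SD
criterion).  Mirror extension of the boundary extrema tames end effects.
Completeness (sum of IMFs + residue == input) holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "emd"]


@dataclass
class IMFSet:
    """IMFs ordered high-to-low frequency, plus the monotone-ish residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out

    def __len__(self) -> int:
        return len(self.imfs)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    dx = np.diff(x)
    # collapse flats so plateau edges register once
    nz = np.nonzero(dx)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    sign = np.sign(dx[nz])
    flips = np.nonzero(np.diff(sign))[0]
    maxima, minima = [], []
    for f in flips:
        left, right = nz[f], nz[f + 1]
        idx = (left + right + 1) // 2
        if sign[f] > 0:
            maxima.append(idx)
        else:
            minima.append(idx)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror(idx: np.ndarray, vals: np.ndarray, n: int, n_pad: int = 2):
    """Reflect boundary extrema about both signal ends to anchor the splines.

    Even reflection about t=0 and t=n-1 guarantees the spline knots cover the
    whole domain, so envelope evaluation never extrapolates.
    """
    left_i = (-idx[:n_pad])[::-1]
    left_v = vals[:n_pad][::-1]
    right_i = (2 * (n - 1) - idx[-n_pad:])[::-1]
    right_v = vals[-n_pad:][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    vi = np.concatenate([left_v, vals, right_v])
    # guard strictly-increasing knots (degenerate mirrors at short inputs)
    keep = np.concatenate([[True], np.diff(xi) > 0])
    return xi[keep], vi[keep]


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    maxi, mini = _local_extrema(x)
    if maxi.size < 2 or mini.size < 2:
        return None
    n = x.shape[0]
    t = np.arange(n)
    pad = min(2, maxi.size - 1, mini.size - 1)
    mx_i, mx_v = _mirror(maxi, x[maxi], n, pad)
    mn_i, mn_v = _mirror(mini, x[mini], n, pad)
    upper = CubicSpline(mx_i, mx_v)(t)
    lower = CubicSpline(mn_i, mn_v)(t)
    return 0.5 * (upper + lower)


def emd(
    x: np.ndarray,
    max_imfs: int = 12,
    max_siftings: int = 100,
    sd_threshold: float = 0.2,
) -> IMFSet:
    """Decompose ``x`` into IMFs plus a residue.

    Inputs with fewer than 4 extrema (e.g. a monotone ramp) yield zero IMFs
    with the input returned untouched as the residue.
    """
    x = np.asarray(x, dtype=float)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    eps = 1e-12
    for _ in range(max_imfs):
        maxi, mini = _local_extrema(residue)
        if maxi.size + mini.size < 4 or maxi.size < 2 or mini.size < 2:
            break
        h = residue.copy()
        n_sifts = 0
        for _ in range(max_siftings):
            m = _mean_envelope(h)
            if m is None:
                break
            h_new = h - m
            n_sifts += 1
            sd = float(np.sum((h - h_new) ** 2) / np.sum(h**2 + eps))
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        counts.append(n_sifts)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue, sift_counts=counts)
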