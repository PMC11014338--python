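"""Automatic S1/S2 labeling from the PCG band.

S1 and S2 candidates are local maxima of a smoothed normalized Shannon
energy envelope; candidates are expressed as phase-in-cycle and split into
two clusters (k=2); the earlier-phase cluster is S1, the later one S2.  The
ordering rule -- never the cluster index -- decides which is which.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from scipy.ndimage import uniform_filter1d
from sklearn.cluster import KMeans

from .segment import RPeakList

__all__ = [
    "EnergyEnvelope",
    "S1S2Labels",
    "energy_envelope",
    "label_s1_s2",
    "position_correlation",
]


@dataclass
class EnergyEnvelope:
    """Nonnegative smoothed Shannon-energy trace of a PCG band signal."""

    values: np.ndarray
    window_samples: int
    normalization: float

    def __len__(self) -> int:
        return len(self.values)


def energy_envelope(
    pcg: np.ndarray, sampling_rate: float, window_ms: float = 40.0
) -> EnergyEnvelope:
    """Normalized Shannon energy ``-x^2 log(x^2)`` with moving-average smoothing.

    ``x`` is the amplitude-normalized input, scaled with sqrt(e) headroom so
    the peak maps to x^2 = 1/e where ``-u log u`` is still monotone: the
    envelope then increases with burst amplitude everywhere and its argmax
    sits at the burst center.  A zero-variance input yields an all-zero
    envelope.
    """
    pcg = np.asarray(pcg, dtype=float)
    window = max(1, int(round(window_ms * 1e-3 * sampling_rate)))
    peak = float(np.max(np.abs(pcg)))
    if peak == 0.0:
        return EnergyEnvelope(np.zeros_like(pcg), window, 0.0)
    xn = pcg / (peak * np.sqrt(np.e))
    x2 = xn**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(x2 > 0, -x2 * np.log(x2), 0.0)
    smoothed = uniform_filter1d(se, window)
    smoothed = np.clip(smoothed, 0.0, None)
    return EnergyEnvelope(smoothed, window, peak)


@dataclass
class S1S2Labels:
    """Per-cycle S1/S2 sample indices (absolute) with diagnostics."""

    cycles: list[dict] = field(default_factory=list)

    @property
    def labeled(self) -> list[dict]:
        return [c for c in self.cycles if not c["flagged"]]

    def s1_indices(self) -> np.ndarray:
        return np.array([c["S1"] for c in self.labeled], dtype=int)

    def s2_indices(self) -> np.ndarray:
        return np.array([c["S2"] for c in self.labeled], dtype=int)


def label_s1_s2(
    envelope: EnergyEnvelope,
    r_peaks: RPeakList,
    threshold_frac: float = 0.30,
    min_separation_ms: float = 60.0,
    max_candidates_per_cycle: int = 3,
    outlier_sds: float = 3.0,
    random_state: int = 0,
) -> S1S2Labels:
    """Cluster envelope peaks into S1 and S2 per cycle.

    Candidate peaks above ``threshold_frac`` of the cycle's envelope maximum
    are expressed as phase-in-cycle (fraction of the R-R interval), pooled
    across cycles and split with k-means (k=2).  Per cycle the strongest
    candidate per cluster is kept; cycles with fewer than two candidates (or
    S1 >= S2) are flagged.  Labels deviating more than ``outlier_sds`` SDs
    from their cluster's phase median are flagged as outliers.
    """
    idx = np.asarray(r_peaks.indices, dtype=int)
    if idx.size < 3:
        raise ValueError("need at least 2 cycles (3 R-peaks)")
    env = envelope.values
    fs = r_peaks.sampling_rate
    min_sep = max(1, int(min_separation_ms * 1e-3 * fs))

    candidates = []  # (cycle, abs_index, phase, strength)
    for ci in range(idx.size - 1):
        start, end = int(idx[ci]), int(idx[ci + 1])
        seg = env[start:end]
        if seg.size < 3 or np.max(seg) <= 0:
            continue
        peaks, _ = sp_signal.find_peaks(
            seg, height=threshold_frac * float(np.max(seg)), distance=min_sep
        )
        # keep only the strongest few: boundary shoulders of wide sound
        # envelopes otherwise pollute the phase clustering
        peaks = peaks[np.argsort(seg[peaks])[::-1][:max_candidates_per_cycle]]
        for p in peaks:
            candidates.append((ci, start + int(p), p / (end - start), float(seg[p])))

    n_cycles = idx.size - 1
    out = S1S2Labels(
        cycles=[
            {"cycle_index": ci, "S1": None, "S2": None, "confidence": 0.0,
             "flagged": True, "outlier": False}
            for ci in range(n_cycles)
        ]
    )
    if len(candidates) < 4:
        return out

    phases = np.array([c[2] for c in candidates]).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(phases)
    assign = km.labels_
    centers = km.cluster_centers_.ravel()
    early_cluster = int(np.argmin(centers))  # ordering rule decides S1 vs S2

    for ci in range(n_cycles):
        rows = [
            (cand, assign[k]) for k, cand in enumerate(candidates) if cand[0] == ci
        ]
        best = {0: None, 1: None}
        for cand, cl in rows:
            if best[cl] is None or cand[3] > best[cl][3]:
                best[cl] = cand
        s1 = best[early_cluster]
        s2 = best[1 - early_cluster]
        if s1 is None or s2 is None or s1[1] >= s2[1]:
            continue
        rec = out.cycles[ci]
        rec.update(
            S1=s1[1], S2=s2[1], flagged=False,
            confidence=min(s1[3], s2[3]) / max(1e-12, max(s1[3], s2[3])),
        )

    # automatic outlier rule replacing a manual visual check
    for cluster, key in ((early_cluster, "S1"), (1 - early_cluster, "S2")):
        ph = np.array(
            [
                (c[key] - idx[c["cycle_index"]])
                / (idx[c["cycle_index"] + 1] - idx[c["cycle_index"]])
                for c in out.labeled
            ]
        )
        if ph.size < 3:
            continue
        med, sd = float(np.median(ph)), float(np.std(ph))
        if sd == 0:
            continue
        for c in out.labeled:
            p = (c[key] - idx[c["cycle_index"]]) / (
                idx[c["cycle_index"] + 1] - idx[c["cycle_index"]]
            )
            if abs(p - med) > outlier_sds * sd:
                c["outlier"] = True
    return out


def position_correlation(
    positions_a: np.ndarray, positions_b: np.ndarray
) -> dict[str, float | str]:
    """Pearson correlation and least-squares line of b on a.

    Returns ``{"pearson_r", "slope", "intercept", "status"}``; zero variance
    in either input yields ``status="undefined"`` with NaN statistics.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired lists with n >= 3")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return {
            "pearson_r": float("nan"),
            "slope": float("nan"),
            "intercept": float("nan"),
            "status": "undefined",
        }
    res = stats.linregress(a, b)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "status": "ok",
    }
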