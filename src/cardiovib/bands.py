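"""Band decomposition of the composite vibration channel.

Zero-phase (forward-backward) Butterworth band-pass filtering splits the
composite channel into the canonical ECG / ULF-SCG / SCG / PCG bands, and an
empirical-mode-decomposition path provides an independent, adaptive
decomposition used to cross-validate the band model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .emd import IMFSet, emd  # noqa: F401  (re-exported)

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "zero_phase_bandpass",
    "decompose_bands",
    "emd",
    "IMFSet",
    "match_imfs_to_bands",
    "spectral_centroid",
    "band_energy_fraction",
]


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band and the Butterworth design order used to isolate it.

    ``order`` is the design order of the underlying filter *before* the
    forward-backward pass, so the effective magnitude response is the squared
    (2*order) response.
    """

    name: str
    low_hz: float
    high_hz: float
    order: int = 2

    def validate(self, sampling_rate: float) -> None:
        if not (0.0 < self.low_hz < self.high_hz < sampling_rate / 2.0):
            raise ValueError(
                f"band {self.name} ({self.low_hz}-{self.high_hz} Hz) invalid "
                f"for sampling rate {sampling_rate} Hz"
            )


#: Canonical bands: reference ECG plus the three vibration bands.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "ECG": BandDefinition("ECG", 1.0, 40.0),
    "ULF-SCG": BandDefinition("ULF-SCG", 1.0, 5.0),
    "SCG": BandDefinition("SCG", 5.0, 30.0),
    "PCG": BandDefinition("PCG", 20.0, 200.0),
}


def zero_phase_bandpass(
    x: np.ndarray, band: BandDefinition, sampling_rate: float
) -> np.ndarray:
    """Forward-backward Butterworth band-pass; zero net phase shift.

    Even-reflection padding of 3x the filter length suppresses edge
    transients on short records.
    """
    band.validate(sampling_rate)
    x = np.asarray(x, dtype=float)
    sos = signal.butter(
        band.order,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if x.shape[0] <= padlen:
        raise ValueError(
            f"input length {x.shape[0]} too short for filter warm-up "
            f"(needs > {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def decompose_bands(
    vibration: np.ndarray,
    ecg: np.ndarray,
    sampling_rate: float,
    bands: dict[str, BandDefinition] | None = None,
) -> dict[str, np.ndarray]:
    """Split channels into the four canonical bands.

    The ECG band filters the ECG channel; the three vibration bands filter
    the composite vibration channel.
    """
    if vibration.shape != ecg.shape:
        raise ValueError("vibration and ecg must have the same length")
    bands = CANONICAL_BANDS if bands is None else bands
    out: dict[str, np.ndarray] = {}
    for name, band in bands.items():
        source = ecg if name == "ECG" else vibration
        out[name] = zero_phase_bandpass(source, band, sampling_rate)
    return out


def spectral_centroid(x: np.ndarray, sampling_rate: float) -> float:
    """Power-weighted mean frequency of a trace (Hz)."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / sampling_rate)
    total = float(np.sum(spec))
    if total == 0.0:
        return 0.0
    return float(np.sum(freqs * spec) / total)


def band_energy_fraction(
    x: np.ndarray, low_hz: float, high_hz: float, sampling_rate: float
) -> float:
    """Fraction of (DC-removed) spectral energy inside [low_hz, high_hz]."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / sampling_rate)
    total = float(np.sum(spec))
    if total == 0.0:
        return 0.0
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    return float(np.sum(spec[mask]) / total)


def match_imfs_to_bands(
    imf_set: IMFSet, bands: dict[str, np.ndarray]
) -> tuple[dict[str, int], np.ndarray, bool]:
    """Assign each band the IMF with maximal absolute Pearson correlation.

    Returns ``(mapping, corr_matrix, injective)``; ``corr_matrix[i, j]`` is
    |r| between band i (insertion order) and IMF j.  The mapping is reported
    even when two bands select the same IMF, flagged via ``injective``.
    """
    names = list(bands)
    n_imfs = len(imf_set.imfs)
    if n_imfs == 0:
        raise ValueError("IMF set is empty")
    corr = np.zeros((len(names), n_imfs))
    for i, name in enumerate(names):
        b = np.asarray(bands[name], dtype=float)
        for j, imf in enumerate(imf_set.imfs):
            if b.shape != imf.shape:
                raise ValueError("band and IMF lengths differ")
            sb, si = np.std(b), np.std(imf)
            if sb == 0.0 or si == 0.0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = abs(float(np.corrcoef(b, imf)[0, 1]))
    mapping = {name: int(np.argmax(corr[i])) for i, name in enumerate(names)}
    injective = len(set(mapping.values())) == len(mapping)
    return mapping, corr, injective
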