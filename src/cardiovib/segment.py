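"""R-wave anchored cycle segmentation and dataset assembly.

R peaks are detected on the reference ECG with a Pan-Tompkins-style pipeline
(band-pass, derivative, squaring, moving-window integration, adaptive
threshold).  Every band trace is then truncated into half-open [R_i, R_{i+1})
windows, zero-padded at the tail to a fixed length of 2048 samples, and
labeled with event sample indices relative to the cycle onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import uniform_filter1d

from .bands import BandDefinition, zero_phase_bandpass
from .simulate import EXTRACTION_TARGETS, CardiacEventSchedule, SyntheticRecording

__all__ = [
    "SEGMENT_LENGTH",
    "FEATURE_BAND",
    "RPeakList",
    "CycleSegment",
    "LabeledDataset",
    "detect_r_peaks",
    "truncate_cycles",
    "attach_labels",
    "curvature_trace",
    "ulf_extrema",
    "segment_recording",
]

#: Fixed single-cycle segment length in samples (2 kHz sampling).
SEGMENT_LENGTH = 2048

#: Which band trace feeds the localizer for each extraction target.
FEATURE_BAND: dict[str, str] = {
    **{f: "SCG" for f in ("MC", "IM", "AO", "IC", "RE", "AC", "MO", "RF")},
    "S1": "PCG",
    "S2": "PCG",
}

_MIN_RR_S = 0.24
_MAX_RR_S = 3.0


@dataclass(frozen=True)
class RPeakList:
    """Detected R-peak sample indices, strictly increasing."""

    indices: np.ndarray
    sampling_rate: float

    def validate(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size < 2:
            return
        rr = np.diff(idx) / self.sampling_rate
        if np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")
        if np.any(rr < _MIN_RR_S) or np.any(rr > _MAX_RR_S):
            raise ValueError(
                f"R-R interval outside [{_MIN_RR_S}, {_MAX_RR_S}] s plausibility bounds"
            )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.indices) / self.sampling_rate

    def __len__(self) -> int:
        return len(self.indices)


def detect_r_peaks(ecg: np.ndarray, sampling_rate: float) -> RPeakList:
    """Pan-Tompkins-style R detector.

    Band-pass 5-15 Hz -> derivative -> squaring -> 150 ms moving-window
    integration -> peak picking with a 240 ms refractory distance and a
    threshold adapted to the integrated-energy distribution; each candidate
    is refined to the local ECG maximum within +/-60 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    fs = sampling_rate
    if ecg.shape[0] < 3 * fs:
        raise ValueError("ECG must be at least 3 s long")
    if np.all(ecg == ecg[0]):
        return RPeakList(indices=np.array([], dtype=int), sampling_rate=fs)

    bp = zero_phase_bandpass(ecg, BandDefinition("QRS", 5.0, 15.0), fs)
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi = uniform_filter1d(sq, max(1, int(0.150 * fs)))

    refractory = int(_MIN_RR_S * fs)
    peaks, props = sp_signal.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return RPeakList(indices=np.array([], dtype=int), sampling_rate=fs)
    heights = mwi[peaks]
    # adaptive threshold: a fraction of the median of the strong peaks
    strong = np.sort(heights)[-max(1, heights.size // 2) :]
    threshold = 0.25 * float(np.median(strong))
    peaks = peaks[heights >= threshold]
    if peaks.size == 0:
        return RPeakList(indices=np.array([], dtype=int), sampling_rate=fs)

    half = int(0.060 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(ecg.shape[0], p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # enforce the refractory bound after refinement
    keep = [0]
    for i in range(1, refined.size):
        if refined[i] - refined[keep[-1]] >= refractory:
            keep.append(i)
    out = RPeakList(indices=refined[keep], sampling_rate=fs)
    out.validate()
    return out


@dataclass
class CycleSegment:
    """One fixed-length R-to-R window across every band."""

    traces: dict[str, np.ndarray]  # band name -> length-L trace
    start: int  # absolute sample of R_i
    end: int  # absolute sample of R_{i+1} (half-open)
    pad_length: int
    truncated: bool
    cycle_index: int
    labels: dict[str, int] = field(default_factory=dict)
    valid: bool = True

    @property
    def cycle_length(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return next(iter(self.traces.values())).shape[0]


def truncate_cycles(
    band_traces: dict[str, np.ndarray],
    r_peaks: RPeakList,
    length: int = SEGMENT_LENGTH,
) -> list[CycleSegment]:
    """Cut every band into [R_i, R_{i+1}) windows of fixed ``length``.

    Short cycles are zero-padded at the tail; cycles longer than ``length``
    are cut at ``length`` and flagged ``truncated``.  The trailing partial
    cycle (after the last R) is dropped.
    """
    idx = np.asarray(r_peaks.indices, dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 R-peaks to form a cycle")
    segments: list[CycleSegment] = []
    for i in range(idx.size - 1):
        start, end = int(idx[i]), int(idx[i + 1])
        clen = end - start
        take = min(clen, length)
        traces = {}
        for name, x in band_traces.items():
            seg = np.zeros(length, dtype=float)
            seg[:take] = np.asarray(x[start : start + take], dtype=float)
            traces[name] = seg
        segments.append(
            CycleSegment(
                traces=traces,
                start=start,
                end=end,
                pad_length=max(0, length - clen),
                truncated=clen > length,
                cycle_index=i,
            )
        )
    return segments


@dataclass
class LabeledDataset:
    """Labeled single-cycle segments ready for localizer training."""

    segments: list[CycleSegment]
    feature_names: tuple[str, ...]
    sampling_rate: float
    n_excluded: int = 0
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.segments)

    def arrays(self, feature: str, band: str | None = None):
        """(X, y) for one feature: segment traces of the feature's band."""
        if feature not in self.feature_names:
            raise KeyError(f"feature {feature!r} not in dataset")
        band = FEATURE_BAND.get(feature, "SCG") if band is None else band
        X = np.stack([s.traces[band] for s in self.segments]).astype(np.float32)
        y = np.array([s.labels[feature] for s in self.segments], dtype=np.float32)
        return X, y


def attach_labels(
    segments: list[CycleSegment],
    schedules: list[CardiacEventSchedule],
    sampling_rate: float,
    targets: tuple[str, ...] = EXTRACTION_TARGETS,
    provenance: str = "",
) -> LabeledDataset:
    """Attach event labels (samples from cycle onset) to each segment.

    A segment is excluded (and counted) when any target lands at or beyond
    the usable window -- past the fixed length for truncated cycles or past
    the actual cycle end otherwise.
    """
    if len(segments) != len(schedules):
        raise ValueError(
            f"{len(segments)} segments vs {len(schedules)} schedules: "
            "one schedule per R-R interval is required"
        )
    kept: list[CycleSegment] = []
    n_excluded = 0
    for seg, sched in zip(segments, schedules):
        limit = min(seg.length, seg.cycle_length)
        labels = {}
        ok = True
        for feat in targets:
            t = sched.event_times.get(feat)
            if t is None:
                ok = False
                break
            li = int(round(t * sampling_rate))
            if not (0 <= li < limit):
                ok = False
                break
            labels[feat] = li
        if ok:
            seg.labels = labels
            kept.append(seg)
        else:
            seg.valid = False
            n_excluded += 1
    return LabeledDataset(
        segments=kept,
        feature_names=tuple(targets),
        sampling_rate=sampling_rate,
        n_excluded=n_excluded,
        provenance=provenance,
    )


def curvature_trace(x: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Discrete curvature kappa = |x''| / (1 + x'^2)^(3/2), labeling aid.

    Central differences in the interior; endpoint values replicated.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    d1 = np.gradient(x, dx)
    d2 = np.gradient(d1, dx)
    kappa = np.abs(d2) / (1.0 + d1**2) ** 1.5
    kappa[0], kappa[-1] = kappa[1], kappa[-2]
    return kappa


def ulf_extrema(
    ulf: np.ndarray, r_peaks: RPeakList
) -> list[dict]:
    """Per-cycle WC (most prominent peak) and WT (subsequent trough).

    Returned dicts carry absolute sample indices and a ``flagged`` marker for
    cycles without a usable extremum pair.  Reported separately from the CNN
    targets.
    """
    ulf = np.asarray(ulf, dtype=float)
    idx = np.asarray(r_peaks.indices, dtype=int)
    out = []
    for i in range(idx.size - 1):
        start, end = int(idx[i]), int(idx[i + 1])
        seg = ulf[start:end]
        res = {"cycle_index": i, "WC": None, "WT": None, "flagged": True}
        peaks, pprops = sp_signal.find_peaks(seg, prominence=0.0)
        if peaks.size:
            wc = peaks[int(np.argmax(pprops["prominences"]))]
            troughs, tprops = sp_signal.find_peaks(-seg, prominence=0.0)
            after = troughs > wc
            if np.any(after):
                cand = troughs[after]
                prom = tprops["prominences"][after]
                wt = cand[int(np.argmax(prom))]
                res.update(WC=start + int(wc), WT=start + int(wt), flagged=False)
        out.append(res)
    return out


def segment_recording(
    recording: SyntheticRecording,
    band_traces: dict[str, np.ndarray],
    length: int = SEGMENT_LENGTH,
    use_true_onsets: bool = False,
) -> LabeledDataset:
    """simulate -> detect -> truncate -> label in one call.

    With ``use_true_onsets`` the stored ground-truth cycle onsets anchor the
    segments (exact label round-trip); otherwise the detector runs on the
    ECG channel and detected cycles are aligned to the truth schedules by
    nearest onset.
    """
    fs = recording.sampling_rate
    if use_true_onsets:
        onsets = recording.cycle_start_samples
        peaks = RPeakList(indices=onsets, sampling_rate=fs)
        schedules = list(recording.schedules)
        # append a virtual end marker so the last full cycle is kept
        last_end = onsets[-1] + int(round(recording.schedules[-1].period_T * fs))
        peaks = RPeakList(
            indices=np.concatenate([onsets, [last_end]]), sampling_rate=fs
        )
    else:
        peaks = detect_r_peaks(recording.ecg, fs)
        true_onsets = recording.cycle_start_samples
        matched_scheds = []
        matched_idx = []
        for i in range(len(peaks) - 1):
            d = np.abs(true_onsets - peaks.indices[i])
            j = int(np.argmin(d))
            if d[j] <= int(0.05 * fs):
                matched_scheds.append(recording.schedules[j])
                matched_idx.append(i)
        schedules = matched_scheds
        if len(matched_idx) < len(peaks) - 1:
            keep = set(matched_idx)
            segs = truncate_cycles(band_traces, peaks, length)
            segs = [s for i, s in enumerate(segs) if i in keep]
            return attach_labels(segs, schedules, fs, provenance="detected")
    segs = truncate_cycles(band_traces, peaks, length)
    return attach_labels(
        segs, schedules, fs, provenance="truth" if use_true_onsets else "detected"
    )
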