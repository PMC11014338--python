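"""Readers and writers for recordings, annotations and datasets.

Recordings travel as two-channel CSV with ``#``-prefixed header lines
(sampling rate, channel names) or as an HDF5 container with ``/signals``
and ``/annotations`` groups.  Labeled datasets use HDF5 (``/segments``,
``/labels``, ``/meta``) with a CSV export for the labels.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .segment import FEATURE_BAND, CycleSegment, LabeledDataset
from .simulate import SyntheticRecording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_recording_h5",
    "write_dataset_h5",
    "read_dataset_h5",
    "export_labels_csv",
]


def write_recording_csv(recording: SyntheticRecording, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate:g}\n")
        fh.write("# channels=ecg,vibration\n")
        writer = csv.writer(fh)
        writer.writerow(["ecg", "vibration"])
        for e, v in zip(recording.ecg, recording.vibration):
            writer.writerow([f"{e:.9g}", f"{v:.9g}"])


def read_recording_csv(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Returns (ecg, vibration, sampling_rate)."""
    path = Path(path)
    fs = None
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "sampling_rate_hz":
                fs = float(val)
    if fs is None:
        raise ValueError(f"{path}: missing '# sampling_rate_hz=' header")
    df = pd.read_csv(path, skiprows=header_lines)
    return df["ecg"].to_numpy(float), df["vibration"].to_numpy(float), fs


def write_annotations_csv(recording: SyntheticRecording, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cycle_index", "event", "sample_index"])
        writer.writerows(recording.annotations())


def read_annotations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_recording_h5(recording: SyntheticRecording, path) -> None:
    with h5py.File(path, "w") as fh:
        sig = fh.create_group("signals")
        sig.create_dataset("ecg", data=recording.ecg)
        sig.create_dataset("vibration", data=recording.vibration)
        sig.attrs["sampling_rate_hz"] = recording.sampling_rate
        ann = fh.create_group("annotations")
        rows = recording.annotations()
        ann.create_dataset("cycle_index", data=[r[0] for r in rows])
        ann.create_dataset(
            "event", data=np.array([r[1] for r in rows], dtype="S4")
        )
        ann.create_dataset("sample_index", data=[r[2] for r in rows])
        ann.create_dataset("r_peak_times", data=recording.r_peak_times)


def write_dataset_h5(dataset: LabeledDataset, path) -> None:
    bands = sorted({b for s in dataset.segments for b in s.traces})
    n = len(dataset.segments)
    L = dataset.segments[0].length if n else 0
    seg_arr = np.zeros((n, len(bands), L), dtype=np.float32)
    for i, seg in enumerate(dataset.segments):
        for j, b in enumerate(bands):
            seg_arr[i, j] = seg.traces[b]
    labels = np.array(
        [[s.labels[f] for f in dataset.feature_names] for s in dataset.segments],
        dtype=np.int64,
    )
    with h5py.File(path, "w") as fh:
        fh.create_dataset("segments", data=seg_arr)
        fh.create_dataset("labels", data=labels)
        meta = fh.create_group("meta")
        meta.attrs["sampling_rate_hz"] = dataset.sampling_rate
        meta.attrs["bands"] = ",".join(bands)
        meta.attrs["features"] = ",".join(dataset.feature_names)
        meta.attrs["n_excluded"] = dataset.n_excluded
        meta.attrs["provenance"] = dataset.provenance
        meta.create_dataset("start", data=[s.start for s in dataset.segments])
        meta.create_dataset("end", data=[s.end for s in dataset.segments])


def read_dataset_h5(path) -> LabeledDataset:
    with h5py.File(path, "r") as fh:
        seg_arr = fh["segments"][...]
        labels = fh["labels"][...]
        meta = fh["meta"]
        fs = float(meta.attrs["sampling_rate_hz"])
        bands = meta.attrs["bands"].split(",")
        features = tuple(meta.attrs["features"].split(","))
        n_excluded = int(meta.attrs["n_excluded"])
        provenance = str(meta.attrs["provenance"])
        starts = meta["start"][...]
        ends = meta["end"][...]
    segments = []
    for i in range(seg_arr.shape[0]):
        traces = {b: seg_arr[i, j].astype(float) for j, b in enumerate(bands)}
        seg = CycleSegment(
            traces=traces,
            start=int(starts[i]),
            end=int(ends[i]),
            pad_length=max(0, seg_arr.shape[2] - (int(ends[i]) - int(starts[i]))),
            truncated=(int(ends[i]) - int(starts[i])) > seg_arr.shape[2],
            cycle_index=i,
            labels={f: int(labels[i, j]) for j, f in enumerate(features)},
        )
        segments.append(seg)
    return LabeledDataset(
        segments=segments,
        feature_names=features,
        sampling_rate=fs,
        n_excluded=n_excluded,
        provenance=provenance,
    )


def export_labels_csv(dataset: LabeledDataset, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cycle_index", "event", "sample_index"])
        for seg in dataset.segments:
            for feat in dataset.feature_names:
                writer.writerow([seg.cycle_index, feat, seg.labels[feat]])
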