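"""On-disk containers for raw signals and TFR datasets.

Schemas (NPZ archives, one sample per file):

* raw signal  — ``iq`` complex 1-D array, ``fs_hz`` scalar, ``subject_id``
  string, ``label`` int;
* TFR sample  — ``values`` (T, F) float, ``freq_axis`` (F,) float,
  ``label`` int, ``subject_id`` string, ``channel_semantics`` string.

A dataset directory additionally carries ``manifest.csv`` listing file,
label and subject per sample, for leave-one-subject-out grouping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tfr_pipeline import RadarSegment, TFRSample

__all__ = ["save_radar_segment", "load_radar_segment",
           "save_tfr_sample", "load_tfr_sample",
           "write_tfr_dataset", "read_tfr_dataset"]


def save_radar_segment(path: str | Path, seg: RadarSegment) -> None:
    np.savez(path, iq=seg.samples, fs_hz=np.float64(seg.sampling_rate),
             subject_id=np.str_(seg.subject_id), label=np.int64(seg.label))


def load_radar_segment(path: str | Path) -> RadarSegment:
    with np.load(path, allow_pickle=False) as data:
        return RadarSegment(samples=data["iq"], sampling_rate=float(data["fs_hz"]),
                            subject_id=str(data["subject_id"]),
                            label=int(data["label"]))


def save_tfr_sample(path: str | Path, sample: TFRSample) -> None:
    np.savez(path, values=sample.values, freq_axis=sample.freq_axis,
             label=np.int64(sample.label), subject_id=np.str_(sample.subject_id),
             channel_semantics=np.str_(sample.channel_semantics))


def load_tfr_sample(path: str | Path) -> TFRSample:
    with np.load(path, allow_pickle=False) as data:
        return TFRSample(values=data["values"], freq_axis=data["freq_axis"],
                         label=int(data["label"]),
                         channel_semantics=str(data["channel_semantics"]),
                         subject_id=str(data["subject_id"]))


def write_tfr_dataset(directory: str | Path, samples: Sequence[TFRSample]) -> Path:
    """Write samples as sample_00000.npz ... plus a manifest.csv; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"sample_{i:05d}.npz"
        save_tfr_sample(directory / name, s)
        rows.append({"file": name, "label": s.label, "subject_id": s.subject_id})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_tfr_dataset(directory: str | Path) -> list[TFRSample]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [load_tfr_sample(directory / row.file) for row in manifest.itertuples()]
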