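"""Artifact I/O: 16-bit map images, numeric grids, and SNIRF files.

Feature maps are persisted twice: a lossless ``.npz`` with the raw float
grids (the representation the classifier consumes) and a 16-bit grayscale
PNG rendering of the [0, 1]-scaled grid for visual inspection.  A manifest
CSV ties every sample to its subject, group, task, trial and feature kind.

The SNIRF writer emits a minimal continuous-wave amplitude file
(format version 1.0: ``/nirs/data1`` time series, one measurement-list
entry per channel and wavelength, probe geometry, required metadata tags);
it exists so synthetic cohorts can be exchanged with standard fNIRS
toolchains, and is validated in the tests against an independent reader.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .features import ChannelLayout, FeatureSet
from .preprocess import OpticalRecording

__all__ = [
    "save_map_png",
    "save_feature_set",
    "write_snirf",
    "read_snirf",
]


def save_map_png(grid: np.ndarray, path: str | Path,
                 scale: tuple[float, float] | None = None) -> None:
    """Write a scalar grid as 16-bit grayscale PNG.

    ``scale`` defaults to the grid's own (min, max); the PNG is for
    display only, numeric analysis should use the lossless grids.
    """
    g = np.asarray(grid, dtype=float)
    lo, hi = scale if scale is not None else (float(g.min()), float(g.max()))
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((g - lo) / (hi - lo), 0.0, 1.0)
    img = (scaled * 65535.0).round().astype(np.uint16)
    Image.fromarray(img).save(Path(path))


def save_feature_set(fs: FeatureSet, out_dir: str | Path,
                     write_png: bool = False) -> Path:
    """Persist a task's feature set: grids (.npz), manifest.csv and
    optionally one PNG per image."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / f"{fs.task}_grids.npz", **fs.images)
    rows = []
    for name, stack in fs.images.items():
        for i, meta in fs.meta.iterrows():
            rows.append({
                "sample": f"{fs.task}_{name}_{i}",
                "subject": meta["subject"],
                "group": "impaired" if meta["label"] == 1 else "control",
                "task": fs.task,
                "trial": meta["trial"],
                "feature": name,
                "path": f"{fs.task}_grids.npz:{name}[{i}]",
            })
            if write_png:
                png = out / f"{fs.task}_{name}_s{meta['subject']}_t{meta['trial']}.png"
                save_map_png(stack[i], png)
                rows[-1]["png"] = png.name
    pd.DataFrame(rows).to_csv(out / f"{fs.task}_manifest.csv", index=False)
    return out


# --------------------------------------------------------------------- #
# Minimal SNIRF (HDF5) continuous-wave amplitude I/O


def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=value.encode())


def write_snirf(path: str | Path, rec: OpticalRecording,
                layout: ChannelLayout | None = None,
                subject_id: str = "anonymous") -> None:
    """Write an :class:`OpticalRecording` as a CW-amplitude SNIRF file.

    Optical density is converted back to relative intensity
    (``amplitude = exp(-dOD)``, unit baseline), the representation SNIRF
    stores for continuous-wave data.  Channel positions come from
    ``layout`` (default montage when omitted), placed in a plane in mm.
    """
    layout = layout or ChannelLayout.default_48()
    if layout.n_channels != len(rec.channel_ids):
        raise ValueError("layout does not match the recording's channels")
    n_ch, n_samp = rec.od.shape[1], rec.od.shape[2]
    amplitude = np.exp(-rec.od)  # (2, n_ch, n_samp)
    series = np.concatenate([amplitude[0].T, amplitude[1].T], axis=1)

    with h5py.File(Path(path), "w") as f:
        _str_ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", subject_id)
        _str_ds(meta, "MeasurementDate", "2020-01-01")
        _str_ds(meta, "MeasurementTime", "00:00:00")
        _str_ds(meta, "LengthUnit", "mm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm, float))
        # Plane montage: unit square scaled to a 90 x 60 mm prefrontal band,
        # with a co-located detector 30 mm lateral of each source.
        src = layout.positions * np.array([90.0, 60.0])
        det = src + np.array([30.0, 0.0])
        probe.create_dataset("sourcePos3D", data=np.column_stack([src, np.zeros(n_ch)]))
        probe.create_dataset("detectorPos3D", data=np.column_stack([det, np.zeros(n_ch)]))
        src_names = [f"S{i + 1}" for i in range(n_ch)]
        det_names = [f"D{i + 1}" for i in range(n_ch)]
        probe.create_dataset("sourceLabels", data=np.array(src_names, dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(det_names, dtype="S"))

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_samp) / rec.fs)
        for col in range(2 * n_ch):
            wl = col // n_ch
            ch = col % n_ch
            ml = data.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=np.int32(ch + 1))
            ml.create_dataset("detectorIndex", data=np.int32(ch + 1))
            ml.create_dataset("wavelengthIndex", data=np.int32(wl + 1))
            ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=np.int32(1))


def read_snirf(path: str | Path) -> OpticalRecording:
    """Read a CW-amplitude SNIRF file back into an
    :class:`OpticalRecording` (optical density, both wavelengths)."""
    with h5py.File(Path(path), "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"], float))
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        src = [int(np.asarray(data[k]["sourceIndex"])) for k in ml_names]
        wli = [int(np.asarray(data[k]["wavelengthIndex"])) for k in ml_names]
    fs = 1.0 / np.median(np.diff(time))
    n_ch = len(set(src))
    od = np.empty((2, n_ch, series.shape[0]))
    for col, (s, w) in enumerate(zip(src, wli)):
        od[w - 1, s - 1] = -np.log(series[:, col])
    channel_ids = [f"CH{i + 1:02d}" for i in range(n_ch)]
    return OpticalRecording(od=od, fs=float(fs), channel_ids=channel_ids,
                            wavelengths_nm=wavelengths)
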