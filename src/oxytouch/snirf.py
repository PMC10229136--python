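"""Minimal SNIRF (Shared Near-Infrared Spectroscopy Format) reader/writer.

Covers the subset of the HDF5-based community standard this pipeline
needs: a single ``/nirs`` block with one data element, per-column
measurement lists (source, detector, wavelength, data type), a probe group
with wavelengths and schematic optode positions, and basic metadata tags.
Raw intensity columns use dataType 1; optical density and chromophore
concentrations use the processed dataType 99999 with dataTypeLabel
``dOD`` / ``HbO`` / ``HbR``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .montage import DEFAULT_ROI_MAP, Montage
from .recording import FnirsRecording

__all__ = ["write_snirf", "read_snirf", "SnirfError"]

_PROCESSED = 99999
_LABELS = {"HbO": "HbO", "HbR": "HbR"}


class SnirfError(ValueError):
    """Malformed SNIRF content; the message names the offending HDF5 path."""


def _str(value: str) -> np.bytes_:
    return np.bytes_(value.encode())


def write_snirf(
    path: str | Path,
    recordings: list[FnirsRecording],
    montage: Optional[Montage] = None,
    subject_id: str = "unknown",
) -> Path:
    """Write one or more recordings (same montage/rate) to a SNIRF file.

    Each recording contributes one column block (one column per channel);
    intensity/OD recordings must carry their wavelength.
    """
    path = Path(path)
    if not recordings:
        raise ValueError("no recordings to write")
    first = recordings[0]
    montage = montage or first.montage
    if montage is None:
        raise ValueError("a montage is required to write SNIRF")
    for r in recordings:
        if r.sampling_rate != first.sampling_rate or r.n_samples != first.n_samples:
            raise ValueError("all recordings must share sampling rate and length")

    wavelengths = sorted({r.wavelength for r in recordings if r.wavelength is not None}) or [760.0, 850.0]
    n = first.n_samples
    time = np.arange(n) / first.sampling_rate

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_str("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=_str(subject_id))
        meta.create_dataset("MeasurementDate", data=_str("unknown"))
        meta.create_dataset("MeasurementTime", data=_str("unknown"))
        meta.create_dataset("LengthUnit", data=_str("cm"))
        meta.create_dataset("TimeUnit", data=_str("s"))
        meta.create_dataset("FrequencyUnit", data=_str("Hz"))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        n_src = max(c[1] for c in montage.channels)
        n_det = max(c[2] for c in montage.channels)
        # schematic positions (not a head registration)
        probe.create_dataset(
            "sourcePos2D", data=np.column_stack([np.arange(n_src), np.zeros(n_src)]).astype(float)
        )
        probe.create_dataset(
            "detectorPos2D", data=np.column_stack([np.arange(n_det), np.ones(n_det)]).astype(float)
        )

        data = nirs.create_group("data1")
        columns = np.concatenate([r.data for r in recordings], axis=0).T  # time x columns
        data.create_dataset("dataTimeSeries", data=columns)
        data.create_dataset("time", data=time)

        src_of = {c[0]: c[1] for c in montage.channels}
        det_of = {c[0]: c[2] for c in montage.channels}
        j = 1
        for r in recordings:
            for cid in r.channel_ids:
                ml = data.create_group(f"measurementList{j}")
                ml.create_dataset("sourceIndex", data=np.int32(src_of[cid]))
                ml.create_dataset("detectorIndex", data=np.int32(det_of[cid]))
                if r.signal_kind == "intensity":
                    ml.create_dataset("dataType", data=np.int32(1))
                    ml.create_dataset("wavelengthIndex", data=np.int32(wavelengths.index(r.wavelength) + 1))
                else:
                    ml.create_dataset("dataType", data=np.int32(_PROCESSED))
                    label = "dOD" if r.signal_kind == "od" else _LABELS[r.chromophore]
                    ml.create_dataset("dataTypeLabel", data=_str(label))
                    if r.wavelength is not None:
                        ml.create_dataset("wavelengthIndex", data=np.int32(wavelengths.index(r.wavelength) + 1))
                ml.create_dataset("dataTypeIndex", data=np.int32(1))
                j += 1
    return path


def _read_scalar(group: h5py.Group, name: str, path: str):
    if name not in group:
        raise SnirfError(f"missing {path}/{name}")
    return group[name][()]


def read_snirf(path: str | Path) -> tuple[list[FnirsRecording], Montage]:
    """Read a SNIRF file back into recordings plus the montage.

    Columns are grouped into recordings by (signal kind, chromophore,
    wavelength); channel ids are assigned in column order within each
    group.  The default ROI partition is attached when the channel count
    matches the study probe (26 channels).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise SnirfError("missing /nirs")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise SnirfError("missing /nirs/data1")
        data = nirs["data1"]
        if "time" not in data:
            raise SnirfError("missing sampling information at /nirs/data1/time")
        time = np.asarray(data["time"][()], dtype=float).ravel()
        if time.size == 2:  # [start, dt] short form
            fs = 1.0 / time[1]
        elif time.size > 2:
            dt = np.diff(time)
            if dt.min() <= 0:
                raise SnirfError("non-monotone time vector at /nirs/data1/time")
            fs = 1.0 / float(np.median(dt))
        else:
            raise SnirfError("degenerate time vector at /nirs/data1/time")
        if "dataTimeSeries" not in data:
            raise SnirfError("missing /nirs/data1/dataTimeSeries")
        series = np.asarray(data["dataTimeSeries"][()], dtype=float)

        wavelengths = np.atleast_1d(
            np.asarray(nirs["probe"]["wavelengths"][()], dtype=float)
        ) if "probe" in nirs and "wavelengths" in nirs["probe"] else np.array([])

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList") :]),
        )
        if len(ml_names) != series.shape[1]:
            raise SnirfError(
                f"/nirs/data1 has {series.shape[1]} columns but {len(ml_names)} measurementList entries"
            )

        column_meta = []
        for k in ml_names:
            ml = data[k]
            src = int(_read_scalar(ml, "sourceIndex", f"/nirs/data1/{k}"))
            det = int(_read_scalar(ml, "detectorIndex", f"/nirs/data1/{k}"))
            dtype = int(_read_scalar(ml, "dataType", f"/nirs/data1/{k}"))
            wl = None
            if "wavelengthIndex" in ml and wavelengths.size:
                wl = float(wavelengths[int(ml["wavelengthIndex"][()]) - 1])
            if dtype == 1:
                kind, chrom = "intensity", None
            elif dtype == _PROCESSED:
                label = ml["dataTypeLabel"][()]
                label = label.decode() if isinstance(label, bytes) else str(label)
                if label == "dOD":
                    kind, chrom = "od", None
                elif label in _LABELS:
                    kind, chrom = "concentration", label
                else:
                    raise SnirfError(f"unsupported dataTypeLabel {label!r} at /nirs/data1/{k}")
            else:
                raise SnirfError(f"unsupported dataType {dtype} at /nirs/data1/{k}")
            column_meta.append((kind, chrom, wl, src, det))

    # group columns into recordings
    groups: dict[tuple, list[int]] = {}
    for i, (kind, chrom, wl, _s, _d) in enumerate(column_meta):
        groups.setdefault((kind, chrom, wl), []).append(i)

    first_cols = next(iter(groups.values()))
    channels = tuple(
        (j + 1, column_meta[ci][3], column_meta[ci][4]) for j, ci in enumerate(first_cols)
    )
    roi_map = dict(DEFAULT_ROI_MAP) if len(channels) == 26 else {}
    montage = Montage(channels=channels, roi_map=roi_map)

    recordings = []
    for (kind, chrom, wl), cols in groups.items():
        recordings.append(
            FnirsRecording(
                data=series[:, cols].T,
                sampling_rate=fs,
                signal_kind=kind,
                chromophore=chrom,
                wavelength=wl,
                montage=montage if len(cols) == len(channels) else None,
            )
        )
    return recordings, montage
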