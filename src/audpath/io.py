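"""File I/O for pipeline artifacts.

Conventions: BIDS-style TSV for events and design matrices, CSV for tabular
data, NIfTI-1 for volumes and masks (integer labels plus a JSON sidecar
naming label -> region/hemisphere), raw float32 binary plus a JSON header
for electrophysiology recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .abr import ClickEvents, RawRecording
from .fmri_glm import RoiMask, VolumeSeries
from .physio import PhysioTrace


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tabular


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ParseError(f"{path}: cohort table missing 'participant_id'")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ParseError(f"events table missing columns {sorted(missing)}")
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing events columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# ABR


def write_raw_recording(raw: RawRecording, stem) -> tuple[Path, Path]:
    """Write channels as interleaved float32 binary + JSON header."""
    stem = Path(stem)
    data = np.stack(
        [raw.cz, raw.left_mastoid, raw.right_mastoid]
    ).astype("<f4")
    bin_path = stem.with_suffix(".dat")
    data.T.tofile(bin_path)
    header = {
        "fs_hz": raw.fs_hz,
        "channels": ["cz", "left_mastoid", "right_mastoid"],
        "dtype": "<f4",
        "order": "sample-major",
        "n_samples": int(data.shape[1]),
    }
    hdr_path = stem.with_suffix(".json")
    hdr_path.write_text(json.dumps(header, indent=1))
    return bin_path, hdr_path


def read_raw_recording(stem) -> RawRecording:
    stem = Path(stem)
    hdr_path = stem.with_suffix(".json")
    try:
        header = json.loads(hdr_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{hdr_path}: invalid JSON header: {exc}") from exc
    for key in ("fs_hz", "channels", "dtype", "n_samples"):
        if key not in header:
            raise ParseError(f"{hdr_path}: header missing field {key!r}")
    raw = np.fromfile(stem.with_suffix(".dat"), dtype=header["dtype"])
    n = header["n_samples"]
    mat = raw.reshape(n, len(header["channels"])).T.astype(float)
    channels = dict(zip(header["channels"], mat))
    return RawRecording(
        fs_hz=float(header["fs_hz"]),
        cz=channels["cz"],
        left_mastoid=channels["left_mastoid"],
        right_mastoid=channels["right_mastoid"],
    )


def write_click_events(events: ClickEvents, path) -> None:
    pd.DataFrame({"onset_s": events.onsets_s, "ear": events.ears}).to_csv(
        path, sep="\t", index=False
    )


def read_click_events(path) -> ClickEvents:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "ear"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return ClickEvents(
        onsets_s=df["onset_s"].to_numpy(float),
        ears=df["ear"].to_numpy(str),
    )


# ---------------------------------------------------------------------------
# physio


def write_physio(trace: PhysioTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_physio(path) -> PhysioTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "cardiac", "respiratory"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / np.median(np.diff(t))
    return PhysioTrace(
        fs_hz=float(round(fs, 6)),
        cardiac=df["cardiac"].to_numpy(float),
        respiratory=df["respiratory"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# NIfTI volumes and masks


def write_volume(vol: VolumeSeries, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(
        (vol.voxel_size_mm,) * 3 + ((1.0,) if vol.data.ndim == 4 else ())
    )
    nib.save(img, str(path))


def read_volume(path, run_lengths=None) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    zooms = img.header.get_zooms()
    return VolumeSeries(
        data,
        voxel_size_mm=float(zooms[0]),
        affine=np.asarray(img.affine),
        run_lengths=run_lengths,
    )


def write_mask(mask: RoiMask, path) -> None:
    """Integer-label NIfTI plus a ``.labels.json`` sidecar."""
    path = Path(path)
    affine = mask.affine if mask.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), affine), str(path))
    sidecar = {
        str(lab): {"region": reg, "hemisphere": hemi}
        for lab, (reg, hemi) in mask.label_names.items()
    }
    sidecar_path = path.with_name(path.name.split(".")[0] + ".labels.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def read_mask(path) -> RoiMask:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    sidecar_path = path.with_name(path.name.split(".")[0] + ".labels.json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except FileNotFoundError:
        raise ParseError(f"missing label sidecar: {sidecar_path}")
    label_names = {
        int(k): (v["region"], v["hemisphere"]) for k, v in sidecar.items()
    }
    return RoiMask(
        labels=labels, label_names=label_names, affine=np.asarray(img.affine)
    )
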