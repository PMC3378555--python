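"""Serialization: events TSV, voxel/estimate tables, and BOLD containers."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from retinowm.protocol import BoldSeries, TaskTiming


def write_events_tsv(trials: pd.DataFrame, path) -> None:
    """Write a trial table as a BIDS-style events TSV plus a JSON sidecar.

    ``onset``/``duration`` are in seconds (S1 onset to S2 offset, or to the
    modeled catch window end); the task-specific columns ride alongside.
    The sidecar (same stem, ``.json``) carries the timing parameters and
    session length so the table round-trips losslessly.
    """
    path = Path(path)
    timing: TaskTiming = trials.attrs["timing"]
    out = trials.copy()
    out.insert(0, "onset", out["s1_onset_ms"] / 1000.0)
    end_ms = np.where(
        out["trial_type"] == "catch",
        out["s1_onset_ms"] + timing.stim_ms + timing.median_jitter_ms,
        out["s2_onset_ms"] + timing.stim_ms,
    )
    out.insert(1, "duration", (end_ms - out["s1_onset_ms"]) / 1000.0)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")
    sidecar = {
        "session_ms": trials.attrs["session_ms"],
        "timing": asdict(timing),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_events_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values="n/a")
    df = df.drop(columns=["onset", "duration"])
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df.attrs["session_ms"] = sidecar["session_ms"]
    df.attrs["timing"] = TaskTiming(**sidecar["timing"])
    return df


def write_bold_nifti(series: BoldSeries, path) -> None:
    """Write a BoldSeries as 4-D NIfTI on a 1-voxel-thick grid.

    Data are laid out (n_voxels, 1, 1, n_volumes); the sidecar JSON (same
    stem) carries volume interval, voxel ids and offsets.
    """
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(
        series.data[:, np.newaxis, np.newaxis, :].astype(np.float64), affine=np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, series.volume_ms / 1000.0))
    nib.save(img, path)
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(series.to_dict_header(), indent=2)
    )


def read_bold_nifti(path) -> BoldSeries:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)[:, 0, 0, :]
    header = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return BoldSeries(
        data=data,
        volume_ms=header["volume_ms"],
        voxel_ids=np.array(header["voxel_ids"]),
        onset_offset_ms=header["onset_offset_ms"],
    )


def write_bold_flat(series: BoldSeries, path) -> None:
    """Raw little-endian float64 matrix with a JSON header alongside."""
    path = Path(path)
    series.data.astype("<f8").tofile(path)
    path.with_suffix(".json").write_text(json.dumps(series.to_dict_header(), indent=2))


def read_bold_flat(path) -> BoldSeries:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype="<f8").reshape(header["n_voxels"], header["n_volumes"])
    return BoldSeries(
        data=data,
        volume_ms=header["volume_ms"],
        voxel_ids=np.array(header["voxel_ids"]),
        onset_offset_ms=header["onset_offset_ms"],
    )


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="n/a")
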