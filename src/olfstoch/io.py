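"""Serialization of response tensors: HDF5 and long-format CSV."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .tensor import ResponseTensor


def save_hdf5(tensor: ResponseTensor, path) -> None:
    """Write a tensor to HDF5: one dataset plus metadata attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("dF_F", data=tensor.values)
        ds.attrs["frame_duration"] = tensor.frame_duration
        ds.attrs["odor_onset_frame"] = tensor.odor_onset_frame
        ds.attrs["labels"] = [str(x) for x in tensor.labels]


def load_hdf5(path) -> ResponseTensor:
    with h5py.File(path, "r") as f:
        if "dF_F" not in f:
            raise ValueError(f"{path}: missing 'dF_F' dataset")
        ds = f["dF_F"]
        required = ("frame_duration", "odor_onset_frame", "labels")
        missing = [a for a in required if a not in ds.attrs]
        if missing:
            raise ValueError(f"{path}: missing attributes {missing}")
        return ResponseTensor(
            values=ds[()],
            frame_duration=float(ds.attrs["frame_duration"]),
            odor_onset_frame=int(ds.attrs["odor_onset_frame"]),
            labels=[
                x.decode() if isinstance(x, bytes) else str(x)
                for x in ds.attrs["labels"]
            ],
        )


def to_long_csv(tensor: ResponseTensor, path) -> None:
    """Write the tensor as tidy rows (cell, odor, trial, frame, dF_F).

    Metadata travels in '#key=value' header comments so the round trip is
    lossless.
    """
    n_c, n_o, n_t, n_f = tensor.values.shape
    idx = np.indices((n_c, n_o, n_t, n_f)).reshape(4, -1)
    df = pd.DataFrame(
        {
            "cell": idx[0],
            "odor": idx[1],
            "trial": idx[2],
            "frame": idx[3],
            "dF_F": tensor.values.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"#frame_duration={tensor.frame_duration!r}\n")
        fh.write(f"#odor_onset_frame={tensor.odor_onset_frame}\n")
        fh.write(f"#labels={','.join(str(x) for x in tensor.labels)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def from_long_csv(path) -> ResponseTensor:
    """Load a long-format CSV, validating that the (cell, odor, trial,
    frame) grid is complete — a missing trial is an error, not padding."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    required_cols = {"cell", "odor", "trial", "frame", "dF_F"}
    if not required_cols.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required_cols - set(df.columns)}")
    for key in ("frame_duration", "odor_onset_frame"):
        if key not in meta:
            raise ValueError(f"{path}: missing '#{key}=' metadata header")
    dims = [df[c].max() + 1 for c in ("cell", "odor", "trial", "frame")]
    expected = int(np.prod(dims))
    if len(df) != expected or df.duplicated(["cell", "odor", "trial", "frame"]).any():
        raise ValueError(
            f"{path}: incomplete grid — expected {expected} unique rows, "
            f"found {len(df)}"
        )
    values = np.full(dims, np.nan)
    values[df.cell, df.odor, df.trial, df.frame] = df.dF_F
    labels = meta.get("labels", "").split(",") if meta.get("labels") else []
    return ResponseTensor(
        values=values,
        frame_duration=float(meta["frame_duration"]),
        odor_onset_frame=int(meta["odor_onset_frame"]),
        labels=labels,
    )


def load_dataset(path, format: str | None = None) -> ResponseTensor:
    """Load a response tensor; format inferred from the suffix if omitted.

    Supported formats: ``hdf5`` and long-format ``csv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {"h5": "hdf5", "hdf5": "hdf5", "csv": "csv"}.get(
            path.suffix.lstrip("."), path.suffix.lstrip(".")
        )
    if format == "hdf5":
        return load_hdf5(path)
    if format == "csv":
        return from_long_csv(path)
    if format == "nwb":
        raise ValueError(
            "NWB loading requires pynwb, which this installation does not "
            "provide; convert the recording to the HDF5 or long-CSV layout"
        )
    raise ValueError(f"unknown format {format!r}")
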