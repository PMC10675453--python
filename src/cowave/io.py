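"""Readers and writers: case CSV pairs, segment HDF5 containers, YAML configs.

A case is interchanged as two CSV files — ``<case_id>.csv`` with columns
``time_s, ppg, art`` and ``<case_id>_co.csv`` with columns ``time_s, co`` —
with empty cells standing for missing samples. Segment collections use one
HDF5 container.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from cowave.errors import ValidationError
from cowave.preprocessing import Segment
from cowave.synthetic import WaveformRecord


def write_case_csv(record: WaveformRecord, directory) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(record.n_samples) / record.sampling_rate
    wave_path = directory / f"{record.case_id}.csv"
    pd.DataFrame({"time_s": t, "ppg": record.ppg, "art": record.art}).to_csv(
        wave_path, index=False, float_format="%.6f"
    )
    co_path = directory / f"{record.case_id}_co.csv"
    co_t = record.co_sample_indices / record.sampling_rate
    co_df = pd.DataFrame({"time_s": co_t, "co": record.co_values})
    if record.true_co is not None:
        co_df["true_co"] = record.true_co
    co_df.to_csv(co_path, index=False, float_format="%.6f")
    return wave_path, co_path


def read_case_csv(path, co_path=None) -> WaveformRecord:
    """Read a case CSV pair; empty cells become NaN (missing-value sentinel)."""
    path = Path(path)
    if co_path is None:
        co_path = path.with_name(path.stem + "_co.csv")
    df = pd.read_csv(path)
    for col in ("time_s", "ppg", "art"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path.name}: time_s must be strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))
    co_df = pd.read_csv(co_path)
    for col in ("time_s", "co"):
        if col not in co_df.columns:
            raise ValidationError(f"{Path(co_path).name}: missing required column {col!r}")
    indices = np.round(co_df["time_s"].to_numpy(float) * fs).astype(np.int64)
    true_co = co_df["true_co"].to_numpy(float) if "true_co" in co_df.columns else None
    return WaveformRecord(
        case_id=path.stem,
        sampling_rate=fs,
        ppg=df["ppg"].to_numpy(float),
        art=df["art"].to_numpy(float),
        co_values=co_df["co"].to_numpy(float),
        co_sample_indices=indices,
        true_co=true_co,
    )


def read_case_dir(directory) -> List[WaveformRecord]:
    """Read every case CSV pair in a directory (sorted by case id)."""
    directory = Path(directory)
    paths = sorted(p for p in directory.glob("*.csv") if not p.stem.endswith("_co"))
    if not paths:
        raise ValidationError(f"no case CSV files found in {directory}")
    return [read_case_csv(p) for p in paths]


def write_segments_h5(segments: List[Segment], path) -> None:
    if not segments:
        raise ValidationError("cannot write an empty segment collection")
    lengths = {s.length for s in segments}
    if len(lengths) != 1:
        raise ValidationError(f"segments have inconsistent lengths: {sorted(lengths)}")
    with h5py.File(path, "w") as fh:
        for name in ("ppg_raw", "art_raw", "ppg_in", "art_in"):
            fh.create_dataset(name, data=np.stack([getattr(s, name) for s in segments]))
        fh.create_dataset("co_label", data=np.array([s.co_label for s in segments]))
        fh.create_dataset(
            "co_label_scaled", data=np.array([s.co_label_scaled for s in segments])
        )
        fh.create_dataset("center_index", data=np.array([s.center_index for s in segments]))
        fh.create_dataset(
            "true_co",
            data=np.array(
                [np.nan if s.true_co is None else s.true_co for s in segments]
            ),
        )
        fh.create_dataset("normalized", data=np.array([s.normalized for s in segments]))
        fh.create_dataset(
            "case_id",
            data=np.array([s.case_id for s in segments], dtype=h5py.string_dtype()),
        )


def read_segments_h5(path) -> List[Segment]:
    with h5py.File(path, "r") as fh:
        n = fh["co_label"].shape[0]
        segments = []
        for i in range(n):
            true_co = float(fh["true_co"][i])
            segments.append(
                Segment(
                    case_id=fh["case_id"][i].decode(),
                    ppg_raw=fh["ppg_raw"][i],
                    art_raw=fh["art_raw"][i],
                    ppg_in=fh["ppg_in"][i],
                    art_in=fh["art_in"][i],
                    co_label=float(fh["co_label"][i]),
                    co_label_scaled=float(fh["co_label_scaled"][i]),
                    center_index=int(fh["center_index"][i]),
                    true_co=None if np.isnan(true_co) else true_co,
                    normalized=bool(fh["normalized"][i]),
                )
            )
    return segments


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at the top level")
    return data
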