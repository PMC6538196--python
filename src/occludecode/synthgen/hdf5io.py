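"""HDF5 container for epoched datasets.

Layout: datasets ``/data`` (float32, subject×condition×trial×sensor×time),
``/time_ms``, ``/condition_table`` (fixed-field records), ``/sensor_groups``;
root attributes ``sample_rate_hz``, ``seed``, ``spec_version``.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .generator import EpochedDataset, SensorLayout

__all__ = ["save_dataset", "load_dataset", "SPEC_VERSION"]

SPEC_VERSION = "1.0"


def save_dataset(ds: EpochedDataset, path) -> None:
    table = ds.condition_table
    rec = np.empty(len(table), dtype=[("object", "S16"), ("occlusion", "i4"), ("mask", "S16")])
    rec["object"] = table["object"].astype(str).values
    rec["occlusion"] = table["occlusion"].astype(int).values
    rec["mask"] = table["mask"].astype(str).values

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data.astype(np.float32))
        f.create_dataset("time_ms", data=np.asarray(ds.time_ms, dtype=float))
        f.create_dataset("condition_table", data=rec)
        f.create_dataset("sensor_groups", data=ds.sensor_layout.group_index)
        f.attrs["sample_rate_hz"] = float(ds.sample_rate_hz)
        f.attrs["seed"] = int(ds.seed)
        f.attrs["spec_version"] = SPEC_VERSION
        f.attrs["group_size"] = int(ds.sensor_layout.group_size)


def load_dataset(path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        time_ms = f["time_ms"][...]
        rec = f["condition_table"][...]
        group_size = int(f.attrs.get("group_size", 3))
        table = pd.DataFrame({
            "object": [b.decode() for b in rec["object"]],
            "occlusion": rec["occlusion"].astype(int),
            "mask": [b.decode() for b in rec["mask"]],
        })
        return EpochedDataset(
            data=data,
            time_ms=time_ms,
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            condition_table=table,
            sensor_layout=SensorLayout(data.shape[3], group_size),
            seed=int(f.attrs["seed"]),
        )
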