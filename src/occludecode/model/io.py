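"""Weight serialization for the folded net (single HDF5 container)."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .net import ArchSettings, FoldedNet, build_net

__all__ = ["save_net", "load_net"]


def save_net(net: FoldedNet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["arch"] = json.dumps({
            "channels": list(net.arch.channels),
            "kernel": net.arch.kernel,
            "input_size": net.arch.input_size,
            "n_classes": net.arch.n_classes,
        })
        f.attrs["seed"] = net.seed
        for i, u in enumerate(net.units):
            for name, layer in (("conv_in", u.conv_in), ("norm_in", u.norm_in),
                                ("conv_res", u.conv_res), ("norm_res", u.norm_res)):
                for k, v in layer.params.items():
                    f.create_dataset(f"units/{i}/{name}/{k}", data=v)
        for k, v in net.head.params.items():
            f.create_dataset(f"head/{k}", data=v)


def load_net(path) -> FoldedNet:
    with h5py.File(path, "r") as f:
        spec = json.loads(f.attrs["arch"])
        arch = ArchSettings(channels=tuple(spec["channels"]), kernel=spec["kernel"],
                            input_size=spec["input_size"], n_classes=spec["n_classes"])
        net = build_net(arch, seed=int(f.attrs["seed"]))
        for i, u in enumerate(net.units):
            for name, layer in (("conv_in", u.conv_in), ("norm_in", u.norm_in),
                                ("conv_res", u.conv_res), ("norm_res", u.norm_res)):
                for k in layer.params:
                    layer.params[k] = f[f"units/{i}/{name}/{k}"][...]
        for k in net.head.params:
            net.head.params[k] = f[f"head/{k}"][...]
        return net
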