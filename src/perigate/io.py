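"""Persistence: hierarchical array container for traces/spikes, CSV tables,
and JSON serialization of LN models and parameters."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ln import LinearFilter, LNModel, Nonlinearity
from .stimuli import IntensityTrace, SpikeResponse

__all__ = [
    "save_experiment",
    "load_experiment",
    "save_condition_table",
    "load_condition_table",
    "ln_model_to_json",
    "ln_model_from_json",
]


def save_experiment(path: str | Path, group: str,
                    stimulus: IntensityTrace | None = None,
                    spikes: SpikeResponse | None = None,
                    attrs: dict | None = None) -> None:
    """Write one experiment group (datasets ``stimulus``/``counts``) to HDF5."""
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if stimulus is not None:
            if "stimulus" in g:
                del g["stimulus"]
            d = g.create_dataset("stimulus", data=stimulus.values)
            d.attrs["dt"] = stimulus.dt
            d.attrs["mean"] = stimulus.mean
            d.attrs["contrast"] = stimulus.contrast
        if spikes is not None:
            if "counts" in g:
                del g["counts"]
            d = g.create_dataset("counts", data=spikes.counts)
            d.attrs["bin_s"] = spikes.bin_s
            d.attrs["alignment"] = spikes.alignment
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def load_experiment(path: str | Path, group: str
                    ) -> tuple[IntensityTrace | None, SpikeResponse | None,
                               dict]:
    """Read back one experiment group written by :func:`save_experiment`."""
    with h5py.File(path, "r") as f:
        g = f[group]
        stim = None
        spikes = None
        if "stimulus" in g:
            d = g["stimulus"]
            stim = IntensityTrace(d[()], float(d.attrs["dt"]),
                                  float(d.attrs["mean"]),
                                  float(d.attrs["contrast"]))
        if "counts" in g:
            d = g["counts"]
            spikes = SpikeResponse(d[()], float(d.attrs["bin_s"]),
                                   float(d.attrs["alignment"]))
        attrs = dict(g.attrs)
    return stim, spikes, attrs


def save_condition_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_condition_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def ln_model_to_json(model: LNModel) -> str:
    return json.dumps({
        "filter": {"weights": model.filter.weights.tolist(),
                   "dt": model.filter.dt,
                   "normalization": model.filter.normalization},
        "nonlinearity": {"bin_centers": model.nonlinearity.bin_centers.tolist(),
                         "mean_rate": model.nonlinearity.mean_rate.tolist(),
                         "occupancy": model.nonlinearity.occupancy.tolist()},
        "window": list(model.window) if model.window else None,
        "meta": model.meta,
    })


def ln_model_from_json(blob: str) -> LNModel:
    d = json.loads(blob)
    filt = LinearFilter(np.array(d["filter"]["weights"]),
                        d["filter"]["dt"], d["filter"]["normalization"])
    nl = Nonlinearity(np.array(d["nonlinearity"]["bin_centers"]),
                      np.array(d["nonlinearity"]["mean_rate"]),
                      np.array(d["nonlinearity"]["occupancy"], dtype=int))
    window = tuple(d["window"]) if d["window"] else None
    return LNModel(filt, nl, window=window, meta=d.get("meta", {}))
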