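"""Readers and writers for the on-disk bundle layout.

A dataset bundle is a directory holding

* ``data.h5`` -- ``/mua`` (int, trial x channel x bin), optional ``/lfp``
  (float, trial x channel x sample), optional ``/silhouettes`` (stimulus x
  H x W uint8) plus time attributes (``bin_width_ms``, ``sfreq_hz``,
  ``t_start_ms``, ...);
* ``trials.csv`` -- ``trial_id, stimulus_id`` (1-based);
* ``stimuli.csv`` -- ``stimulus_id, shape_type, category, name``.

RDMs travel as square CSV matrices whose first row/column hold the
stimulus ids; tuning tables as one-row-per-channel CSV; decoding and RSA
summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import RDM, SchemaError, StimulusDesign, TrialDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_design",
    "load_design",
    "save_rdm",
    "load_rdm",
    "save_json",
    "load_json",
]


def save_design(design: StimulusDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def load_design(path: str | Path, silhouettes: dict[int, np.ndarray] | None = None) -> StimulusDesign:
    table = pd.read_csv(path)
    return StimulusDesign(table, silhouettes)


def save_dataset(data: TrialDataset, out_dir: str | Path) -> Path:
    """Write a dataset bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "data.h5", "w") as h5:
        d = h5.create_dataset("mua", data=np.asarray(data.mua, dtype=np.int64))
        d.attrs["bin_width_ms"] = data.bin_width_ms
        d.attrs["t_start_ms"] = data.t_start_ms
        h5.attrs["baseline_start_ms"] = data.baseline_window[0]
        h5.attrs["baseline_end_ms"] = data.baseline_window[1]
        if data.lfp is not None:
            l = h5.create_dataset("lfp", data=np.asarray(data.lfp, dtype=np.float64))
            l.attrs["sfreq_hz"] = data.sfreq_hz
            l.attrs["t_start_ms"] = data.lfp_t_start_ms
        if data.design.silhouettes:
            ids = sorted(data.design.silhouettes)
            stack = np.stack([data.design.silhouettes[i] for i in ids]).astype(np.uint8)
            s = h5.create_dataset("silhouettes", data=stack)
            s.attrs["stimulus_ids"] = np.asarray(ids, dtype=np.int64)
    data.trial_table.to_csv(out / "trials.csv", index=False)
    save_design(data.design, out / "stimuli.csv")
    return out


def load_dataset(path: str | Path) -> TrialDataset:
    """Load and validate a dataset bundle written by :func:`save_dataset`."""
    bundle = Path(path)
    h5path = bundle / "data.h5"
    for required in (h5path, bundle / "trials.csv", bundle / "stimuli.csv"):
        if not required.exists():
            raise SchemaError(f"bundle is missing {required.name}")
    silhouettes = None
    with h5py.File(h5path, "r") as h5:
        if "mua" not in h5:
            raise SchemaError("data.h5 is missing the /mua array")
        mua = h5["mua"][()]
        bin_width = float(h5["mua"].attrs["bin_width_ms"])
        t_start = float(h5["mua"].attrs["t_start_ms"])
        baseline = (
            float(h5.attrs.get("baseline_start_ms", -300.0)),
            float(h5.attrs.get("baseline_end_ms", 0.0)),
        )
        lfp = sfreq = lfp_t0 = None
        if "lfp" in h5:
            lfp = h5["lfp"][()]
            sfreq = float(h5["lfp"].attrs["sfreq_hz"])
            lfp_t0 = float(h5["lfp"].attrs["t_start_ms"])
        if "silhouettes" in h5:
            stack = h5["silhouettes"][()]
            ids = h5["silhouettes"].attrs["stimulus_ids"]
            silhouettes = {int(i): stack[k] for k, i in enumerate(ids)}
    trial_table = pd.read_csv(bundle / "trials.csv")
    design = load_design(bundle / "stimuli.csv", silhouettes)
    kwargs = dict(
        mua=mua,
        trial_table=trial_table,
        design=design,
        bin_width_ms=bin_width,
        t_start_ms=t_start,
        baseline_window=baseline,
    )
    if lfp is not None:
        kwargs.update(lfp=lfp, sfreq_hz=sfreq, lfp_t_start_ms=lfp_t0)
    return TrialDataset(**kwargs)


def save_rdm(rdm: RDM, path: str | Path) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, index_label="stimulus_id")


def load_rdm(path: str | Path, source: str = "neural") -> RDM:
    df = pd.read_csv(path, index_col=0)
    labels = df.index.to_numpy()
    return RDM(df.to_numpy(dtype=float), labels, source)


def save_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
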