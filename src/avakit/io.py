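"""Reading and writing the package's on-disk formats.

Rasters live in HDF5 containers (datasets ``lambda`` [neurons x frames] and
``frame_rate``, ground-truth parameters as attributes) with a plain-CSV
alternative for small fixtures; stimulus protocols, ensemble catalogs and
fit results are CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SpikeProbRaster, StimulusProtocol, SyntheticGroundTruth, Trial

__all__ = [
    "save_raster_h5",
    "load_raster_h5",
    "save_raster_csv",
    "load_raster_csv",
    "save_protocol_csv",
    "load_protocol_csv",
    "save_json",
]

PROTOCOL_COLUMNS = ["trial", "frequency_hz", "level_db", "onset_frame", "duration_frames"]


def save_raster_h5(
    path: str | Path,
    raster: SpikeProbRaster,
    ground_truth: SyntheticGroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("lambda", data=raster.lam, compression="gzip")
        h5.create_dataset("frame_rate", data=float(raster.frame_rate))
        if ground_truth is not None:
            g = h5.create_group("ground_truth")
            for f in dataclasses.fields(ground_truth):
                v = getattr(ground_truth, f.name)
                if v is None:
                    continue
                if f.name == "extra":
                    g.attrs["extra_json"] = json.dumps(v)
                elif isinstance(v, tuple):
                    g.attrs[f.name] = np.asarray(v)
                else:
                    g.attrs[f.name] = v


def load_raster_h5(path: str | Path) -> tuple[SpikeProbRaster, SyntheticGroundTruth | None]:
    with h5py.File(path, "r") as h5:
        lam = h5["lambda"][()]
        fr = float(h5["frame_rate"][()])
        truth = None
        if "ground_truth" in h5:
            attrs = dict(h5["ground_truth"].attrs)
            extra = json.loads(attrs.pop("extra_json", "{}"))
            kw = {}
            for k, v in attrs.items():
                if isinstance(v, np.ndarray):
                    kw[k] = tuple(float(x) for x in v)
                elif isinstance(v, (np.integer, np.floating)):
                    kw[k] = v.item()
                else:
                    kw[k] = v
            truth = SyntheticGroundTruth(extra=extra, **kw)
    return SpikeProbRaster(lam, frame_rate=fr), truth


def save_raster_csv(path: str | Path, raster: SpikeProbRaster) -> None:
    """Plain-text raster for small fixtures: one row per neuron, header stores the frame rate."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={raster.frame_rate}\n")
        np.savetxt(fh, raster.lam, fmt="%.6g", delimiter=",")


def load_raster_csv(path: str | Path) -> SpikeProbRaster:
    with open(path) as fh:
        header = fh.readline().strip()
        fr = float(header.split("=", 1)[1]) if "=" in header else 30.0
        lam = np.loadtxt(fh, delimiter=",", ndmin=2)
    return SpikeProbRaster(lam, frame_rate=fr)


def save_protocol_csv(path: str | Path, protocol: StimulusProtocol) -> None:
    df = protocol.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={protocol.frame_rate} isi_lo={protocol.isi_range[0]} "
                 f"isi_hi={protocol.isi_range[1]}\n")
        df.to_csv(fh, index=False)


def load_protocol_csv(path: str | Path) -> StimulusProtocol:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
        meta = dict(kv.split("=", 1) for kv in header if "=" in kv)
        df = pd.read_csv(fh)
    trials = tuple(
        Trial(float(r.frequency_hz), float(r.level_db), int(r.onset_frame),
              int(r.duration_frames))
        for r in df.itertuples()
    )
    return StimulusProtocol(
        trials,
        frame_rate=float(meta.get("frame_rate", 30.0)),
        isi_range=(float(meta.get("isi_lo", 4.0)), float(meta.get("isi_hi", 6.0))),
    )


def save_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
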