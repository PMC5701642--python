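"""Persistence: HDF5 array container, CSV/TSV/JSON exports.

Dataset layout of the HDF5 container:

* ``/leadfield/gain``      — (sensors, nodes, 3) gain tensor, attrs ``units``,
  ``model_label``, ``modality``, ``referenced``
* ``/sensors/positions``   — (sensors, 3) mm; optional ``/sensors/orientations``;
  attrs ``modality``, ``gradiometer_baseline``, ``reference``
* ``/sources/positions``   — (nodes, 3) mm, attr ``cortex_radius``
* ``/measurement/data``    — (channels, samples), attrs ``rate``, ``modality``,
  ``units``
"""
from __future__ import annotations

import json
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .forward import Leadfield, SensorArray, SourceSpace
from .simulate import Measurement


def save_forward_bundle(path, leadfield: Leadfield, sensors: SensorArray,
                        source_space: Optional[SourceSpace] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_dataset("leadfield/gain", data=np.atleast_3d(leadfield.gain))
        g.attrs["units"] = leadfield.units
        g.attrs["model_label"] = leadfield.model_label
        g.attrs["modality"] = leadfield.modality
        g.attrs["referenced"] = leadfield.referenced
        s = f.create_dataset("sensors/positions", data=sensors.positions)
        s.attrs["modality"] = sensors.modality
        s.attrs["reference"] = sensors.reference
        if sensors.gradiometer_baseline is not None:
            s.attrs["gradiometer_baseline"] = sensors.gradiometer_baseline
        if sensors.orientations is not None:
            f.create_dataset("sensors/orientations", data=sensors.orientations)
        if source_space is not None:
            p = f.create_dataset("sources/positions", data=source_space.node_positions)
            p.attrs["cortex_radius"] = source_space.cortex_radius


def load_forward_bundle(path):
    """Returns (Leadfield, SensorArray, SourceSpace-or-None)."""
    with h5py.File(path, "r") as f:
        g = f["leadfield/gain"]
        s = f["sensors/positions"]
        sensors = SensorArray(
            positions=s[...], modality=s.attrs["modality"],
            orientations=f["sensors/orientations"][...] if "sensors/orientations" in f else None,
            gradiometer_baseline=float(s.attrs["gradiometer_baseline"])
            if "gradiometer_baseline" in s.attrs else None,
            reference=s.attrs.get("reference", "none"))
        space = None
        positions = None
        if "sources/positions" in f:
            p = f["sources/positions"]
            positions = p[...]
            space = SourceSpace(node_positions=positions,
                                cortex_radius=float(p.attrs.get("cortex_radius", np.nan)))
        lead = Leadfield(gain=g[...], units=g.attrs["units"],
                         model_label=g.attrs.get("model_label", ""),
                         modality=g.attrs.get("modality", sensors.modality),
                         referenced=bool(g.attrs.get("referenced", False)),
                         node_positions=positions)
    return lead, sensors, space


def save_measurement(path, meas: Measurement, seed: Optional[int] = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("measurement/data", data=meas.data)
        d.attrs["rate"] = meas.rate
        d.attrs["modality"] = meas.modality
        d.attrs["units"] = meas.units
        if seed is not None:
            d.attrs["seed"] = seed
    if meas.truth is not None:
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(meas.truth, fh, indent=1, default=_jsonable)


def load_measurement(path) -> Measurement:
    with h5py.File(path, "r") as f:
        d = f["measurement/data"]
        meas = Measurement(data=d[...], rate=float(d.attrs["rate"]),
                           modality=d.attrs["modality"], units=d.attrs.get("units", ""))
    return meas


def positions_to_tsv(path, positions: np.ndarray, label: str = "pos") -> None:
    df = pd.DataFrame(np.atleast_2d(positions), columns=["x_mm", "y_mm", "z_mm"])
    df.index.name = f"{label}_id"
    df.to_csv(path, sep="\t")


def scan_to_frame(outputs: Sequence) -> pd.DataFrame:
    """Scan outputs as a frame (node_id, x, y, z, constraint, outputs, orientation)."""
    rows = []
    for s in outputs:
        x, y, z = s.position
        ox, oy, oz = s.orientation
        rows.append({"node_id": s.node, "x": x, "y": y, "z": z,
                     "constraint": s.constraint,
                     "variance_output": s.variance_output,
                     "kurtosis_output": s.kurtosis_output,
                     "ori_x": ox, "ori_y": oy, "ori_z": oz, "ok": s.ok})
    return pd.DataFrame(rows)


def scan_to_csv(path, outputs: Sequence) -> None:
    scan_to_frame(outputs).to_csv(path, index=False)


def summaries_to_json(path, summary_frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        json.dump(summary_frame.to_dict(orient="records"), fh, indent=1,
                  default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
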