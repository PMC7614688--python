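"""HDF5 containers for recordings and YAML scenario configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .synth import (
    PopulationRecording,
    ScenarioSpec,
    spec_from_dict,
    spec_to_dict,
)

__all__ = [
    "save_recording",
    "load_recording",
    "save_scenario",
    "load_scenario",
    "save_trajectory",
]


def save_recording(path: str | Path, rec: PopulationRecording) -> None:
    """Write a recording to an HDF5 container.

    Layout: ``/activity`` (trial x time x neuron), ``/behavior/run_speed``,
    ``/behavior/licks``, and ``/meta`` holding condition labels, cell
    types, the time axis and the sampling period.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=rec.activity)
        beh = f.create_group("behavior")
        beh.create_dataset("run_speed", data=rec.run_speed)
        beh.create_dataset("licks", data=rec.licks)
        meta = f.create_group("meta")
        meta.create_dataset(
            "condition", data=np.asarray(rec.condition, dtype="S8")
        )
        meta.create_dataset(
            "cell_types", data=np.asarray(rec.cell_types, dtype="S8")
        )
        meta.create_dataset("time_axis", data=rec.time_axis)
        meta.attrs["Ts"] = rec.Ts


def load_recording(path: str | Path) -> PopulationRecording:
    with h5py.File(path, "r") as f:
        return PopulationRecording(
            activity=f["activity"][()],
            condition=f["meta/condition"][()].astype("U8"),
            time_axis=f["meta/time_axis"][()],
            run_speed=f["behavior/run_speed"][()],
            licks=f["behavior/licks"][()],
            cell_types=f["meta/cell_types"][()].astype("U8"),
            Ts=float(f["meta"].attrs["Ts"]),
        )


def save_scenario(path: str | Path, spec: ScenarioSpec) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec)))


def load_scenario(path: str | Path) -> ScenarioSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_trajectory(path: str | Path, trajectory: np.ndarray,
                    dt: float = 1.0) -> None:
    """Write a simulated trajectory (time x neuron) as an HDF5 dataset."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trajectory", data=trajectory)
        d.attrs["dt"] = dt
        d.attrs["axes"] = "time x neuron"
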