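"""HDF5 persistence for field records and medium maps."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .medium import MediumMaps
from .solver import FieldRecord

__all__ = ["save_record", "load_record", "save_medium", "load_medium"]


def save_record(record: FieldRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pressure", data=record.pressure)
        f.attrs["dt"] = record.dt
        f.attrs["center_frequency"] = record.center_frequency
        for k, v in record.metadata.items():
            try:
                f.attrs[f"meta_{k}"] = v
            except TypeError:
                f.attrs[f"meta_{k}"] = str(v)


def load_record(path: str | Path) -> FieldRecord:
    with h5py.File(path, "r") as f:
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return FieldRecord(
            pressure=np.asarray(f["pressure"]),
            dt=float(f.attrs["dt"]),
            center_frequency=float(f.attrs["center_frequency"]),
            metadata=meta,
        )


def save_medium(medium: MediumMaps, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sound_speed", data=medium.sound_speed)
        f.create_dataset("density", data=medium.density)
        f.create_dataset("absorption_prefactor",
                         data=medium.absorption_prefactor)
        f.attrs["voxel_size"] = medium.voxel_size
        f.attrs["power_law_exponent"] = medium.power_law_exponent


def load_medium(path: str | Path) -> MediumMaps:
    with h5py.File(path, "r") as f:
        return MediumMaps(
            sound_speed=np.asarray(f["sound_speed"]),
            density=np.asarray(f["density"]),
            absorption_prefactor=np.asarray(f["absorption_prefactor"]),
            voxel_size=float(f.attrs["voxel_size"]),
            power_law_exponent=float(f.attrs["power_law_exponent"]),
        )
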