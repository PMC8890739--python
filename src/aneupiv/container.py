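"""HDF5 container for ground truth, per-cycle fields and phase averages.

Layout (one scenario per file):

    /velocity   (phase, y, x, 3)  phase-averaged velocity, m/s
    /std        (phase, y, x, 3)  cycle-to-cycle standard deviation (optional)
    /cycles     (cycle, phase, y, x, 3)  per-cycle fields (optional)
    /mask       (y, x)            lumen / validity mask
    /waveform   (phase,)          normalized inflow waveform
    /x, /y      axes, mm
    attrs: cycle_duration_s, n_cycles, scenario, seed
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .cycles import PhaseAveragedCycle

__all__ = ["save_cycle", "load_cycle", "save_cycle_fields", "load_cycle_fields"]


def save_cycle(path, pac: PhaseAveragedCycle, mask: np.ndarray | None = None,
               waveform: np.ndarray | None = None, scenario: str = "",
               seed: int = 0, extra: dict[str, np.ndarray] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("velocity", data=pac.mean.astype(np.float32))
        if pac.std is not None:
            fh.create_dataset("std", data=pac.std.astype(np.float32))
        for name, data in (extra or {}).items():
            fh.create_dataset(name, data=np.asarray(data, dtype=np.float32))
        if mask is not None:
            fh.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))
        if waveform is not None:
            fh.create_dataset("waveform", data=np.asarray(waveform, dtype=np.float32))
        fh.create_dataset("x", data=pac.x_mm)
        fh.create_dataset("y", data=pac.y_mm)
        fh.attrs["cycle_duration_s"] = pac.cycle_duration_s
        fh.attrs["n_cycles"] = pac.n_cycles
        fh.attrs["scenario"] = scenario
        fh.attrs["seed"] = seed
    return path


def load_cycle(path) -> tuple[PhaseAveragedCycle, dict]:
    with h5py.File(path, "r") as fh:
        mean = fh["velocity"][()].astype(float)
        std = fh["std"][()].astype(float) if "std" in fh else None
        meta = dict(fh.attrs)
        meta["mask"] = fh["mask"][()].astype(bool) if "mask" in fh else None
        meta["waveform"] = fh["waveform"][()] if "waveform" in fh else None
        meta["oop_noise"] = fh["oop_noise"][()].astype(float) if "oop_noise" in fh else None
        pac = PhaseAveragedCycle(mean=mean, std=std,
                                 n_cycles=int(fh.attrs["n_cycles"]),
                                 cycle_duration_s=float(fh.attrs["cycle_duration_s"]),
                                 x_mm=fh["x"][()], y_mm=fh["y"][()])
    return pac, meta


def save_cycle_fields(path, fields: np.ndarray, x_mm, y_mm,
                      cycle_duration_s: float, scenario: str = "", seed: int = 0) -> Path:
    """Store raw per-(cycle, phase) 3C fields (cycle, phase, y, x, 3)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cycles", data=np.asarray(fields, dtype=np.float32),
                          compression="gzip", compression_opts=1)
        fh.create_dataset("x", data=np.asarray(x_mm))
        fh.create_dataset("y", data=np.asarray(y_mm))
        fh.attrs["cycle_duration_s"] = cycle_duration_s
        fh.attrs["scenario"] = scenario
        fh.attrs["seed"] = seed
    return path


def load_cycle_fields(path):
    with h5py.File(path, "r") as fh:
        return (fh["cycles"][()].astype(float), fh["x"][()], fh["y"][()],
                float(fh.attrs["cycle_duration_s"]))
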