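"""Persistence helpers: HDF5 field snapshots and flat key-value configs.

Documented config keys: ``c0``, ``rho0``, ``ppw``, ``cfl``,
``sponge_cycles``, ``design_depth``, ``dilation_cells``, ``lens_cL``,
``lens_rhoL``, ``seed``.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import h5py
import numpy as np

from .experiments import ExperimentConfig
from .wave_engine import ComplexField

__all__ = ["save_field", "load_field", "read_config", "write_config"]


def save_field(field: ComplexField, path: "str | Path") -> None:
    """Persist a complex field with its grid metadata."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("values", data=field.values)
        f.attrs["kind"] = field.kind
        f.attrs["dh"] = field.dh
        f.attrs["f0"] = field.f0
        f.attrs["z"] = field.z
        for k, v in field.meta.items():
            if isinstance(v, (int, float, bool, str)):
                f.attrs[f"meta_{k}"] = v


def load_field(path: "str | Path") -> ComplexField:
    with h5py.File(str(path), "r") as f:
        meta = {
            k[5:]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return ComplexField(
            values=f["values"][...],
            kind=str(f.attrs["kind"]),
            dh=float(f.attrs["dh"]),
            f0=float(f.attrs["f0"]),
            z=float(f.attrs["z"]),
            meta=meta,
        )


def write_config(config: ExperimentConfig, path: "str | Path") -> None:
    lines = [f"{f.name} = {getattr(config, f.name)!r}" for f in dc_fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: "str | Path") -> ExperimentConfig:
    """Parse a flat ``key = value`` text file; unknown keys are rejected."""
    known = {f.name: f.type for f in dc_fields(ExperimentConfig)}
    kwargs = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"malformed config line: {ln!r}")
        key, val = (tok.strip() for tok in ln.split("=", 1))
        if key not in known:
            raise ValueError(f"unknown config key: {key!r}")
        kwargs[key] = int(val) if key in ("dilation_cells", "seed") else float(val)
    return ExperimentConfig(**kwargs)
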