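"""HDF5 dataset container and report serialization.

One versioned HDF5 file holds everything a run produces or consumes:

* ``/volume_<i>/{b1_real, b1_imag, density, mask}`` — complex channel
  fields stored as separate real/imaginary float64 arrays with layout
  ``[channel, slice, row, col]``, plus per-slice density and mask;
* ``/reference/...`` — cached reference shim weights and RMSEs;
* ``/nfd/{maps, labels}`` — the detector's labeled magnitude maps;
* root attributes — ``layout_version``, generator seed and configuration,
  so every dataset carries its own provenance.

Reads are strict: a missing layout version or group raises a format error
naming the offending key instead of propagating a cryptic KeyError.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .fieldsim import (
    ChannelFieldSlice,
    CoilArraySpec,
    FieldVolume,
    GeneratorConfig,
    PhantomSpec,
    RegionMask,
)

logger = logging.getLogger(__name__)

LAYOUT_VERSION = 1

__all__ = [
    "DatasetFormatError",
    "write_dataset",
    "read_dataset",
    "write_reference",
    "read_reference",
    "write_nfd_maps",
    "read_nfd_maps",
]


class DatasetFormatError(ValueError):
    """The file is not a supported dataset container."""


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__dataclass__": type(obj).__name__, **dataclasses.asdict(obj)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_SPEC_TYPES = {"CoilArraySpec": CoilArraySpec, "PhantomSpec": PhantomSpec}


def _revive(obj):
    if isinstance(obj, dict):
        name = obj.pop("__dataclass__", None)
        obj = {k: _revive(v) for k, v in obj.items()}
        if name in _SPEC_TYPES:
            cls = _SPEC_TYPES[name]
            fields = {f.name for f in dataclasses.fields(cls)}
            kwargs = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in obj.items()
                if k in fields
            }
            return cls(**kwargs)
        return obj
    if isinstance(obj, list):
        return [_revive(v) for v in obj]
    return obj


def write_dataset(
    volumes: Sequence[FieldVolume],
    path: str | Path,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    mode: str = "w",
) -> None:
    """Write a collection of field volumes to the container."""
    path = Path(path)
    try:
        with h5py.File(path, mode) as f:
            f.attrs["layout_version"] = LAYOUT_VERSION
            f.attrs["n_volumes"] = len(volumes)
            if seed is not None:
                f.attrs["seed"] = int(seed)
            if config is not None:
                f.attrs["config"] = json.dumps(config, default=_json_default)
            for i, vol in enumerate(volumes):
                g = f.create_group(f"volume_{i}")
                b1 = np.stack([s.values for s in vol.slices], axis=1)  # (C, Z, H, W)
                g.create_dataset("b1_real", data=b1.real)
                g.create_dataset("b1_imag", data=b1.imag)
                g.create_dataset("density", data=np.stack(vol.densities))
                g.create_dataset("mask", data=np.stack([m.inside for m in vol.masks]))
                g.attrs["metadata"] = json.dumps(vol.metadata, default=_json_default)
    except OSError as exc:
        raise OSError(f"cannot write dataset to {path}: {exc}") from exc


def read_dataset(path: str | Path) -> list[FieldVolume]:
    """Read a dataset container back into field volumes (lossless round
    trip of all arrays)."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DatasetFormatError(f"{path} is not a readable HDF5 file: {exc}") from exc
    with f:
        if "layout_version" not in f.attrs:
            raise DatasetFormatError(f"{path}: missing 'layout_version' attribute")
        version = int(f.attrs["layout_version"])
        if version != LAYOUT_VERSION:
            raise DatasetFormatError(
                f"{path}: unsupported layout version {version} (expected {LAYOUT_VERSION})"
            )
        n = int(f.attrs.get("n_volumes", 0))
        volumes = []
        for i in range(n):
            key = f"volume_{i}"
            if key not in f:
                raise DatasetFormatError(f"{path}: missing group '/{key}'")
            g = f[key]
            for ds in ("b1_real", "b1_imag", "density", "mask"):
                if ds not in g:
                    raise DatasetFormatError(f"{path}: missing dataset '/{key}/{ds}'")
            b1 = g["b1_real"][...] + 1j * g["b1_imag"][...]
            density = g["density"][...]
            mask = g["mask"][...].astype(bool)
            metadata = _revive(json.loads(g.attrs.get("metadata", "{}")))
            n_slices = b1.shape[1]
            volumes.append(
                FieldVolume(
                    slices=[ChannelFieldSlice(b1[:, z]) for z in range(n_slices)],
                    masks=[RegionMask(mask[z]) for z in range(n_slices)],
                    densities=[density[z] for z in range(n_slices)],
                    metadata=metadata,
                )
            )
    return volumes


# ---------------------------------------------------------------------------
# cached reference shims
# ---------------------------------------------------------------------------

def write_reference(tables: Sequence[pd.DataFrame], path: str | Path) -> None:
    """Append reference shim tables (one per volume, from
    :func:`ptxshim.shimcore.shim_volume`) under ``/reference``."""
    with h5py.File(Path(path), "a") as f:
        if "reference" in f:
            del f["reference"]
        g = f.create_group("reference")
        vol_idx, slice_idx, rmse, obj, weights = [], [], [], [], []
        for v, table in enumerate(tables):
            for _, row in table.iterrows():
                if not row["ok"]:
                    continue
                vol_idx.append(v)
                slice_idx.append(int(row["slice"]))
                rmse.append(float(row["rmse_percent"]))
                obj.append(float(row["objective"]))
                weights.append(np.asarray(row["weights"]))
        W = np.stack(weights)
        g.create_dataset("volume", data=np.array(vol_idx))
        g.create_dataset("slice", data=np.array(slice_idx))
        g.create_dataset("rmse_percent", data=np.array(rmse))
        g.create_dataset("objective", data=np.array(obj))
        g.create_dataset("weights_real", data=W.real)
        g.create_dataset("weights_imag", data=W.imag)


def read_reference(path: str | Path) -> list[pd.DataFrame]:
    """Read cached reference tables grouped per volume."""
    with h5py.File(Path(path), "r") as f:
        if "reference" not in f:
            raise DatasetFormatError(f"{path}: missing group '/reference'")
        g = f["reference"]
        W = g["weights_real"][...] + 1j * g["weights_imag"][...]
        df = pd.DataFrame(
            {
                "volume": g["volume"][...],
                "slice": g["slice"][...],
                "rmse_percent": g["rmse_percent"][...],
                "objective": g["objective"][...],
            }
        )
        df["weights"] = [W[i] for i in range(len(df))]
        df["ok"] = True
    return [
        sub.drop(columns="volume").reset_index(drop=True)
        for _, sub in df.groupby("volume", sort=True)
    ]


# ---------------------------------------------------------------------------
# NFD maps
# ---------------------------------------------------------------------------

def write_nfd_maps(maps: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    with h5py.File(Path(path), "a") as f:
        if "nfd" in f:
            del f["nfd"]
        g = f.create_group("nfd")
        g.create_dataset("maps", data=np.asarray(maps))
        g.create_dataset(
            "labels", data=np.array([l.encode() for l in labels])
        )


def read_nfd_maps(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with h5py.File(Path(path), "r") as f:
        if "nfd" not in f:
            raise DatasetFormatError(f"{path}: missing group '/nfd'")
        g = f["nfd"]
        return g["maps"][...], [l.decode() for l in g["labels"][...]]
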