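"""Snapshot containers: HDF5 (primary) and NPZ (fallback) with one schema.

A :class:`SnapshotSeries` stores the four fields sampled at a regular
cadence, plus the noise-channel mask, the simulation configuration and the
parameter registry that produced it.  Fixture generators emit the same
container, so every analysis path is format-blind.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .params import ModelParams

SCHEMA_VERSION = 1

__all__ = ["SnapshotSeries", "read_container", "write_container", "params_hash"]


def params_hash(p: ModelParams) -> str:
    blob = json.dumps(p.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SnapshotSeries:
    """Time-stamped stack of grid states.

    ``v, r, s, a`` have shape ``(T, n, n)`` (or ``(T, n)`` in 1-D);
    ``noise_mask`` matches if present.  ``times`` is strictly increasing.
    """

    times: np.ndarray
    v: np.ndarray
    r: np.ndarray | None = None
    s: np.ndarray | None = None
    a: np.ndarray | None = None
    noise_mask: np.ndarray | None = None
    domain_length: float = 2.0  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v = np.asarray(self.v)
        if len(self.times) != len(self.v):
            raise ValueError("times and v must have equal leading length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("r", "s", "a", "noise_mask"):
            arr = getattr(self, name)
            if arr is not None and np.shape(arr) != np.shape(self.v):
                raise ValueError(f"field {name} shape mismatch")

    @property
    def grid_n(self) -> int:
        return self.v.shape[-1]

    @property
    def dx(self) -> float:
        return self.domain_length / self.grid_n

    @property
    def dt_snap(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def __eq__(self, other) -> bool:  # full-field equality, used in round-trip tests
        if not isinstance(other, SnapshotSeries):
            return NotImplemented
        if self.domain_length != other.domain_length:
            return False
        for name in ("times", "v", "r", "s", "a", "noise_mask"):
            x, y = getattr(self, name), getattr(other, name)
            if (x is None) != (y is None):
                return False
            if x is not None and not np.array_equal(x, y):
                return False
        return self.meta == other.meta


_FIELDS = ("times", "v", "r", "s", "a", "noise_mask")


def write_container(series: SnapshotSeries, path: str | Path) -> None:
    """Write a series; the extension selects HDF5 (.h5/.hdf5) or NPZ (.npz)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["schema_version"] = SCHEMA_VERSION
            fh.attrs["domain_length"] = series.domain_length
            fh.attrs["meta"] = json.dumps(series.meta, sort_keys=True)
            for name in _FIELDS:
                arr = getattr(series, name)
                if arr is not None:
                    fh.create_dataset(name, data=arr, compression="gzip", shuffle=True)
    elif path.suffix == ".npz":
        payload = {
            "schema_version": np.array(SCHEMA_VERSION),
            "domain_length": np.array(series.domain_length),
            "meta_json": np.array(json.dumps(series.meta, sort_keys=True)),
        }
        for name in _FIELDS:
            arr = getattr(series, name)
            if arr is not None:
                payload[name] = arr
        np.savez_compressed(path, **payload)
    else:
        raise ValueError(f"unsupported container extension: {path.suffix}")


def read_container(path: str | Path) -> SnapshotSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as fh:
                ver = int(fh.attrs["schema_version"])
                if ver != SCHEMA_VERSION:
                    raise ValueError(f"unsupported schema version {ver}")
                kwargs = {name: fh[name][...] for name in _FIELDS if name in fh}
                return SnapshotSeries(
                    domain_length=float(fh.attrs["domain_length"]),
                    meta=json.loads(fh.attrs["meta"]),
                    **kwargs,
                )
        elif path.suffix == ".npz":
            with np.load(path, allow_pickle=False) as z:
                ver = int(z["schema_version"])
                if ver != SCHEMA_VERSION:
                    raise ValueError(f"unsupported schema version {ver}")
                kwargs = {name: z[name] for name in _FIELDS if name in z.files}
                return SnapshotSeries(
                    domain_length=float(z["domain_length"]),
                    meta=json.loads(str(z["meta_json"])),
                    **kwargs,
                )
        else:
            raise ValueError(f"unsupported container extension: {path.suffix}")
    except (OSError, KeyError, zipfile.BadZipFile) as exc:
        raise CorruptContainerError(f"cannot read container {path}: {exc}") from exc


class CorruptContainerError(RuntimeError):
    """Raised when a container file is truncated or otherwise unreadable."""
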