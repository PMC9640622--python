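"""Snapshot container and HDF5 persistence.

A :class:`SnapshotStore` is an ordered list of frames (named float arrays
with a time stamp) plus run metadata (parameters with provenance tags,
seed, format version).  Round trips through HDF5 are bit-exact; reads of a
corrupted or version-incompatible file fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from PIL import Image

from .information import QuantizationSpec, quantize_field

__all__ = [
    "Frame",
    "SnapshotStore",
    "SnapshotError",
    "write_snapshots",
    "read_snapshots",
    "store_from_hydro",
    "store_from_abm",
    "export_png_frames",
]

FORMAT_VERSION = 1


class SnapshotError(RuntimeError):
    """Snapshot file unreadable, corrupted or incompatible."""


@dataclass
class Frame:
    time: float
    data: dict  # name -> ndarray


@dataclass
class SnapshotStore:
    frames: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise SnapshotError("frames must be strictly time-ordered")

    def __len__(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def write_snapshots(store: SnapshotStore, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["meta"] = json.dumps(store.meta)
        grp = h5.create_group("frames")
        for i, frame in enumerate(store.frames):
            fg = grp.create_group(f"{i:06d}")
            fg.attrs["time"] = frame.time
            for name, arr in frame.data.items():
                fg.create_dataset(name, data=np.asarray(arr))


def read_snapshots(path, t_range: tuple | None = None) -> SnapshotStore:
    """Read a store, optionally restricted to frames with time in
    ``[t_range[0], t_range[1]]`` (inclusive)."""
    try:
        with h5py.File(path, "r") as h5:
            version = int(h5.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise SnapshotError(
                    f"snapshot format version {version} incompatible with "
                    f"supported version {FORMAT_VERSION}"
                )
            meta = json.loads(h5.attrs.get("meta", "{}"))
            frames = []
            for key in sorted(h5["frames"]):
                fg = h5["frames"][key]
                t = float(fg.attrs["time"])
                if t_range is not None and not (t_range[0] <= t <= t_range[1]):
                    continue
                frames.append(
                    Frame(time=t, data={name: fg[name][()] for name in fg})
                )
    except (OSError, KeyError) as exc:
        raise SnapshotError(f"cannot read snapshot file {path}: {exc}") from exc
    return SnapshotStore(frames=frames, meta=meta)


def store_from_hydro(snaps: list, meta: dict | None = None) -> SnapshotStore:
    """Wrap a list of :class:`~commswarm.hydro.HydroFields` snapshots."""
    frames = [Frame(time=f.t, data=f.as_dict()) for f in snaps]
    return SnapshotStore(frames=frames, meta=dict(meta or {}))


def store_from_abm(snaps: list, meta: dict | None = None) -> SnapshotStore:
    """Wrap a list of :class:`~commswarm.abm.ABMSnapshot` frames."""
    frames = [
        Frame(
            time=s.t,
            data={
                "positions": s.ensemble.positions,
                "headings": s.ensemble.headings,
                "states": s.ensemble.states,
                "c": s.grid.c,
            },
        )
        for s in snaps
    ]
    return SnapshotStore(frames=frames, meta=dict(meta or {}))


def export_png_frames(store: SnapshotStore, spec: QuantizationSpec, out_dir,
                      fields: tuple | None = None) -> list:
    """Write one 8-bit grayscale PNG per frame per field.

    Deterministic bytes given the store and spec (fixed quantization, no
    timestamps).  Returns the list of written paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = fields if fields is not None else tuple(
        n for n in spec.layout if n in store.frames[0].data
    )
    written = []
    for i, frame in enumerate(store.frames):
        for name in names:
            lo, hi = spec.ranges[name]
            img = quantize_field(frame.data[name], lo, hi, spec.resolution,
                                 spec.mode)
            path = out_dir / f"{name}_{i:06d}.png"
            Image.fromarray(img, mode="L").save(path, format="PNG")
            written.append(path)
    return written
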