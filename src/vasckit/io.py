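"""Common carriers and file I/O.

Every image pipeline in the package consumes an :class:`ImageStack`: a stack
of 2-D grayscale frames plus the physical metadata (pixel size, frame
interval) needed to convert pixel measurements into micrometres and seconds.
Stacks are stored on disk as multi-page TIFFs with a JSON sidecar carrying
the metadata; every quantification stage emits a :class:`MetricRecord`, a
uniform JSON-serializable result envelope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "MetricRecord",
    "read_image_stack",
    "write_image_stack",
    "load_config",
    "PACKAGE_VERSION",
]

PACKAGE_VERSION = "0.1.0"


@dataclass
class ImageStack:
    """A stack of 2-D grayscale frames with physical metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``.  For multi-channel
        snapshots (e.g. live/dead/nuclei) the first axis indexes channels
        and ``channel_names`` labels them.
    pixel_size
        Physical size of one pixel, µm/px.  Strictly positive.
    frame_interval
        Time between consecutive frames, s.  ``None`` for single-timepoint
        or channel stacks.
    channel_names
        Optional labels for the first axis when it indexes channels.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n, rows, cols), got shape {self.frames.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval is not None and not self.frame_interval > 0:
            raise ValueError(
                f"frame_interval must be > 0 or None, got {self.frame_interval}"
            )
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.frames.shape[0]:
                raise ValueError("channel_names length must match frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (first frame at t = 0)."""
        if self.frame_interval is None:
            raise ValueError("stack has no frame_interval; not a time series")
        return np.arange(self.n_frames) * float(self.frame_interval)


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON metadata sidecar.

    The sidecar is ``<path>.json`` and stores pixel size, frame interval and
    channel names; pixels round-trip bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_image_stack`.

    Raises
    ------
    FileNotFoundError
        If the TIFF or its sidecar is missing.
    KeyError / ValueError
        If the sidecar lacks a required field (the error names the field).
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_um" not in meta or meta["pixel_size_um"] is None:
        raise ValueError(f"metadata field 'pixel_size_um' missing in {sidecar}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    names = meta.get("channel_names")
    return ImageStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=meta.get("frame_interval_s"),
        channel_names=tuple(names) if names else None,
    )


@dataclass
class MetricRecord:
    """Uniform result envelope emitted by every quantification stage.

    ``timestamp`` is optional and deliberately excluded from deterministic
    pipeline reports so that repeated runs are byte-identical.
    """

    metric: str
    value: Any
    units: str
    params: dict = field(default_factory=dict)
    input_hash: str | None = None
    version: str = PACKAGE_VERSION
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value": self.value,
            "units": self.units,
            "params": self.params,
            "input_hash": self.input_hash,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)

    @classmethod
    def from_json(cls, s: str) -> "MetricRecord":
        d = json.loads(s)
        return cls(**d)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def hash_array(arr: np.ndarray) -> str:
    """SHA-256 of an array's bytes, for provenance records."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    """Load a flat key-value configuration file (YAML or JSON).

    Keys mirror the porous-domain parameter names (density, water_content,
    youngs_modulus, dynamic_viscosity_matrix, porosity, permeability,
    species_diffusivity); missing keys fall back to the package defaults
    when the dict is passed to the parameter records.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config must be a flat mapping, got {type(data)}")
    return dict(data)
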