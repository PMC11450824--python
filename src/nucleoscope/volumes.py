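"""In-memory containers and TIFF round-trip for 4D microscopy volumes.

The package-wide coordinate convention is ``(t, z, y, x)`` with 0-based
indices; ``z`` increases basally, so ``z = 0`` is the apical-most layer.
Physical quantities are always derived through ``voxel_size`` (dz, dy, dx)
in micrometres and ``frame_interval`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

AXES = "TZCYX"


@dataclass
class ImageVolumeSeries:
    """Multi-channel intensity time series.

    Parameters
    ----------
    data : ndarray, shape (t, z, c, y, x)
        Non-negative intensities.
    voxel_size : tuple of float
        (dz, dy, dx) in micrometres.
    frame_interval : float
        Seconds between frames.
    channel_names : list of str
        One name per channel, e.g. ``["membrane", "nuclei", "myosin"]``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 0.16, 0.16)
    frame_interval: float = 15.0
    channel_names: list[str] = field(default_factory=lambda: ["membrane", "nuclei"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected (t, z, c, y, x) data, got ndim={self.data.ndim}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError("channel_names must match channel axis length")
        if any(v <= 0 for v in self.voxel_size) or self.frame_interval <= 0:
            raise ValueError("voxel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (t, z, y, x) array."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.data[:, :, idx]


@dataclass
class LabelVolumeSeries:
    """Integer-labelled segmentation aligned to an :class:`ImageVolumeSeries`.

    Label 0 is background.  Labels double as track ids: the same positive
    integer refers to the same tracked object in every frame.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 0.16, 0.16)
    frame_interval: float = 15.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError(f"expected (t, z, y, x) labels, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_z(self) -> int:
        return self.labels.shape[1]

    def tracks(self) -> np.ndarray:
        """Sorted array of non-zero track ids present anywhere in the series."""
        u = np.unique(self.labels)
        return u[u > 0]

    def frame(self, t: int) -> np.ndarray:
        return self.labels[t]


def write_volume(path, volume: ImageVolumeSeries) -> None:
    """Write a multi-page TIFF in TZCYX order with calibration metadata."""
    meta = {
        "axes": AXES,
        "voxel_size_um": list(volume.voxel_size),
        "frame_interval_s": volume.frame_interval,
        "channel_names": volume.channel_names,
    }
    tifffile.imwrite(path, volume.data, metadata=meta)


def read_volume(path, *, voxel_size=None, frame_interval=None) -> ImageVolumeSeries:
    """Read a TZCYX TIFF written by :func:`write_volume`.

    Calibration is taken from the embedded metadata; pass ``voxel_size`` /
    ``frame_interval`` to supply it for foreign files.  A file whose declared
    axis order is not TZCYX raises rather than silently transposing.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    axes = meta.get("axes")
    if axes is not None and axes != AXES:
        raise ValueError(f"axis order {axes!r} is not {AXES!r}; refusing to transpose silently")
    if data.ndim != 5:
        raise ValueError(f"expected 5D TZCYX data, got shape {data.shape}")
    vs = voxel_size or meta.get("voxel_size_um")
    fi = frame_interval or meta.get("frame_interval_s")
    if vs is None:
        raise ValueError("missing µm calibration: supply voxel_size (config key voxel_size_um)")
    if fi is None:
        raise ValueError("missing frame interval: supply frame_interval (config key frame_interval_s)")
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[2])]
    return ImageVolumeSeries(data, tuple(vs), float(fi), list(names))


def write_labels(path, labels: LabelVolumeSeries) -> None:
    meta = {
        "axes": "TZYX",
        "voxel_size_um": list(labels.voxel_size),
        "frame_interval_s": labels.frame_interval,
    }
    tifffile.imwrite(path, labels.labels.astype(np.int32), metadata=meta)


def read_labels(path, *, voxel_size=None, frame_interval=None) -> LabelVolumeSeries:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    vs = voxel_size or meta.get("voxel_size_um") or (1.0, 0.16, 0.16)
    fi = frame_interval or meta.get("frame_interval_s") or 15.0
    return LabelVolumeSeries(data.astype(np.int32), tuple(vs), float(fi))
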