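"""Core in-memory containers shared by all pipeline stages.

Axis convention: all voxel grids are indexed ``(z, y, x)`` (0-based), and
multichannel stacks ``(channel, z, y, x)``.  Physical voxel spacing is carried
as ``(dz, dy, dx)`` in micrometres.  A voxel is either in or out of a mask;
there is no sub-voxel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel roles a stack may declare
CHANNEL_ROLES = ("nuclei", "gfp", "stain", "stain2", "death")


@dataclass
class ImageStack:
    """A multichannel 3D fluorescence stack with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity array indexed ``(channel, z, y, x)``, arbitrary units.
    voxel_size
        ``(dz, dy, dx)`` in micrometres; strictly positive.
    channel_map
        Mapping from channel role (e.g. ``"gfp"``, ``"death"``) to channel
        index in ``data``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be (C, Z, Y, X); got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError("all stack dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dz, dy, dx)")
        n_chan = self.data.shape[0]
        indices = list(self.channel_map.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel_map indices must be unique")
        for role, idx in self.channel_map.items():
            if not (0 <= idx < n_chan):
                raise ValueError(f"channel_map[{role!r}]={idx} out of range for {n_chan} channels")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(n_z, n_y, n_x)``."""
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def has_role(self, role: str) -> bool:
        return role in self.channel_map

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` intensity array for a channel role."""
        if role not in self.channel_map:
            raise KeyError(
                f"stack has no {role!r} channel (available: {sorted(self.channel_map)})"
            )
        return self.data[self.channel_map[role]]


@dataclass
class LabelMask:
    """Integer-labeled voxel grid on the same ``(z, y, x)`` grid as a stack.

    Label 0 is background.  For binary masks the single foreground label is 1.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label mask must be a 3D (z, y, x) array")
        if self.labels.dtype.kind not in "iub":
            raise ValueError("labels must be integer or boolean")
        if self.labels.dtype.kind == "b":
            self.labels = self.labels.astype(np.int32)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of labeled (non-background) voxels."""
        return self.labels > 0

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def volume(self) -> float:
        """Total labeled volume in µm³."""
        return float(np.count_nonzero(self.labels)) * self.voxel_volume

    def same_grid(self, other) -> bool:
        return self.labels.shape == getattr(other, "labels", getattr(other, "data", None)).shape[-3:]


@dataclass
class SpotSet:
    """Point detections (e.g. ubiquitin speckles) in physical coordinates.

    ``coords`` is an ``(n, 3)`` array of ``(z, y, x)`` positions in µm;
    ``response`` the per-spot detection score.
    """

    coords: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.shape[1] != 3:
            raise ValueError("spot coords must be (n, 3) in (z, y, x) µm")
        self.response = np.asarray(self.response, dtype=float).reshape(-1)
        if len(self.response) != len(self.coords):
            raise ValueError("response must align with coords")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class CompartmentMasks:
    """Anterior/posterior compartment masks on the stack grid.

    The two masks must be disjoint and non-empty; by the usual display
    convention the posterior compartment is the right (high-``x``) side.
    """

    anterior: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        self.anterior = np.asarray(self.anterior, dtype=bool)
        self.posterior = np.asarray(self.posterior, dtype=bool)
        if self.anterior.shape != self.posterior.shape:
            raise ValueError("compartment masks must share one grid")
        if not self.anterior.any() or not self.posterior.any():
            raise ValueError("both compartments must be non-empty")
        if np.logical_and(self.anterior, self.posterior).any():
            raise ValueError("compartment masks must be disjoint")


@dataclass
class QuantRecord:
    """One disc-level measurement: the unit of statistical analysis.

    Each record is one data point in a cohort comparison — one wing disc (or
    one disc compartment/territory) × one metric.
    """

    disc_id: str
    metric: str
    scope: str
    value: float
    units: str = ""
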