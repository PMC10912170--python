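"""Shared voxel-grid substrate.

All modules use world coordinates in micrometres with axis order (z, y, x),
origin at the volume corner, and voxel centres at ``(i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel roles
ROLES = ("neuron", "microglia", "puncta")


@dataclass
class LabeledVolume:
    """Anisotropic voxel grid carrying per-channel instance labels.

    Parameters
    ----------
    labels
        Mapping from channel role (``"neuron"``, ``"microglia"``) to a 3D
        integer array of shape (z, y, x). 0 is background; positive integers
        are instance ids. Ids are unique within a channel, not across
        channels.
    voxel_size
        Physical voxel spacing in micrometres, ordered (z, y, x).
    """

    labels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    channel_roles: tuple[str, ...] = field(default=("neuron", "microglia"))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        for role, arr in self.labels.items():
            arr = np.asarray(arr)
            if arr.ndim != 3:
                raise ValueError(f"channel {role!r} must be 3D, got ndim={arr.ndim}")
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"channel {role!r} must be integer-typed")
            if arr.min() < 0:
                raise ValueError(f"channel {role!r} has negative labels")
            self.labels[role] = arr
        shapes = {arr.shape for arr in self.labels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.labels.values())).shape

    def world_extent(self) -> np.ndarray:
        """Physical size of the volume in um, (z, y, x)."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices (N, 3) to world um coordinates."""
        return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(self.voxel_size)
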