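"""Per-cell closed surface meshes from instance-label volumes, soma
extraction, and nearest-neuron pairing.

Meshes are produced by iso-surfacing each binary label at the 0.5 level
(marching cubes on the anisotropic grid), optionally after a light Gaussian
smoothing in physical units that suppresses voxel staircase bias. All
coordinates are world micrometres, axis order (z, y, x), voxel centres at
``(i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import measure

from .volume import LabeledVolume

__all__ = ["CellSurface", "PairAssignment", "build_surfaces", "extract_soma", "assign_pairs"]


@dataclass
class CellSurface:
    """A closed triangulated cell surface in world um coordinates."""

    cell_id: int
    cell_class: str  # neuron_soma | microglia_soma | microglia_whole
    mesh: trimesh.Trimesh
    centroid: np.ndarray
    area: float
    volume: float
    truncated: bool = False
    # voxel provenance, kept so soma extraction can reuse the exact mask
    _mask: np.ndarray | None = field(default=None, repr=False)
    _origin_um: np.ndarray | None = field(default=None, repr=False)
    _voxel_size: tuple[float, float, float] | None = field(default=None, repr=False)

    def require_closed(self) -> None:
        if not self.mesh.is_watertight:
            raise ValueError(
                f"{self.cell_class} {self.cell_id}: mesh is not closed "
                f"({len(self.mesh.faces)} faces)"
            )


def _mask_to_mesh(mask: np.ndarray, voxel_size, origin_um, smoothing_um: float,
                  taubin_iterations: int = 10) -> trimesh.Trimesh:
    """Marching cubes on a (padded) binary mask; vertices in world um.

    A light Gaussian pre-smoothing of the indicator field plus a
    volume-preserving Taubin relaxation of the mesh remove the voxel
    staircase (which otherwise inflates areas by ~14 % on this grid)
    without eroding thin structures such as crescent-shaped contact rims.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    pad = 2
    field_ = np.pad(mask.astype(np.float32), pad)
    if smoothing_um > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=smoothing_um / voxel_size)
    # smoothing can pull the max below the iso level for very thin objects
    level = min(0.5, 0.5 * float(field_.max()))
    verts, faces, _, _ = measure.marching_cubes(field_, level=level, spacing=tuple(voxel_size))
    verts = verts + np.asarray(origin_um) + (0.5 - pad) * voxel_size
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if taubin_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=taubin_iterations)
    return mesh


def build_surfaces(
    vol: LabeledVolume,
    channel: str,
    cell_class: str | None = None,
    smoothing_um: float = 0.1,
) -> list[CellSurface]:
    """One closed mesh per instance label of ``channel``.

    Cells touching the volume border are flagged ``truncated`` (standard
    stereology exclusion); they are still returned but are skipped by
    :func:`assign_pairs`.
    """
    if channel not in vol.labels:
        raise KeyError(f"channel {channel!r} not in volume (has {sorted(vol.labels)})")
    labels = vol.labels[channel]
    if cell_class is None:
        cell_class = {"neuron": "neuron_soma", "microglia": "microglia_soma"}.get(channel, channel)
    voxel_size = np.asarray(vol.voxel_size)
    out: list[CellSurface] = []
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == idx
        truncated = any(
            (s.start == 0 and np.any(mask.take(0, axis=k)))
            or (s.stop == labels.shape[k] and np.any(mask.take(-1, axis=k)))
            for k, s in enumerate(sl)
        )
        origin = np.array([s.start for s in sl]) * voxel_size
        mesh = _mask_to_mesh(mask, voxel_size, origin, smoothing_um)
        out.append(
            CellSurface(
                cell_id=idx,
                cell_class=cell_class,
                mesh=mesh,
                centroid=np.asarray(mesh.center_mass, dtype=float),
                area=float(mesh.area),
                volume=float(mesh.volume),
                truncated=truncated,
                _mask=mask,
                _origin_um=origin,
                _voxel_size=tuple(vol.voxel_size),
            )
        )
    return out


def extract_soma(
    surface: CellSurface,
    opening_radius_um: float = 1.0,
    smoothing_um: float = 0.1,
) -> CellSurface:
    """Soma of a whole-cell surface by morphological opening of its voxel mask.

    Thin processes (diameter < 2x the opening radius) are removed; the
    largest remaining component is re-meshed. With radius 0 the input is
    returned unchanged.
    """
    if opening_radius_um < 0:
        raise ValueError("opening radius must be >= 0")
    if opening_radius_um == 0:
        return surface
    if surface._mask is None:
        raise ValueError("surface lacks voxel provenance; build it with build_surfaces")
    voxel_size = np.asarray(surface._voxel_size)
    pad = int(np.ceil(opening_radius_um / voxel_size.min())) + 2
    mask = np.pad(surface._mask, pad)
    # opening by an anisotropic ball via two distance transforms
    eroded = ndimage.distance_transform_edt(mask, sampling=voxel_size) > opening_radius_um
    if not eroded.any():
        raise ValueError(
            f"opening radius {opening_radius_um} um erases cell {surface.cell_id} entirely"
        )
    opened = ndimage.distance_transform_edt(~eroded, sampling=voxel_size) <= opening_radius_um
    lab, n = ndimage.label(opened)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        opened = lab == (1 + int(np.argmax(sizes)))
    origin = np.asarray(surface._origin_um) - pad * voxel_size
    mesh = _mask_to_mesh(opened, voxel_size, origin, smoothing_um)
    return CellSurface(
        cell_id=surface.cell_id,
        cell_class="microglia_soma" if surface.cell_class.startswith("microglia") else surface.cell_class,
        mesh=mesh,
        centroid=np.asarray(mesh.center_mass, dtype=float),
        area=float(mesh.area),
        volume=float(mesh.volume),
        truncated=surface.truncated,
        _mask=opened,
        _origin_um=origin,
        _voxel_size=surface._voxel_size,
    )


@dataclass
class PairAssignment:
    """A microglia matched to the neuron nearest its soma centre."""

    microglia_id: int
    neuron_id: int
    center_distance: float  # um


def assign_pairs(
    neurons: list[CellSurface],
    microglia: list[CellSurface],
    include_truncated: bool = False,
) -> list[PairAssignment]:
    """Nearest-centroid assignment: every microglia gets exactly one neuron.

    Ties (equal distances to machine precision) resolve to the smaller
    neuron id. Truncated cells are excluded unless requested.
    """
    neurons = [n for n in neurons if include_truncated or not n.truncated]
    microglia = [m for m in microglia if include_truncated or not m.truncated]
    if not neurons or not microglia:
        raise ValueError("need at least one (non-truncated) neuron and microglia")
    neurons = sorted(neurons, key=lambda c: c.cell_id)
    ncent = np.array([n.centroid for n in neurons])
    out = []
    for m in sorted(microglia, key=lambda c: c.cell_id):
        d = cdist([m.centroid], ncent)[0]
        best = d.min()
        candidates = np.flatnonzero(d <= best + 1e-9)
        chosen = min(candidates, key=lambda i: neurons[i].cell_id)
        out.append(
            PairAssignment(
                microglia_id=m.cell_id,
                neuron_id=neurons[chosen].cell_id,
                center_distance=float(d[chosen]),
            )
        )
    return out
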