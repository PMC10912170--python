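"""Microglia-neuron contact quantification and extensive-association calling.

Contact is measured on meshes: the contact patch is the set of neuronal
surface faces whose centroid lies within ``delta_contact`` of the microglial
surface; its summed area is the contact area and its fraction of the
neuronal soma area is the 3D coverage. The 2D analogue is the fraction of
the neuronal boundary arc length contacted in the equatorial slice.

Extensive association follows the standard satellite-microglia criteria:
> 25 % of the neuronal circumference in 2D, or >= 13.27 % of the soma
surface in 3D, the latter obtained by evaluating the 2D->3D ordinary
least-squares calibration (slope 0.545, intercept -0.355, coverages in
percent) at the 25 % threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from skimage import measure

from ._geometry import MeshDistance
from .surfaces import CellSurface, PairAssignment
from .volume import LabeledVolume

__all__ = [
    "AssociationRecord",
    "CalibrationModel",
    "contact_patch",
    "coverage_2d",
    "coverage_2d_volume",
    "fit_calibration",
    "map_threshold",
    "classify_association",
    "measure_association",
    "THRESHOLD_2D_PERCENT",
    "THRESHOLD_3D_PERCENT",
]

#: 2D criterion: microglia covering more than one quarter of the neuronal
#: circumference in a single confocal plane.
THRESHOLD_2D_PERCENT = 25.0
#: 3D criterion mapped through the calibration regression, at printed precision.
THRESHOLD_3D_PERCENT = 13.27

DEFAULT_DELTA_CONTACT = 0.2  # um, one in-plane voxel


@dataclass
class AssociationRecord:
    """Contact metrics for one nearest microglia-neuron pair."""

    pair: PairAssignment
    coverage_2d: float | None  # fraction of circumference, equatorial slice
    coverage_3d: float  # fraction of soma surface area
    contact_area: float  # um^2
    extensive_2d: bool | None
    extensive_3d: bool


@dataclass
class CalibrationModel:
    """OLS of 3D coverage (%) on 2D coverage (%)."""

    slope: float
    intercept: float
    r2: float
    n_cells: int


def contact_patch(
    neuron: CellSurface,
    microglia: CellSurface,
    delta_contact: float = DEFAULT_DELTA_CONTACT,
) -> tuple[float, float]:
    """Contact area (um^2) and 3D coverage fraction of a pair.

    Returns the summed area of neuron faces whose centroid lies within
    ``delta_contact`` of the microglial mesh, and that area divided by the
    total neuronal soma area.
    """
    if delta_contact <= 0:
        raise ValueError("delta_contact must be > 0")
    neuron.require_closed()
    microglia.require_closed()
    query = MeshDistance(microglia.mesh)
    d = query.signed_normal(neuron.mesh.triangles_center)
    in_contact = d <= delta_contact  # interior (overlapping) faces count
    contact_area = float(neuron.mesh.area_faces[in_contact].sum())
    return contact_area, contact_area / neuron.area


def contact_face_mask(
    neuron: CellSurface,
    microglia: CellSurface,
    delta_contact: float = DEFAULT_DELTA_CONTACT,
) -> np.ndarray:
    """Boolean mask over neuron faces inside the contact patch."""
    query = MeshDistance(microglia.mesh)
    d = query.signed_normal(neuron.mesh.triangles_center)
    return d <= delta_contact


def coverage_2d(
    neuron_mask: np.ndarray,
    microglia_mask: np.ndarray,
    pixel_size: tuple[float, float],
    delta_contact: float = DEFAULT_DELTA_CONTACT,
) -> float:
    """Fraction of the neuronal boundary arc length within ``delta_contact``
    of the microglial mask, on a single analysis plane.

    ``pixel_size`` is (y, x) in um. The boundary is the sub-pixel 0.5-level
    contour of the neuron mask; each contour segment contributes its arc
    length if its midpoint lies within the contact distance of the microglia.
    """
    neuron_mask = np.asarray(neuron_mask).astype(bool)
    microglia_mask = np.asarray(microglia_mask).astype(bool)
    if not neuron_mask.any():
        raise ValueError("neuron absent from the analysis slice")
    if not microglia_mask.any():
        return 0.0
    py, px = pixel_size
    contours = measure.find_contours(neuron_mask.astype(float), 0.5)
    contour = max(contours, key=len)
    # distance (um) from anywhere in the plane to the microglia mask
    dist = ndimage.distance_transform_edt(~microglia_mask, sampling=pixel_size)
    scale = np.array([py, px])
    p0 = contour[:-1] * scale
    p1 = contour[1:] * scale
    seg_len = np.linalg.norm(p1 - p0, axis=1)
    mid = 0.5 * (contour[:-1] + contour[1:])
    mid_dist = ndimage.map_coordinates(dist, mid.T, order=1, mode="nearest")
    # half-pixel allowance: the EDT measures to pixel centres, the mask
    # region extends half a pixel beyond them
    allowance = 0.5 * float(np.hypot(py, px))
    covered = seg_len[mid_dist <= delta_contact + allowance].sum()
    total = seg_len.sum()
    return float(covered / total) if total > 0 else 0.0


def coverage_2d_volume(
    vol: LabeledVolume,
    neuron: CellSurface,
    microglia_id: int | None = None,
    delta_contact: float = DEFAULT_DELTA_CONTACT,
    mode: str = "centroid",
) -> float:
    """2D coverage on a single analysis z-plane.

    ``mode="centroid"`` (default) analyses the equatorial slice through the
    neuron centroid, mimicking one confocal plane per cell. ``mode="max"``
    scans every slice containing the neuron and reports the maximum, which
    emulates an experimenter picking the plane that best shows the
    apposition (a polar contact is invisible in the equatorial plane).
    """
    vz = vol.voxel_size[0]
    mg = vol.labels["microglia"]
    nl = vol.labels["neuron"]
    if mode == "centroid":
        zs = [int(np.clip(round(neuron.centroid[0] / vz - 0.5), 0, vol.shape[0] - 1))]
    elif mode == "max":
        counts = np.array([(nl[z] == neuron.cell_id).sum() for z in range(vol.shape[0])])
        # only planes showing a substantial soma cross-section qualify as
        # analysis planes (polar caps exaggerate circumference coverage)
        zs = [z for z in range(vol.shape[0]) if counts[z] >= 0.5 * counts.max()]
        if not zs:
            raise ValueError(f"neuron {neuron.cell_id} absent from every slice")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best = 0.0
    for z in zs:
        nslice = nl[z] == neuron.cell_id
        if not nslice.any():
            raise ValueError(f"neuron {neuron.cell_id} absent from slice {z}")
        mslice = (mg[z] == microglia_id) if microglia_id is not None else (mg[z] > 0)
        best = max(best, coverage_2d(nslice, mslice, vol.voxel_size[1:], delta_contact))
    return best


def fit_calibration(coverage_2d_percent, coverage_3d_percent) -> CalibrationModel:
    """Ordinary least squares of 3D coverage on 2D coverage, both in percent."""
    x = np.asarray(coverage_2d_percent, dtype=float)
    y = np.asarray(coverage_3d_percent, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1D samples required")
    if len(x) < 3:
        raise ValueError(f"calibration needs >= 3 cells, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: 2D coverages have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        n_cells=len(x),
    )


def map_threshold(model: CalibrationModel, threshold_2d: float = THRESHOLD_2D_PERCENT) -> float:
    """Map a 2D circumference threshold (%) into 3D surface coverage (%),
    reported to two decimals."""
    return round(model.slope * threshold_2d + model.intercept, 2)


def measure_association(
    neurons: list[CellSurface],
    microglia: list[CellSurface],
    pairs: list[PairAssignment],
    delta_contact: float = DEFAULT_DELTA_CONTACT,
    vol: LabeledVolume | None = None,
) -> pd.DataFrame:
    """Per-pair association table (coverages, contact area, extensive flags).

    If ``vol`` is given, the 2D coverage on the equatorial slice is computed
    as well; otherwise only the 3D metrics are filled.
    """
    nmap = {n.cell_id: n for n in neurons}
    mmap = {m.cell_id: m for m in microglia}
    rows = []
    for p in pairs:
        neuron, mg = nmap[p.neuron_id], mmap[p.microglia_id]
        area, cov3 = contact_patch(neuron, mg, delta_contact)
        cov2 = (
            coverage_2d_volume(vol, neuron, p.microglia_id, delta_contact)
            if vol is not None
            else np.nan
        )
        rows.append(
            dict(
                microglia_id=p.microglia_id,
                neuron_id=p.neuron_id,
                center_distance=p.center_distance,
                coverage_2d=cov2,
                coverage_3d=cov3,
                contact_area=area,
            )
        )
    df = pd.DataFrame(rows)
    return classify_association(df)


def classify_association(
    records: pd.DataFrame,
    threshold_3d_percent: float = THRESHOLD_3D_PERCENT,
    threshold_2d_percent: float = THRESHOLD_2D_PERCENT,
    by: tuple[str, ...] | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Attach extensive-association flags; optionally summarise per group.

    Coverages are fractions in the input table. The 3D flag is inclusive at
    the printed threshold (``coverage_3d * 100 >= 13.27``); the 2D flag is
    strict (``> 25``). With ``by`` (e.g. ``("region", "animal_id")``) a
    summary of percent-extensive per group cell is returned as well; group
    cells with no microglia are simply absent (missing, never 0 %).
    """
    df = records.copy()
    if "coverage_3d" in df:
        df["extensive_3d"] = df["coverage_3d"] * 100.0 >= threshold_3d_percent
    if "coverage_2d" in df and df["coverage_2d"].notna().any():
        df["extensive_2d"] = df["coverage_2d"] * 100.0 > threshold_2d_percent
    if by is None:
        return df
    flag = "extensive_3d" if "extensive_3d" in df else "extensive_2d"
    grouped = df.groupby(list(by))[flag]
    summary = grouped.agg(n_extensive="sum", n_total="count").reset_index()
    summary["percent_extensive"] = 100.0 * summary["n_extensive"] / summary["n_total"]
    return df, summary
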