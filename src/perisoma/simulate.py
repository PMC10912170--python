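"""Synthetic tissue, trajectory and signal generators with planted ground truth.

The volumetric generator emulates the specimen geometry the analysis
assumes: neuronal somata as mildly distorted ellipsoids, microglial somata
apposed to a controllable fraction of neurons at a controllable surface
coverage, Poisson-distributed presynaptic (VGAT-like) puncta on soma
surfaces that are *displaced* (relocated to the microglial surface, or
suppressed) inside contact patches, and a small engulfed population strictly
interior to microglia. Because the total puncta draw per pair is taken
before displacement, pair totals are independent of association by
construction - the simulator realises the displacement (rather than loss)
hypothesis and its null.

Association is planted by solving for the microglia-neuron centre distance
that yields a target surface-coverage fraction: a closed-form spherical-cap
formula provides the bracket and a bisection on area-weighted surface
samples of the actual ellipsoids refines it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabeledVolume
from ._geometry import Ellipsoid, random_rotation

__all__ = [
    "TissueConfig",
    "GroundTruth",
    "simulate_volume",
    "simulate_cohort",
    "simulate_coculture_tracks",
    "simulate_calcium",
    "simulate_lfp",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TissueConfig:
    """Design constants of a simulated specimen.

    Defaults mirror adult cortical tissue at confocal scale: ~9 um neuronal
    somata, slightly smaller microglial somata, a 0.5 um z-step with 0.2 um
    in-plane sampling, and puncta densities that put per-soma perisomatic
    counts in the tens.
    """

    volume_shape: tuple[int, int, int] = (56, 160, 160)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2)  # um
    n_neurons: int = 3
    n_microglia: int = 3
    neuron_radius_um: tuple[float, float] = (4.5, 0.3)  # mean, sd
    microglia_radius_um: tuple[float, float] = (4.0, 0.3)
    p_assoc: float = 0.5
    coverage_assoc: float = 0.25  # target 3D coverage for associated pairs
    coverage_nonassoc: float = 0.03
    puncta_density: float = 0.15  # expected puncta per um^2 of soma surface
    displacement_mode: str = "relocate"  # or "suppress"
    engulf_rate: float = 2.0  # expected engulfed puncta per microglia
    n_processes: int = 0  # tubular protrusions per microglia
    snr: float = 10.0
    axis_distortion: float = 0.08  # per-axis semi-axis jitter (ratio <= ~1.17)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_assoc <= 1.0):
            raise ValueError(f"p_assoc must be in [0, 1], got {self.p_assoc}")
        if not (self.coverage_assoc > self.coverage_nonassoc >= 0.0):
            raise ValueError(
                "require coverage_assoc > coverage_nonassoc >= 0, got "
                f"{self.coverage_assoc} vs {self.coverage_nonassoc}"
            )
        if self.coverage_assoc >= 1.0:
            raise ValueError("coverage_assoc must be < 1")
        for name in ("neuron_radius_um", "microglia_radius_um"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have positive mean and non-negative sd")
        if self.puncta_density <= 0:
            raise ValueError("puncta_density must be > 0")
        if self.displacement_mode not in ("relocate", "suppress"):
            raise ValueError(f"unknown displacement_mode {self.displacement_mode!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        # the largest plausible cell (mean + 3 sd) must fit with margin
        extent = np.asarray(self.volume_shape) * np.asarray(self.voxel_size)
        dmax = 2 * max(
            self.neuron_radius_um[0] + 3 * self.neuron_radius_um[1],
            self.microglia_radius_um[0] + 3 * self.microglia_radius_um[1],
        )
        if np.any(extent < dmax + 2.0):
            raise ValueError(
                f"volume extent {extent} um cannot hold a soma of diameter "
                f"~{dmax:.1f} um without truncation"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated specimen, the recovery oracle.

    ``pairs`` has one row per microglia with its host neuron; ``puncta`` one
    row per surviving punctum (centres in world um, axis order z, y, x);
    ``cells`` records the planted ellipsoid geometry.
    """

    pairs: pd.DataFrame
    puncta: pd.DataFrame
    cells: pd.DataFrame
    config: TissueConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# planting helpers


def _draw_radii(mean: float, sd: float, distortion: float, rng: np.random.Generator) -> np.ndarray:
    base = max(1.0, rng.normal(mean, sd))
    factors = rng.uniform(1.0 - distortion, 1.0 + distortion, size=3)
    factors /= np.cbrt(np.prod(factors))  # volume-preserving
    return base * factors


def _cap_distance(R: float, r: float, coverage: float) -> float | None:
    """Centre distance so a sphere of radius ``r`` covers ``coverage`` of a
    sphere of radius ``R`` (spherical-cap area formula); None if infeasible."""
    cos_theta = 1.0 - 2.0 * coverage
    disc = R * R * cos_theta * cos_theta - R * R + r * r
    if disc < 0:
        return None
    d = R * cos_theta + np.sqrt(disc)
    return d if d > 0 else None


def _coverage_of(neuron: Ellipsoid, microglia: Ellipsoid, samples: np.ndarray, weights: np.ndarray) -> float:
    inside = microglia.contains(samples)
    return float(np.sum(weights[inside]) / np.sum(weights))


#: offset applied to the microglial surface when planting coverage (negative
#: = inflate), compensating the mean gap between the analytic contact cap and
#: what anisotropic rasterisation plus the 0.2 um contact band realises
RASTER_INSET_UM = -0.05


def _raster_correction(dz_abs: float, coverage: float) -> float:
    """Expected realized-minus-target coverage after rasterisation.

    Calibrated once against the brute-force voxel contact measure on this
    grid (0.5 x 0.2 x 0.2 um): the residual depends on how the approach
    axis aligns with the coarse z-axis and on the cap size. Used to adjust
    the bisection target so realized coverage matches the request.
    """
    return 0.019 + 0.022 * dz_abs - 0.098 * coverage


def _solve_apposition(
    neuron: Ellipsoid,
    mg_radii: np.ndarray,
    mg_rot: np.ndarray,
    direction: np.ndarray,
    target: float,
    rng: np.random.Generator,
    n_samples: int = 4096,
    inset: float = RASTER_INSET_UM,
) -> tuple[Ellipsoid, float] | None:
    """Bisect the centre distance along ``direction`` to the target coverage."""
    samples, weights = neuron.surface_points(n_samples, rng)
    R = neuron.mean_radius
    r = float(np.cbrt(np.prod(mg_radii)))
    inset_radii = np.maximum(mg_radii - inset, 0.5)
    correction = _raster_correction(abs(float(direction[0])), target)
    requested, target = target, float(np.clip(target - correction, 0.005, 0.92))

    def make(d: float) -> Ellipsoid:
        return Ellipsoid(neuron.center + d * direction, inset_radii, mg_rot)

    # coverage peaks at d* = sqrt(R^2 - r^2) for r < R (tangent interior
    # circle) and decreases monotonically beyond; bracket from the peak
    r_eff = float(np.cbrt(np.prod(inset_radii)))
    d_lo = max(0.25, np.sqrt(max(R * R - r_eff * r_eff, 0.0)))
    d_hi = R + float(mg_radii.max()) + 1.0
    c_lo = _coverage_of(neuron, make(d_lo), samples, weights)
    if c_lo < target:  # even maximal interpenetration cannot reach the target
        return None
    guess = _cap_distance(R, r, target)
    if guess is not None and d_lo < guess < d_hi:
        # narrow the bracket around the spherical estimate
        if _coverage_of(neuron, make(guess), samples, weights) >= target:
            d_lo = guess
        else:
            d_hi = guess
    for _ in range(40):
        mid = 0.5 * (d_lo + d_hi)
        if _coverage_of(neuron, make(mid), samples, weights) >= target:
            d_lo = mid
        else:
            d_hi = mid
    d = 0.5 * (d_lo + d_hi)
    achieved = _coverage_of(neuron, make(d), samples, weights)
    if abs(achieved - target) > 0.02:
        return None
    planted = float(np.clip(achieved + correction, 0.0, 1.0))
    return Ellipsoid(neuron.center + d * direction, mg_radii, mg_rot), planted


def _sample_surface_weighted(ell: Ellipsoid, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform by area on the ellipsoid surface (rejection on weights)."""
    out = np.empty((0, 3))
    while len(out) < n:
        pts, w = ell.surface_points(max(4 * n, 64), rng)
        keep = rng.uniform(0, w.max(), size=len(w)) < w
        out = np.vstack([out, pts[keep]])
    return out[:n]


# ---------------------------------------------------------------------------
# volumetric simulator


def simulate_volume(cfg: TissueConfig) -> tuple[LabeledVolume, dict[str, np.ndarray], GroundTruth]:
    """Generate a labelled specimen, rendered intensity channels and its truth.

    Returns
    -------
    vol : LabeledVolume with ``neuron`` and ``microglia`` instance channels.
    intensities : dict of float volumes (``neuron``, ``microglia``,
        ``puncta``) rendered with diffraction-scale Gaussian spots
        (FWHM ~0.5 um in xy, ~1 um in z for puncta) plus white noise at the
        configured peak-signal-to-noise ratio.
    truth : GroundTruth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    voxel_size = np.asarray(cfg.voxel_size)
    extent = np.asarray(cfg.volume_shape) * voxel_size

    # --- place neurons ------------------------------------------------------
    neurons: list[Ellipsoid] = []
    for _ in range(cfg.n_neurons):
        placed = False
        for _attempt in range(400):
            radii = _draw_radii(*cfg.neuron_radius_um, cfg.axis_distortion, rng)
            rmax = radii.max()
            margin = rmax + 0.8
            if np.any(extent - 2 * margin <= 0):
                raise RuntimeError(
                    f"volume extent {extent} too small for neuron radius {rmax:.2f} um"
                )
            center = rng.uniform(margin, extent - margin)
            ok = all(
                np.linalg.norm(center - n.center) > rmax + n.radii.max() + 0.6 for n in neurons
            )
            if ok:
                neurons.append(Ellipsoid(center, radii, random_rotation(rng)))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not pack {cfg.n_neurons} neurons of ~{cfg.neuron_radius_um[0]} um "
                f"radius into extent {extent} um (non-overlap constraint)"
            )

    # --- place microglia against hosts -------------------------------------
    n_assoc = int(round(cfg.p_assoc * cfg.n_microglia))
    host_order = rng.permutation(cfg.n_neurons)
    microglia: list[Ellipsoid] = []
    pair_rows = []
    for m_idx in range(cfg.n_microglia):
        associated = m_idx < n_assoc
        target = cfg.coverage_assoc if associated else cfg.coverage_nonassoc
        host = neurons[host_order[m_idx % cfg.n_neurons]]
        host_id = int(host_order[m_idx % cfg.n_neurons]) + 1
        placed = None
        for _attempt in range(120):
            radii = _draw_radii(*cfg.microglia_radius_um, cfg.axis_distortion, rng)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            rot = random_rotation(rng)
            if target > 0:
                sol = _solve_apposition(host, radii, rot, direction, target, rng)
                if sol is None:
                    continue
                mg, achieved = sol
            else:
                d = host.mean_radius + float(np.cbrt(np.prod(radii))) + 1.2
                mg = Ellipsoid(host.center + d * direction, radii, rot)
                achieved = 0.0
            rmax = mg.radii.max()
            if np.any(mg.center - rmax < 0.6) or np.any(mg.center + rmax > extent - 0.6):
                continue
            clash = False
            for other in neurons:
                if other is host:
                    continue
                if np.linalg.norm(mg.center - other.center) < rmax + other.radii.max() + 0.5:
                    clash = True
            for other in microglia:
                if np.linalg.norm(mg.center - other.center) < rmax + other.radii.max() + 0.5:
                    clash = True
            if not clash:
                placed = (mg, achieved)
                break
        if placed is None:
            raise RuntimeError(
                f"could not appose microglia {m_idx + 1} to neuron {host_id} at "
                f"coverage {target:.3f} (radii {cfg.microglia_radius_um} vs "
                f"{cfg.neuron_radius_um}: coverage may be geometrically infeasible)"
            )
        mg, achieved = placed
        microglia.append(mg)
        pair_rows.append(
            {
                "neuron_id": host_id,
                "microglia_id": m_idx + 1,
                "planted_coverage_3d": achieved,
                "planted_contact_area": achieved * host.surface_area(),
                "associated": bool(associated),
            }
        )

    # --- puncta -------------------------------------------------------------
    punctum_rows = []
    pid = 0
    for row in pair_rows:
        neuron = neurons[row["neuron_id"] - 1]
        mg = microglia[row["microglia_id"] - 1]
        n_pre = int(rng.poisson(cfg.puncta_density * neuron.surface_area()))
        pts = _sample_surface_weighted(neuron, n_pre, rng) if n_pre else np.empty((0, 3))
        displaced_mask = mg.contains(pts) if n_pre else np.zeros(0, dtype=bool)
        n_displaced = int(displaced_mask.sum())
        for p in pts[~displaced_mask]:
            pid += 1
            punctum_rows.append(
                dict(id=pid, z_um=p[0], y_um=p[1], x_um=p[2], host="neuron_surface",
                     neuron_id=row["neuron_id"], microglia_id=row["microglia_id"])
            )
        if cfg.displacement_mode == "relocate" and n_displaced:
            relocated = _relocated_positions(mg, neuron, n_displaced, rng)
            for p in relocated:
                pid += 1
                punctum_rows.append(
                    dict(id=pid, z_um=p[0], y_um=p[1], x_um=p[2], host="microglia_surface",
                         neuron_id=row["neuron_id"], microglia_id=row["microglia_id"])
                )
        row["puncta_on_neuron"] = n_pre - n_displaced
        row["puncta_relocated"] = n_displaced

    for row in pair_rows:
        mg = microglia[row["microglia_id"] - 1]
        neuron = neurons[row["neuron_id"] - 1]
        n_eng = int(rng.poisson(cfg.engulf_rate))
        interior = _interior_positions(mg, neuron, n_eng, rng)
        for p in interior:
            pid += 1
            punctum_rows.append(
                dict(id=pid, z_um=p[0], y_um=p[1], x_um=p[2], host="microglia_interior",
                     neuron_id=row["neuron_id"], microglia_id=row["microglia_id"])
            )
        row["puncta_engulfed"] = len(interior)

    # --- paint labels -------------------------------------------------------
    neuron_labels = np.zeros(cfg.volume_shape, dtype=np.int32)
    for i, n in enumerate(neurons, start=1):
        n.paint(cfg.volume_shape, voxel_size, neuron_labels, i)
    microglia_labels = np.zeros(cfg.volume_shape, dtype=np.int32)
    neuron_mask = neuron_labels > 0
    for i, mg in enumerate(microglia, start=1):
        mg.paint(cfg.volume_shape, voxel_size, microglia_labels, i, mask_out=neuron_mask)
        for _ in range(cfg.n_processes):
            _paint_process(mg, microglia_labels, neuron_mask, voxel_size, cfg.volume_shape, i, rng)

    vol = LabeledVolume(
        labels={"neuron": neuron_labels, "microglia": microglia_labels},
        voxel_size=tuple(cfg.voxel_size),
    )

    # --- render intensities -------------------------------------------------
    noise_sd = 1.0 / cfg.snr
    intensities = {}
    for role, lab in vol.labels.items():
        img = ndimage.gaussian_filter((lab > 0).astype(np.float32), sigma=1.0)
        img += rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
        intensities[role] = img
    puncta_img = np.zeros(cfg.volume_shape, dtype=np.float32)
    sigma_um = np.array([1.0, 0.5, 0.5]) / 2.355  # FWHM 1 um (z), 0.5 um (xy)
    centers = np.array([[r["z_um"], r["y_um"], r["x_um"]] for r in punctum_rows]).reshape(-1, 3)
    _stamp_gaussians(puncta_img, centers, sigma_um, voxel_size)
    puncta_img += rng.normal(0.0, noise_sd, size=puncta_img.shape).astype(np.float32)
    intensities["puncta"] = puncta_img

    pairs = pd.DataFrame(pair_rows)
    puncta = pd.DataFrame(
        punctum_rows,
        columns=["id", "z_um", "y_um", "x_um", "host", "neuron_id", "microglia_id"],
    )
    def _cell_row(klass, i, e):
        row = dict(cell_class=klass, cell_id=i,
                   z_um=e.center[0], y_um=e.center[1], x_um=e.center[2],
                   radius_um=e.mean_radius, area_um2=e.surface_area(),
                   radius_z_um=e.radii[0], radius_y_um=e.radii[1], radius_x_um=e.radii[2])
        row.update({f"rot_{a}{b}": e.rotation[a, b] for a in range(3) for b in range(3)})
        return row

    cell_rows = [_cell_row("neuron_soma", i + 1, n) for i, n in enumerate(neurons)] + [
        _cell_row("microglia_soma", i + 1, m) for i, m in enumerate(microglia)
    ]
    truth = GroundTruth(pairs=pairs, puncta=puncta, cells=pd.DataFrame(cell_rows), config=cfg)
    return vol, intensities, truth


def _relocated_positions(mg: Ellipsoid, neuron: Ellipsoid, n: int, rng: np.random.Generator) -> np.ndarray:
    """Points on the exposed microglial surface, clear of the neuron."""
    out = []
    margin = 0.6 / float(neuron.radii.min())
    for _ in range(200):
        pts = _sample_surface_weighted(mg, max(4 * n, 16), rng)
        s = np.linalg.norm(neuron.scaled_coords(pts), axis=1)
        pts = pts[s > 1.0 + margin]
        out.extend(pts.tolist())
        if len(out) >= n:
            break
    if len(out) < n:
        raise RuntimeError("microglial surface too occluded to relocate puncta")
    return np.asarray(out[:n])


def _interior_positions(mg: Ellipsoid, neuron: Ellipsoid, n: int, rng: np.random.Generator) -> np.ndarray:
    """Points strictly inside the microglial label (crescent), >=0.4 um deep."""
    if n == 0:
        return np.empty((0, 3))
    depth = 0.4
    out = []
    n_margin = depth / float(neuron.radii.min())
    for _ in range(400):
        u = rng.standard_normal((max(8 * n, 32), 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frac = rng.uniform(0.3, 1.0 - depth / float(mg.radii.min()), size=(len(u), 1))
        pts = (u * frac * mg.radii) @ mg.rotation.T + mg.center
        s = np.linalg.norm(neuron.scaled_coords(pts), axis=1)
        pts = pts[s > 1.0 + n_margin]
        out.extend(pts.tolist())
        if len(out) >= n:
            break
    return np.asarray(out[:n]) if out else np.empty((0, 3))


def _paint_process(mg: Ellipsoid, out: np.ndarray, neuron_mask: np.ndarray,
                   voxel_size: np.ndarray, shape, value: int, rng: np.random.Generator,
                   length_um: float = 4.0, radius_um: float = 0.5) -> None:
    """A thin tubular protrusion leaving the soma along a random direction."""
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    start = mg.center + direction * (mg.mean_radius * 0.9)
    for t in np.arange(0.0, length_um, radius_um / 2):
        c = start + direction * t
        ball = Ellipsoid(c, np.full(3, radius_um), np.eye(3))
        ball.paint(shape, voxel_size, out, value, mask_out=neuron_mask)


def _stamp_gaussians(img: np.ndarray, centers_um: np.ndarray, sigma_um: np.ndarray,
                     voxel_size: np.ndarray, amplitude: float = 1.0) -> None:
    if len(centers_um) == 0:
        return
    half_um = 4.0 * sigma_um
    for c in centers_um:
        lo = np.maximum(((c - half_um) / voxel_size - 1).astype(int), 0)
        hi = np.minimum(((c + half_um) / voxel_size + 2).astype(int), img.shape)
        if np.any(lo >= hi):
            continue
        axes = [
            (np.arange(lo[k], hi[k]) + 0.5) * voxel_size[k] - c[k] for k in range(3)
        ]
        g = np.exp(
            -0.5 * (axes[0][:, None, None] ** 2 / sigma_um[0] ** 2
                    + axes[1][None, :, None] ** 2 / sigma_um[1] ** 2
                    + axes[2][None, None, :] ** 2 / sigma_um[2] ** 2)
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * g


# ---------------------------------------------------------------------------
# tabular cohort generator (statistical fast path)


def simulate_cohort(
    n_animals: int = 5,
    pairs_per_animal: int = 100,
    p_assoc: float = 0.3,
    coverage_assoc: float = 0.4,
    coverage_nonassoc: float = 0.04,
    coverage_sd: tuple[float, float] = (0.05, 0.02),
    puncta_mean: float = 40.0,
    engulf_rate: float = 2.0,
    displacement_mode: str = "relocate",
    animal_effect_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair-level cohort with the same statistical structure as the
    volumetric simulator, without image rendering.

    Each pair draws a pre-displacement Poisson puncta count; the displaced
    count is binomial with probability equal to the pair's realised surface
    coverage (puncta are uniform on the soma surface, so the coverage
    fraction *is* the displacement probability). ``animal_effect_sd``
    injects a lognormal per-animal scale on puncta counts to create
    intra-animal correlation.

    Returns a long-format table with one row per microglia-neuron pair:
    ``animal_id, pair_id, associated_true, coverage_3d, n_pre, n_on_neuron,
    n_on_microglia, n_engulfed, n_pair_total``.
    """
    if displacement_mode not in ("relocate", "suppress"):
        raise ValueError(f"unknown displacement_mode {displacement_mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for animal in range(1, n_animals + 1):
        scale = float(np.exp(rng.normal(0.0, animal_effect_sd))) if animal_effect_sd else 1.0
        assoc = rng.random(pairs_per_animal) < p_assoc
        cov = np.where(
            assoc,
            rng.normal(coverage_assoc, coverage_sd[0], pairs_per_animal),
            rng.normal(coverage_nonassoc, coverage_sd[1], pairs_per_animal),
        )
        cov = np.clip(cov, 0.0, 0.95)
        n_pre = rng.poisson(puncta_mean * scale, pairs_per_animal)
        displaced = rng.binomial(n_pre, cov)
        on_neuron = n_pre - displaced
        on_microglia = displaced if displacement_mode == "relocate" else np.zeros_like(displaced)
        engulfed = rng.poisson(engulf_rate, pairs_per_animal)
        for j in range(pairs_per_animal):
            rows.append(
                dict(
                    animal_id=animal,
                    pair_id=j + 1,
                    associated_true=bool(assoc[j]),
                    coverage_3d=float(cov[j]),
                    n_pre=int(n_pre[j]),
                    n_on_neuron=int(on_neuron[j]),
                    n_on_microglia=int(on_microglia[j]),
                    n_engulfed=int(engulfed[j]),
                    n_pair_total=int(on_neuron[j] + on_microglia[j]),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# co-culture time lapse


def simulate_coculture_tracks(
    n_microglia: int = 50,
    drift: float = 0.5,  # signed um/min toward (+) or away from (-) the soma
    speed_gain: float = 1.0,
    duration: float = 60.0,  # min
    dt: float = 1.0,  # min
    seed: int = 0,
    neuron_radius_um: float = 10.0,
    start_folds: tuple[float, float] = (1.5, 5.0),
    noise_um: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """2D drift-biased microglial walks around a central neuronal soma.

    The radial drift speed scales as ``|drift| * (1 + speed_gain * r / (r + d))``
    with ``d`` the distance to the soma boundary, so locomotion accelerates
    as cells close in when ``speed_gain > 0``. Positive ``drift`` biases the
    walk toward the soma; zero drift leaves a symmetric random walk.

    Returns a long-format trajectory table (``microglia_id, t_min, x_um,
    y_um``) plus the neuron geometry (centre at the origin, radius in um).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    rows = []
    r_n = neuron_radius_um
    for mid in range(1, n_microglia + 1):
        start_r = r_n * rng.uniform(*start_folds)
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([start_r * np.cos(theta), start_r * np.sin(theta)])
        for t in times:
            rows.append(dict(microglia_id=mid, t_min=float(t), x_um=float(p[0]), y_um=float(p[1])))
            rho = np.linalg.norm(p)
            d = max(rho - r_n, 0.05)
            inward = -p / max(rho, 1e-9)
            speed = abs(drift) * (1.0 + speed_gain * r_n / (r_n + d))
            step = np.sign(drift) * speed * dt * inward
            step = step + noise_um * np.sqrt(dt) * rng.standard_normal(2)
            p = p + step
            rho = np.linalg.norm(p)
            if rho < r_n:  # do not enter the soma
                p = p * (r_n / max(rho, 1e-9))
    tracks = pd.DataFrame(rows)
    geometry = {"center_um": (0.0, 0.0), "radius_um": r_n}
    return tracks, geometry


# ---------------------------------------------------------------------------
# calcium and LFP traces


def simulate_calcium(
    rate: float = 3.0,  # events/min
    amp: float = 0.5,  # dF/F
    tau: float = 1.0,  # s
    fs: float = 7.5,  # Hz
    duration: float = 240.0,  # s
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Event-train somatic calcium trace: baseline 1.0 plus instantaneous-rise
    exponential-decay transients plus white noise.

    Returns the raw fluorescence trace and the planted events (time in s,
    amplitude in dF/F units of the baseline).
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    trace = np.ones(n)
    n_events = rng.poisson(rate * duration / 60.0)
    times = np.sort(rng.uniform(0.0, duration, size=n_events))
    for t0 in times:
        m = t >= t0
        trace[m] += amp * np.exp(-(t[m] - t0) / tau)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    events = pd.DataFrame({"time_s": times, "amplitude": np.full(n_events, amp)})
    return trace, events


def simulate_lfp(
    fs: float = 2000.0,
    duration: float = 60.0,
    gamma_power: float = 100.0,  # uV^2 of the injected band-limited component
    gamma_band: tuple[float, float] = (30.0, 100.0),
    pink_exponent: float = 1.0,
    background_rms: float = 20.0,  # uV
    seed: int = 0,
) -> np.ndarray:
    """Pink-noise LFP with an injected band-limited gamma oscillation.

    The background is 1/f^alpha noise scaled to ``background_rms``; the
    gamma component is band-limited Gaussian noise scaled so its variance
    equals ``gamma_power`` exactly. With a fixed seed the background is
    identical across different ``gamma_power`` values, so power differences
    isolate the injection.
    """
    lo, hi = gamma_band
    if not (0.0 < lo < hi < fs / 2):
        raise ValueError(f"gamma_band {gamma_band} must lie inside (0, fs/2={fs / 2})")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # background
    spec = np.fft.rfft(rng.standard_normal(n))
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-pink_exponent / 2.0)
    bg = np.fft.irfft(spec * shaping, n)
    bg *= background_rms / bg.std()
    # gamma injection (always drawn, to keep the stream aligned)
    spec_g = np.fft.rfft(rng.standard_normal(n))
    band = (freqs >= lo) & (freqs <= hi)
    gm = np.fft.irfft(np.where(band, spec_g, 0.0), n)
    if gamma_power > 0:
        gm *= np.sqrt(gamma_power) / gm.std()
    else:
        gm = np.zeros(n)
    return bg + gm
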