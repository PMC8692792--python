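"""RVE selection and per-RVE alveolar morphometrics.

A representative volume element (RVE) is a ~500 μm cube assumed statistically
representative of the parenchyma.  Per cube this module measures the
standard morphometric quantities: porosity phi, mean alveolar diameter (least-squares sphere
fits), alveolar wall thickness (nearest-neighbour gap rule), alveolar surface
area / airspace volume via active-contour refinement plus marching-cubes
triangulation, and the derived surface-to-volume ratio rho = A/V and surface
density eta = A/V_ref.  By construction rho * phi == eta when all three come
from the same measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import marching_cubes
from skimage.segmentation import morphological_chan_vese, watershed

from .core import BinaryMask, axis_index
from .errors import ConfigurationError, PlacementError

log = logging.getLogger("lungmorph")

ZONES = ("apical", "mid", "basal")


@dataclass
class RVE:
    """Cubic subvolume of a binary mask (a view, not a copy)."""

    origin_vox: tuple[int, int, int]
    edge_vox: int
    zone_label: str
    mask_view: np.ndarray  # tissue = 1 / air = 0 subgrid
    spacing_um: float

    @property
    def edge_um(self) -> float:
        return self.edge_vox * self.spacing_um

    @property
    def volume_um3(self) -> float:
        return float(self.edge_vox**3) * self.spacing_um**3


@dataclass
class SphereFitResult:
    spheres: np.ndarray  # (n, 4): centre x,y,z [μm, RVE-local], radius [μm]
    residual_um: float  # RMS boundary-point distance over retained spheres

    def __len__(self) -> int:
        return len(self.spheres)

    @property
    def radii_um(self) -> np.ndarray:
        return self.spheres[:, 3] if len(self.spheres) else np.empty(0)


@dataclass
class SurfaceVolumeMeasurement:
    A_alv_um2: float
    V_airspace_um3: float
    V_ref_um3: float
    clipped_face_area_um2: float = 0.0  # excluded from A_alv, logged


@dataclass
class MorphometryRecord:
    """One row of the per-RVE morphometry table."""

    rho_per_mm: float
    phi: float
    eta_per_mm: float
    mean_diameter_um: float
    wall_thickness_um: float
    group_label: str = ""
    subject_id: str = ""
    zone_label: str = ""


# --------------------------------------------------------------------------


def nearest_odd(x: float) -> int:
    lo = int(np.floor(x))
    lo = lo if lo % 2 == 1 else lo - 1
    hi = lo + 2
    return hi if abs(hi - x) < abs(x - lo) else max(lo, 1)


def select_rves(
    mask: BinaryMask,
    edge_um: float = 500.0,
    n_per_zone: int = 3,
    exclusion_fraction: float = 0.30,
    seed: int = 0,
    zone_axis: str = "apical-basal",
    max_tries: int = 500,
    max_restarts: int = 40,
) -> list[RVE]:
    """Seeded rejection-sampling RVE selection, ``n_per_zone`` per zone.

    Zones are thirds along the apical–basal axis (low index = apical).  A
    candidate cube must lie entirely inside the analysis domain, must not
    overlap an accepted cube, and is rejected when its largest connected
    airspace component exceeds ``exclusion_fraction`` of the cube volume
    (proxy for bronchi / large vessels).  Because zones are filled greedily,
    an unlucky early placement can wedge a later zone; the whole selection
    is then restarted with a fresh sub-seed, up to ``max_restarts`` times.
    """
    last_err: PlacementError | None = None
    for restart in range(max_restarts):
        try:
            return _select_rves_once(
                mask, edge_um, n_per_zone, exclusion_fraction,
                np.random.default_rng([seed, restart]), zone_axis, max_tries,
            )
        except PlacementError as exc:
            last_err = exc
    raise last_err


def _select_rves_once(
    mask, edge_um, n_per_zone, exclusion_fraction, rng, zone_axis, max_tries
) -> list[RVE]:
    spacing = mask.spacing_um
    k = nearest_odd(edge_um / spacing)
    shape = mask.shape
    if any(k > s for s in shape):
        raise PlacementError(f"RVE edge {k} vox exceeds volume shape {shape}")
    ax = axis_index(mask.axis_labels, zone_axis)

    # integral image of the domain for O(1) fully-inside tests
    dom = mask.domain
    c = np.zeros(tuple(s + 1 for s in shape), dtype=np.int64)
    c[1:, 1:, 1:] = dom
    c = c.cumsum(0).cumsum(1).cumsum(2)

    def window_domain_count(o):
        i, j, l = o
        return int(
            c[i + k, j + k, l + k]
            - c[i, j + k, l + k] - c[i + k, j, l + k] - c[i + k, j + k, l]
            + c[i, j, l + k] + c[i, j + k, l] + c[i + k, j, l]
            - c[i, j, l]
        )

    n_ax = shape[ax]
    zone_bounds = np.round(np.linspace(0, n_ax, 4)).astype(int)
    accepted: list[RVE] = []

    def overlaps(o):
        for r in accepted:
            if all(o[a] < r.origin_vox[a] + k and r.origin_vox[a] < o[a] + k for a in range(3)):
                return True
        return False

    full = k**3
    for z, zone in enumerate(ZONES):
        placed = 0
        zlo, zhi = zone_bounds[z], zone_bounds[z + 1]
        # cubes still owed to later zones; preferring axial positions that
        # leave them room avoids wedging tight domains
        later = n_per_zone * (len(ZONES) - 1 - z)
        for trial in range(max_tries):
            if placed == n_per_zone:
                break
            origin = [0, 0, 0]
            for a in range(3):
                if a == ax:
                    # cube centre plane must fall inside the zone
                    lo = max(0, zlo - k // 2)
                    hi = min(shape[a] - k, zhi - 1 - k // 2)
                    if trial < max_tries // 2:
                        cap = shape[a] - k - k * later
                        if cap >= lo:
                            hi = min(hi, cap)
                else:
                    lo, hi = 0, shape[a] - k
                if hi < lo:
                    break
                origin[a] = int(rng.integers(lo, hi + 1))
            else:
                o = tuple(origin)
                if window_domain_count(o) != full or overlaps(o):
                    continue
                view = mask.voxels[o[0]:o[0] + k, o[1]:o[1] + k, o[2]:o[2] + k]
                air = view == 0
                if air.any():
                    lab, n = ndimage.label(air)
                    largest = np.bincount(lab.ravel())[1:].max() if n else 0
                    if largest > exclusion_fraction * full:
                        continue
                accepted.append(RVE(o, k, zone, view, spacing))
                placed += 1
                continue
            break  # zone too thin for the cube
        if placed < n_per_zone:
            raise PlacementError(
                f"could not place {n_per_zone} RVEs in zone {zone!r} "
                f"({placed} placed within {max_tries} tries)"
            )
    return accepted


def rve_porosity(rve: RVE) -> float:
    """Air-voxel fraction of the cube (exact count ratio)."""
    total = rve.mask_view.size
    return float((rve.mask_view == 0).sum()) / total


# --------------------------------------------------------------------------
# sphere fitting


def _fit_sphere_lsq(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit; returns (centre, radius, rms)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        return center, 0.0, np.inf
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(points - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def _interface_points(tissue: np.ndarray, spacing: float):
    """Midpoints of air/tissue voxel faces, with the air-side voxel index.

    Face midpoints straddle the true interface symmetrically, so sphere fits
    to them are unbiased to well below half a voxel.
    """
    air = ~tissue
    pts, owner = [], []
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        for air_side, tis_side, shift in ((lo, hi, 1.0), (hi, lo, 0.0)):
            faces = air[air_side] & tissue[tis_side]
            idx = np.argwhere(faces)
            if air_side is hi:
                idx = idx + np.eye(3, dtype=int)[a][None, :]
            p = (idx + 0.5) * spacing
            p[:, a] += (0.5 if air_side is lo else -0.5) * spacing
            pts.append(p)
            owner.append(idx)
    if not pts:
        return np.empty((0, 3)), np.empty((0, 3), dtype=int)
    return np.concatenate(pts), np.concatenate(owner)


def fit_alveolar_spheres(
    rve: RVE,
    min_separation_um: float = 7.0,
    min_radius_vox: float = 2.0,
    max_residual_frac: float = 0.5,
) -> SphereFitResult:
    """Least-squares sphere fits to each alveolar cavity in the RVE.

    Seeds are local maxima of the airspace Euclidean distance transform with
    a minimum separation of the expected wall thickness; each seed's
    watershed cell supplies the tissue-boundary point cloud for the fit.
    Spheres are discarded when the radius is < ``min_radius_vox`` voxels,
    the RMS residual exceeds ``max_residual_frac`` * radius, or the radius
    exceeds twice the seed's inscribed-sphere radius (degenerate fits to
    nearly planar point clouds otherwise explode).
    """
    tissue = rve.mask_view.astype(bool)
    spacing = rve.spacing_um
    air = ~tissue
    if not air.any():
        return SphereFitResult(np.empty((0, 4)), 0.0)

    edt = ndimage.distance_transform_edt(air, sampling=spacing)
    min_dist_vox = max(1, int(round(min_separation_um / spacing)))
    peaks = peak_local_max(
        edt,
        min_distance=min_dist_vox,
        threshold_abs=min_radius_vox * spacing,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return SphereFitResult(np.empty((0, 4)), 0.0)
    markers = np.zeros(air.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    cells = watershed(-edt, markers, mask=air)

    pts, owner = _interface_points(tissue, spacing)
    if len(pts) == 0:
        return SphereFitResult(np.empty((0, 4)), 0.0)
    labels = cells[tuple(owner.T)]

    spheres, residuals, weights = [], [], []
    for lab in range(1, len(peaks) + 1):
        sel = labels == lab
        if sel.sum() < 10:
            continue
        center, radius, rms = _fit_sphere_lsq(pts[sel])
        if radius < min_radius_vox * spacing or rms > max_residual_frac * radius:
            continue
        inscribed = edt[tuple(peaks[lab - 1])]
        if radius > 2.0 * inscribed + spacing:
            continue
        if np.any(center < 0) or np.any(center > np.array(air.shape) * spacing):
            continue
        spheres.append([*center, radius])
        residuals.append(rms)
        weights.append(sel.sum())
    if not spheres:
        return SphereFitResult(np.empty((0, 4)), 0.0)
    residual = float(np.sqrt(np.average(np.square(residuals), weights=weights)))
    return SphereFitResult(np.asarray(spheres), residual)


def mean_alveolar_diameter(fit: SphereFitResult) -> float:
    """Arithmetic mean of 2r over retained spheres; NaN when empty."""
    if len(fit) == 0:
        return float("nan")
    return float(np.mean(2.0 * fit.radii_um))


def wall_thickness(fit: SphereFitResult, max_gap_um: float = 20.0) -> float:
    """Mean septal wall thickness from contiguous sphere pairs.

    Each sphere's nearest neighbour (centre distance d) defines
    t = d − r_i − r_j; pairs with t <= 0 (overlap would contradict the foam
    model) or t > ``max_gap_um`` (cross-duct pairing) are excluded.  NaN when
    no admissible pair exists.
    """
    if len(fit) < 2:
        return float("nan")
    centers = fit.spheres[:, :3]
    radii = fit.spheres[:, 3]
    tree = cKDTree(centers)
    dist, idx = tree.query(centers, k=2)
    seen, gaps = set(), []
    for i, (d, j) in enumerate(zip(dist[:, 1], idx[:, 1])):
        pair = (min(i, j), max(i, j))
        if pair in seen:
            continue
        seen.add(pair)
        t = d - radii[i] - radii[j]
        if 0.0 < t <= max_gap_um:
            gaps.append(t)
    return float(np.mean(gaps)) if gaps else float("nan")


# --------------------------------------------------------------------------
# cavity surface & volume


def _voxelize_spheres_local(shape, spacing, spheres) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for x, y, z, r in spheres:
        lo = [max(0, int(np.ceil((c - r) / spacing - 0.5))) for c in (x, y, z)]
        hi = [min(shape[a] - 1, int(np.floor(((x, y, z)[a] + r) / spacing - 0.5)))
              for a in range(3)]
        if any(l > h for l, h in zip(lo, hi)):
            continue
        ax = [(np.arange(lo[a], hi[a] + 1) + 0.5) * spacing - (x, y, z)[a] for a in range(3)]
        d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= r * r
    return out


def cavity_surface_volume(
    rve: RVE,
    fit: SphereFitResult,
    iterations: int = 50,
    smoothing: int = 1,
    sigma_vox: float = 1.0,
) -> SurfaceVolumeMeasurement:
    """Active-contour refinement of the fitted spheres to the cavity boundary.

    The union of fitted spheres initializes a region-based morphological
    active contour (fixed iteration budget) on the binary image; the refined
    region gives V_airspace, and its Gaussian-smoothed iso-surface,
    triangulated by marching cubes, gives A_alv.  Cavities escaping the cube
    are clipped at the face; clipped-face area is excluded and logged.
    """
    spacing = rve.spacing_um
    v_ref = rve.volume_um3
    if len(fit) == 0:
        return SurfaceVolumeMeasurement(0.0, 0.0, v_ref)
    air = (rve.mask_view == 0).astype(np.float64)
    init = _voxelize_spheres_local(air.shape, spacing, fit.spheres) & (air > 0)
    if not init.any():
        return SurfaceVolumeMeasurement(0.0, 0.0, v_ref)
    seg = morphological_chan_vese(
        air, num_iter=iterations, init_level_set=init, smoothing=smoothing
    ).astype(bool)
    if (seg & init).sum() < 0.5 * init.sum():
        seg = ~seg  # contour polarity flipped during evolution
    v_air = float(seg.sum()) * spacing**3
    if v_air == 0.0:
        return SurfaceVolumeMeasurement(0.0, 0.0, v_ref)

    pad = 2
    padded = np.pad(seg.astype(np.float64), pad)
    smooth = ndimage.gaussian_filter(padded, sigma=sigma_vox)
    try:
        verts, faces, *_ = marching_cubes(smooth, level=0.5, spacing=(spacing,) * 3)
    except ValueError:
        return SurfaceVolumeMeasurement(0.0, v_air, v_ref)
    tri = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    centroids = tri.mean(axis=1)
    lo_um = pad * spacing  # centre of the first real voxel plane
    hi_um = [(s - 1 + pad) * spacing for s in seg.shape]
    clipped = np.zeros(len(areas), dtype=bool)
    for a in range(3):
        clipped |= (centroids[:, a] < lo_um) | (centroids[:, a] > hi_um[a])
    a_clip = float(areas[clipped].sum())
    if a_clip > 0:
        log.info("cavity clipped at RVE face: %.1f μm² excluded from A_alv", a_clip)
    return SurfaceVolumeMeasurement(float(areas[~clipped].sum()), v_air, v_ref, a_clip)


def rve_sv_ratio(m: SurfaceVolumeMeasurement) -> float:
    """Surface-to-volume ratio rho = A_alv / V_airspace (1/μm); NaN if V=0."""
    if m.V_airspace_um3 <= 0:
        return float("nan")
    return m.A_alv_um2 / m.V_airspace_um3


def measure_rve(
    rve: RVE,
    group_label: str = "",
    subject_id: str = "",
    max_gap_um: float = 20.0,
) -> MorphometryRecord:
    """Full per-RVE morphometry: one summary record (rho/eta in mm⁻¹).

    phi is the exact air-voxel fraction of the cube, rho comes from the
    active-contour cavity measurement, and eta is derived from the identity
    eta = rho * phi (which therefore holds exactly on every record).
    """
    fit = fit_alveolar_spheres(rve)
    m = cavity_surface_volume(rve, fit)
    phi = rve_porosity(rve)
    rho = rve_sv_ratio(m) * 1e3  # 1/μm → 1/mm
    eta = rho * phi
    return MorphometryRecord(
        rho_per_mm=rho,
        phi=phi,
        eta_per_mm=eta,
        mean_diameter_um=mean_alveolar_diameter(fit),
        wall_thickness_um=wall_thickness(fit, max_gap_um=max_gap_um),
        group_label=group_label,
        subject_id=subject_id,
        zone_label=rve.zone_label,
    )
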