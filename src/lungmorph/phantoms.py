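"""Synthetic alveolar-foam phantoms with exact morphometric ground truth.

The generator emulates fixed, air-inflated parenchyma as seen by high
resolution micro-CT (4 μm isotropic): quasi-spherical alveolar cavities of
30–55 μm diameter separated by ~7 μm septal walls.  Cavities are
non-overlapping spheres, so every downstream quantity has a closed-form or
exactly countable truth:

* a voxel is air iff its centre lies inside a cavity — voxel counts are exact;
* the continuum tissue–air interface area is the sum of analytic sphere areas
  (minus the spherical caps of cavities clipped by the box faces);
* the per-slab porosity profile is an exact voxel count per slab.

Packing geometry.  Candidate centres live on a jittered FCC lattice whose
nearest-neighbour distance is ``2*(mean + slack*sd) + wall_gap``; sites are
visited in a seeded random order and a sphere is placed only while its slab
is still below its porosity budget, with per-neighbour feasibility caps
keeping every pairwise gap >= ``wall_gap_um``.  Porosity is therefore
controlled by *thinning* the packing, never by rescaling radii, so the drawn
radius distribution is preserved.  Non-overlapping spheres with ~7 μm walls
cannot exceed a packing-geometry porosity ceiling (about 0.44 for 40 μm
cavities, 0.52 for 55 μm ones even at perfect FCC density); targets above
the ceiling saturate and are reported via :class:`SaturationWarning` while
the truth records the achieved values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import ANATOMICAL_AXES, BinaryMask, VolumeImage, axis_index
from .errors import ConfigurationError


class SaturationWarning(RuntimeWarning):
    """Packing saturated before the porosity target was reached."""


@dataclass(frozen=True)
class RadiusDistribution:
    """Truncated-normal cavity radius model (all lengths in μm)."""

    mean_um: float = 20.0
    sd_um: float = 1.0
    min_um: float = 15.0
    max_um: float = 27.5

    def __post_init__(self):
        if not (0 < self.min_um <= self.mean_um <= self.max_um):
            raise ConfigurationError(
                "radius bounds must satisfy 0 < min <= mean <= max, got "
                f"({self.min_um}, {self.mean_um}, {self.max_um})"
            )
        if self.sd_um < 0:
            raise ConfigurationError("radius sd must be >= 0")


@dataclass
class PhantomSpec:
    """Everything needed to generate one foam phantom reproducibly.

    ``box_um`` is either a cube edge or a 3-tuple of extents.  ``profile``
    (optional) prescribes a per-slab porosity target along ``profile_axis``:
    either a sequence of ``n_slabs`` values or a callable of the normalized
    axis position in [0, 1].  ``lattice_slack_sigmas`` widens the candidate
    lattice so that radius draws up to ``mean + slack*sd`` fit without
    capping (larger slack preserves the radius distribution better at the
    cost of a lower porosity ceiling).
    """

    box_um: float | tuple[float, float, float]
    spacing_um: float = 4.0
    radius: RadiusDistribution = field(default_factory=RadiusDistribution)
    target_porosity: float = 0.35
    wall_gap_um: float = 7.0
    profile: Callable[[float], float] | Sequence[float] | None = None
    profile_axis: str = "ventral-dorsal"
    n_slabs: int = 10
    seed: int = 0
    jitter_um: float = 1.0
    lattice_slack_sigmas: float = 0.5
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self):
        if np.isscalar(self.box_um):
            self.box_um = (float(self.box_um),) * 3
        else:
            self.box_um = tuple(float(b) for b in self.box_um)
            if len(self.box_um) != 3:
                raise ConfigurationError("box_um must be a scalar or 3-tuple")
        if not self.spacing_um > 0:
            raise ConfigurationError("spacing_um must be positive")
        if not (0.0 <= self.target_porosity < 1.0):
            raise ConfigurationError("target_porosity must lie in [0, 1)")
        if self.wall_gap_um < 0 or self.jitter_um < 0:
            raise ConfigurationError("wall_gap_um and jitter_um must be >= 0")
        if self.n_slabs < 1:
            raise ConfigurationError("n_slabs must be >= 1")
        if min(self.box_um) < 4 * self.radius.max_um:
            raise ConfigurationError(
                f"box extent {min(self.box_um)} μm < 4 x max radius "
                f"({4 * self.radius.max_um} μm)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(b / self.spacing_um)) for b in self.box_um)

    def slab_targets(self) -> np.ndarray:
        """Per-slab porosity targets along ``profile_axis``."""
        if self.profile is None:
            return np.full(self.n_slabs, self.target_porosity)
        if callable(self.profile):
            u = (np.arange(self.n_slabs) + 0.5) / self.n_slabs
            vals = np.asarray([float(self.profile(x)) for x in u])
        else:
            vals = np.asarray([float(v) for v in self.profile])
            if len(vals) != self.n_slabs:
                raise ConfigurationError(
                    f"profile sequence length {len(vals)} != n_slabs {self.n_slabs}"
                )
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise ConfigurationError("profile porosity values must lie in (0, 1)")
        return vals


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated phantom."""

    air_voxel_count: int
    total_voxel_count: int
    continuum_surface_area_um2: float
    spheres: np.ndarray  # (n, 4): centre x, y, z [μm], radius [μm]
    per_slab_porosity: np.ndarray
    slab_axis: int
    slab_targets: np.ndarray
    saturated_slabs: np.ndarray
    spacing_um: float

    @property
    def porosity(self) -> float:
        return self.air_voxel_count / self.total_voxel_count

    def to_records(self):
        """Per-sphere table rows (for the CSV sidecar export)."""
        return [
            {"x_um": x, "y_um": y, "z_um": z, "radius_um": r}
            for x, y, z, r in self.spheres
        ]


# --------------------------------------------------------------------------
# packing machinery


def _truncated_normal(rng, n, dist: RadiusDistribution) -> np.ndarray:
    if dist.sd_um == 0:
        return np.full(n, dist.mean_um)
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(200):
        k = int(todo.sum())
        if k == 0:
            break
        draw = rng.normal(dist.mean_um, dist.sd_um, size=k)
        ok = (draw >= dist.min_um) & (draw <= dist.max_um)
        idx = np.flatnonzero(todo)
        out[idx[ok]] = draw[ok]
        todo[idx[ok]] = False
    if todo.any():  # pathological sd; clamp the stragglers
        out[todo] = np.clip(
            rng.normal(dist.mean_um, dist.sd_um, int(todo.sum())),
            dist.min_um,
            dist.max_um,
        )
    return out


def _fcc_sites(box, d, margin, jitter, rng) -> np.ndarray:
    """Jittered FCC candidate centres covering the box plus a margin."""
    a = d * np.sqrt(2.0)  # conventional cubic cell edge
    lo = np.array([-margin] * 3)
    hi = np.asarray(box) + margin
    counts = np.ceil((hi - lo) / a).astype(int) + 1
    grid = np.stack(
        np.meshgrid(*(np.arange(c) for c in counts), indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    offsets = np.array(
        [[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
    )
    sites = (grid[:, None, :] + offsets[None, :, :]).reshape(-1, 3) * a + lo
    if jitter > 0:
        sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    keep = np.all((sites >= lo) & (sites <= hi), axis=1)
    return sites[keep]


def _sphere_voxels(center, r, spacing, shape):
    """Indices of in-box voxels whose centre lies inside the sphere."""
    lo = [max(0, int(np.ceil((center[a] - r) / spacing - 0.5))) for a in range(3)]
    hi = [min(shape[a] - 1, int(np.floor((center[a] + r) / spacing - 0.5)))
          for a in range(3)]
    if any(l > h for l, h in zip(lo, hi)):
        return None
    ax = [(np.arange(lo[a], hi[a] + 1) + 0.5) * spacing - center[a] for a in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    local = d2 <= r * r
    if not local.any():
        return None
    ii, jj, kk = np.nonzero(local)
    return ii + lo[0], jj + lo[1], kk + lo[2]


def _clipped_sphere_area(center, r, box) -> float:
    """Analytic in-box lateral area: 4 pi r^2 minus face caps.

    Exact for spheres clipped by at most one face; spheres straddling an edge
    or corner are slightly under-counted (rare at foam scale, noted in the
    methods documentation).
    """
    area = 4.0 * np.pi * r * r
    for a in range(3):
        for dist in (center[a], box[a] - center[a]):
            h = r - dist
            if h > 0:
                area -= 2.0 * np.pi * r * min(h, 2 * r)
    return max(area, 0.0)


def _slab_of_plane(n_planes: int, n_slabs: int) -> np.ndarray:
    edges = np.round(np.linspace(0, n_planes, n_slabs + 1)).astype(int)
    out = np.empty(n_planes, dtype=int)
    for s in range(n_slabs):
        out[edges[s]:edges[s + 1]] = s
    return out


def generate_sphere_foam(spec: PhantomSpec) -> tuple[BinaryMask, PhantomTruth]:
    """Generate a seeded sphere-foam phantom and its exact ground truth.

    Saturation (sites exhausted more than 0.02 below a slab's porosity
    target) raises :class:`SaturationWarning` and is recorded in the truth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    spacing = spec.spacing_um
    box = spec.box_um
    dist = spec.radius
    slab_axis = axis_index(spec.axis_labels, spec.profile_axis)

    targets = spec.slab_targets()
    # porosity is budgeted per slab even for uniform foams: it pins the
    # slab-scale density (thinning noise would otherwise leak into the
    # regional statistics as spurious between-ROI variance)
    n_budget = len(targets)
    budget_targets = targets
    slab_of_plane = _slab_of_plane(shape[slab_axis], n_budget)
    plane_voxels = np.prod(shape) // shape[slab_axis]
    slab_totals = np.bincount(slab_of_plane, minlength=n_budget) * plane_voxels
    target_counts = np.round(budget_targets * slab_totals).astype(np.int64)

    air = np.zeros(shape, dtype=bool)
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    slab_counts = np.zeros(n_budget, dtype=np.int64)

    if target_counts.sum() > 0:
        d_nn = 2.0 * (dist.mean_um + spec.lattice_slack_sigmas * dist.sd_um) + spec.wall_gap_um
        sites = _fcc_sites(box, d_nn, dist.max_um, spec.jitter_um, rng)
        draws = _truncated_normal(rng, len(sites), dist)
        # static neighbour lists: any pair that could ever conflict
        reach = 2.0 * dist.max_um + spec.wall_gap_um + 2.0 * spec.jitter_um
        tree = cKDTree(sites)
        pairs = tree.query_pairs(r=max(reach, d_nn * 1.05), output_type="ndarray")
        nbrs: list[list[int]] = [[] for _ in range(len(sites))]
        for i, j in pairs:
            nbrs[i].append(j)
            nbrs[j].append(i)

        radius_at = np.full(len(sites), np.nan)
        for i in rng.permutation(len(sites)):
            c = sites[i]
            # slab budgeting by the sphere's centre plane
            plane = int(np.clip(round(c[slab_axis] / spacing - 0.5), 0,
                                shape[slab_axis] - 1))
            slab = slab_of_plane[plane]
            if slab_counts[slab] >= target_counts[slab]:
                continue
            r = draws[i]
            for j in nbrs[i]:
                if not np.isnan(radius_at[j]):
                    gap_cap = float(np.linalg.norm(c - sites[j])) - spec.wall_gap_um - radius_at[j]
                    r = min(r, gap_cap)
            if r < dist.min_um:
                continue
            vox = _sphere_voxels(c, r, spacing, shape)
            radius_at[i] = r
            placed_centers.append(c)
            placed_radii.append(r)
            if vox is not None:
                air[vox] = True
                inc = np.bincount(slab_of_plane[vox[slab_axis]], minlength=n_budget)
                slab_counts += inc

    budget_achieved = slab_counts / slab_totals
    budget_saturated = np.flatnonzero(budget_achieved < budget_targets - 0.02)
    if budget_saturated.size:
        warnings.warn(
            "packing saturated below target porosity in slab(s) "
            f"{budget_saturated.tolist()}: achieved "
            f"{np.round(budget_achieved[budget_saturated], 3).tolist()} "
            f"vs target {np.round(budget_targets[budget_saturated], 3).tolist()}",
            SaturationWarning,
            stacklevel=2,
        )

    # per-slab truth is always reported on spec.n_slabs slabs along the axis
    report_slabs = _slab_of_plane(shape[slab_axis], spec.n_slabs)
    plane_air = np.moveaxis(air, slab_axis, 0).reshape(shape[slab_axis], -1).sum(axis=1)
    report_totals = np.bincount(report_slabs, minlength=spec.n_slabs) * plane_voxels
    per_slab = np.bincount(report_slabs, weights=plane_air,
                           minlength=spec.n_slabs) / report_totals
    saturated = budget_saturated

    spheres = (
        np.column_stack([np.asarray(placed_centers), np.asarray(placed_radii)])
        if placed_radii
        else np.empty((0, 4))
    )
    area = float(sum(_clipped_sphere_area(s[:3], s[3], box) for s in spheres))
    truth = PhantomTruth(
        air_voxel_count=int(air.sum()),
        total_voxel_count=int(np.prod(shape)),
        continuum_surface_area_um2=area,
        spheres=spheres,
        per_slab_porosity=per_slab,
        slab_axis=slab_axis,
        slab_targets=targets,
        saturated_slabs=saturated,
        spacing_um=spacing,
    )
    mask = BinaryMask(
        voxels=(~air).astype(np.uint8),
        spacing_um=spacing,
        axis_labels=spec.axis_labels,
    )
    return mask, truth


def generate_profile_foam(spec: PhantomSpec) -> tuple[BinaryMask, PhantomTruth]:
    """Foam with a slab-wise porosity profile along ``spec.profile_axis``."""
    if spec.profile is None:
        raise ConfigurationError("generate_profile_foam requires spec.profile")
    return generate_sphere_foam(spec)


def digitize_spheres(
    box_um, spacing_um, centers_um, radii_um, axis_labels=ANATOMICAL_AXES,
) -> tuple[BinaryMask, PhantomTruth]:
    """Voxelize an explicit (non-overlapping) sphere list with exact truth.

    Useful for single-cavity oracles where the packing machinery would get
    in the way.
    """
    box = (float(box_um),) * 3 if np.isscalar(box_um) else tuple(map(float, box_um))
    shape = tuple(int(round(b / spacing_um)) for b in box)
    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    radii = np.atleast_1d(np.asarray(radii_um, dtype=float))
    air = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, radii):
        vox = _sphere_voxels(c, r, spacing_um, shape)
        if vox is not None:
            air[vox] = True
    spheres = np.column_stack([centers, radii]) if len(radii) else np.empty((0, 4))
    area = float(sum(_clipped_sphere_area(c, r, box) for c, r in zip(centers, radii)))
    slab_of = _slab_of_plane(shape[0], 1)
    truth = PhantomTruth(
        air_voxel_count=int(air.sum()),
        total_voxel_count=int(np.prod(shape)),
        continuum_surface_area_um2=area,
        spheres=spheres,
        per_slab_porosity=np.array([air.mean()]),
        slab_axis=0,
        slab_targets=np.array([air.mean()]),
        saturated_slabs=np.empty(0, dtype=int),
        spacing_um=spacing_um,
    )
    return BinaryMask((~air).astype(np.uint8), spacing_um, axis_labels=axis_labels), truth


def saf_like_profile(u: float) -> float:
    """Concave ventral–dorsal porosity profile emulating ethanol-fixation
    (SAF-style) subpleural collapse: porosity reduced toward both pleural
    ends, normal at the core.  Values stay inside the sphere-foam generator's
    feasible range so every slab hits its target exactly.
    """
    return 0.30 + 0.15 * float(np.sin(np.pi * u)) ** 2


# --------------------------------------------------------------------------
# CT appearance and preparation artifacts


def apply_ct_appearance(
    mask: BinaryMask,
    mu_air: float = 50.0,
    mu_tissue: float = 200.0,
    psf_sigma_um: float = 4.0,
    noise_sigma: float = 15.0,
    seed: int = 0,
) -> VolumeImage:
    """Render a binary phantom as a CT-like grayscale volume.

    Two-level image (air/tissue class means), blurred by an isotropic
    Gaussian point-spread of width ``psf_sigma_um``, plus i.i.d. Gaussian
    noise.  Deterministic under a fixed seed.
    """
    if mu_air == mu_tissue:
        raise ConfigurationError("mu_air == mu_tissue is unsegmentable by construction")
    if psf_sigma_um < 0 or noise_sigma < 0:
        raise ConfigurationError("psf_sigma_um and noise_sigma must be >= 0")
    img = np.where(mask.tissue, float(mu_tissue), float(mu_air))
    if psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=psf_sigma_um / mask.spacing_um)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return VolumeImage(img, mask.spacing_um, mask.axis_labels)


def apply_subpleural_collapse(
    mask: BinaryMask, shell_depth_um: float, wall_dilation_um: float
) -> BinaryMask:
    """Thicken septal walls inside a boundary shell (micro-atelectasis model).

    Tissue is morphologically dilated, but the dilation is committed only
    within the shell measured inward from the domain boundary; the core is
    unchanged to the voxel.  Porosity never increases anywhere.
    """
    if shell_depth_um < 0 or wall_dilation_um < 0:
        raise ConfigurationError("depths must be >= 0")
    if shell_depth_um > min(mask.shape) * mask.spacing_um / 2:
        raise ConfigurationError("shell_depth_um exceeds half the box extent")
    if shell_depth_um == 0 or wall_dilation_um == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing_um,
                          mask.domain.copy(), mask.axis_labels)
    padded = np.pad(mask.domain, 1, constant_values=False)
    depth_um = ndimage.distance_transform_edt(padded, sampling=mask.spacing_um)
    shell = mask.domain & (depth_um[1:-1, 1:-1, 1:-1] <= shell_depth_um)
    r_vox = int(round(wall_dilation_um / mask.spacing_um))
    if r_vox == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing_um,
                          mask.domain.copy(), mask.axis_labels)
    from skimage.morphology import ball

    dilated = ndimage.binary_dilation(mask.tissue, structure=ball(r_vox))
    out = mask.tissue | (dilated & shell)
    return BinaryMask(out.astype(np.uint8), mask.spacing_um,
                      mask.domain.copy(), mask.axis_labels)


def voxel_surface_oracle(mask: BinaryMask, supersample: int = 1) -> float:
    """Reference tissue–air interface area (μm²), independent of the map path.

    Counts air/tissue voxel faces at (optionally supersampled) resolution and
    weights each face by ``|n_a|`` — the component of the locally estimated
    unit normal along the face axis — which makes the naive face count an
    unbiased area estimate (a flat axis-aligned interface is exact, a smooth
    surface converges as the grid refines).  Intended as a test-time oracle.
    """
    if supersample < 1:
        raise ConfigurationError("supersample must be >= 1")
    air = mask.air
    n_elem = air.size * supersample**3
    if n_elem > 3e8:
        raise ConfigurationError("supersampled volume too large (memory guard)")
    if supersample > 1:
        for a in range(3):
            air = np.repeat(air, supersample, axis=a)
    h = mask.spacing_um / supersample
    if not air.any() or air.all():
        return 0.0
    g = ndimage.gaussian_filter(air.astype(np.float32), sigma=float(supersample))
    grads = np.gradient(g)
    gnorm = np.sqrt(sum(gi * gi for gi in grads))
    area = 0.0
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        faces = air[sl_lo] != air[sl_hi]
        ga = 0.5 * (np.abs(grads[a][sl_lo]) + np.abs(grads[a][sl_hi]))
        gn = 0.5 * (gnorm[sl_lo] + gnorm[sl_hi])
        w = np.ones_like(ga)
        ok = gn > 1e-12
        w[ok] = np.clip(ga[ok] / gn[ok], 0.0, 1.0)
        area += float((w * faces).sum()) * h * h
    return area
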