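"""Voxel-wise 3D parameter maps by moving-mask convolution.

For every voxel, a cubic mask (kernel) of nominal size 140/105/70/35/17.5 μm
is centred on it and the quantity inside the mask is reduced to one number:

* porosity  phi  = mask airspace volume / mask total volume  (1 = all air);
* surface density  eta = tissue–air interface area inside the mask / mask
  volume (mm⁻¹), the interface being a marching-cubes triangulation of the
  smoothed binary boundary accumulated into a per-voxel area source field;
* surface-to-volume ratio  rho = eta / phi  voxel-wise (mm⁻¹), guarded by an
  epsilon on phi.

Window sums are exact integral-image counts, so the phi map is bit-identical
to brute-force per-voxel window counting.  Voxels whose mask exits the
analysis domain carry a NaN sentinel (no partial-window renormalization by
default).  The mask-size sensitivity analysis compares KDE-smoothed value
histograms across kernel sizes with an L1 convergence metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import iqr
from skimage.measure import marching_cubes

from ._window import box_sum
from .core import BinaryMask
from .errors import ConfigurationError, GridMismatchError

log = logging.getLogger("lungmorph")

#: Mask edge lengths (μm) used for the sensitivity analysis.
DEFAULT_MASK_SIZES_UM = (17.5, 35.0, 70.0, 105.0, 140.0)


@dataclass(frozen=True)
class MaskKernel:
    """Cubic moving mask: nominal size and the realized odd voxel edge."""

    nominal_size_um: float
    edge_vox: int
    spacing_um: float

    @property
    def actual_size_um(self) -> float:
        return self.edge_vox * self.spacing_um

    @property
    def volume_vox(self) -> int:
        return self.edge_vox**3


@dataclass
class ParameterMap:
    """Voxel-wise scalar field with its kernel, support and units.

    ``field`` is NaN outside ``support`` (out-of-domain or degenerate
    voxels); quantity is one of ``phi`` (dimensionless), ``eta`` or ``rho``
    (mm⁻¹).
    """

    field: np.ndarray
    quantity: str
    kernel: MaskKernel
    support: np.ndarray
    spacing_um: float
    units: str
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        """Supported (finite) voxel values, flattened."""
        return self.field[self.support]


def make_kernel(nominal_size_um: float, spacing_um: float) -> MaskKernel:
    """Kernel with edge = nearest odd voxel count to nominal/spacing."""
    if spacing_um <= 0:
        raise ConfigurationError("spacing must be positive")
    if nominal_size_um < 3 * spacing_um:
        raise ConfigurationError(
            f"mask size {nominal_size_um} μm below 3 voxels at {spacing_um} μm"
        )
    ratio = nominal_size_um / spacing_um
    lo = int(np.floor(ratio))
    lo = lo if lo % 2 == 1 else lo - 1
    edge = lo + 2 if abs(lo + 2 - ratio) < abs(ratio - lo) else max(lo, 3)
    edge = max(edge, 3)
    k = MaskKernel(nominal_size_um, edge, spacing_um)
    if abs(k.actual_size_um - nominal_size_um) > 1e-9:
        log.info(
            "mask size %.1f μm realized as %d voxels (%.1f μm)",
            nominal_size_um, edge, k.actual_size_um,
        )
    return k


def porosity_map(
    mask: BinaryMask, kernel: MaskKernel, domain: np.ndarray | None = None
) -> ParameterMap:
    """Moving-mask porosity: phi = mask airspace / mask volume, in [0, 1].

    Tissue volume inside each mask is the exact window count of tissue
    voxels; 1 means all air.  Masks exiting the domain carry NaN.
    """
    dom = mask.domain if domain is None else np.asarray(domain, dtype=bool)
    k = kernel.edge_vox
    tissue_sum, inside = box_sum(mask.voxels, k)
    dom_sum, _ = box_sum(dom.astype(np.uint8), k)
    support = inside & (dom_sum == kernel.volume_vox)
    out = np.full(mask.shape, np.nan)
    out[support] = (kernel.volume_vox - tissue_sum[support]) / kernel.volume_vox
    return ParameterMap(out, "phi", kernel, support, mask.spacing_um, "dimensionless")


def surface_field(mask: BinaryMask, sigma_vox: float = 1.0) -> np.ndarray:
    """Per-voxel tissue–air interface area source field (μm² per voxel).

    The boundary is the 0.5 iso-surface of the Gaussian-smoothed (default
    σ = 1 voxel) air indicator, triangulated by marching cubes; each
    triangle's area is accumulated into the voxel containing its centroid.
    The field sums to the total interface area.  Single-phase masks yield a
    zero field.
    """
    s = mask.spacing_um
    air = mask.air.astype(np.float64)
    fld = np.zeros(mask.shape)
    if air.min() == air.max():
        log.info("single-phase mask: zero surface field")
        return fld
    smooth = ndimage.gaussian_filter(air, sigma=sigma_vox)
    try:
        verts, faces, *_ = marching_cubes(smooth, level=0.5, spacing=(s, s, s))
    except ValueError:
        log.info("no 0.5 iso-surface after smoothing: zero surface field")
        return fld
    tri = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    idx = np.clip(
        np.round(tri.mean(axis=1) / s).astype(int),
        0,
        np.array(mask.shape) - 1,
    )
    np.add.at(fld, tuple(idx.T), areas)
    return fld


def surface_density_map(
    fld: np.ndarray,
    mask: BinaryMask,
    kernel: MaskKernel,
    domain: np.ndarray | None = None,
) -> ParameterMap:
    """Moving-mask surface density eta = area in mask / mask volume (mm⁻¹)."""
    dom = mask.domain if domain is None else np.asarray(domain, dtype=bool)
    if fld.shape != mask.shape:
        raise GridMismatchError(
            f"surface field shape {fld.shape} != mask shape {mask.shape}"
        )
    k = kernel.edge_vox
    area_sum, inside = box_sum(np.asarray(fld, dtype=np.float64), k)
    dom_sum, _ = box_sum(dom.astype(np.uint8), k)
    support = inside & (dom_sum == kernel.volume_vox)
    mask_volume_um3 = kernel.volume_vox * mask.spacing_um**3
    out = np.full(mask.shape, np.nan)
    out[support] = area_sum[support] / mask_volume_um3 * 1e3  # 1/μm → mm⁻¹
    return ParameterMap(out, "eta", kernel, support, mask.spacing_um, "mm^-1")


def sv_map(eta_map: ParameterMap, phi_map: ParameterMap, epsilon: float = 0.01) -> ParameterMap:
    """Surface-to-volume map rho = eta / phi voxel-wise (mm⁻¹).

    Voxels with phi < epsilon carry the NaN sentinel instead of a division
    blow-up; epsilon is recorded in the map metadata.
    """
    if eta_map.quantity != "eta" or phi_map.quantity != "phi":
        raise GridMismatchError("sv_map needs an eta map and a phi map")
    if eta_map.field.shape != phi_map.field.shape:
        raise GridMismatchError("eta and phi maps are on different grids")
    if eta_map.kernel.edge_vox != phi_map.kernel.edge_vox:
        raise GridMismatchError(
            f"kernel mismatch: eta {eta_map.kernel.edge_vox} vs phi "
            f"{phi_map.kernel.edge_vox} voxels"
        )
    support = eta_map.support & phi_map.support & (phi_map.field >= epsilon)
    out = np.full(eta_map.field.shape, np.nan)
    out[support] = eta_map.field[support] / phi_map.field[support]
    return ParameterMap(
        out, "rho", eta_map.kernel, support, eta_map.spacing_um, "mm^-1",
        meta={"epsilon": epsilon},
    )


# --------------------------------------------------------------------------
# mask-size sensitivity


@dataclass
class SensitivityResult:
    nominal_sizes_um: tuple
    kernels: list
    grid: np.ndarray
    densities: np.ndarray  # (n_sizes, n_grid), each integrates to 1
    l1_successive: np.ndarray  # L1 distance between successive-size KDEs

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"value": self.grid})
        for size, dens in zip(self.nominal_sizes_um, self.densities):
            df[f"kde_{size:g}um"] = dens
        return df


def _silverman_bw(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    spread = min(sd, iqr(values) / 1.34) if iqr(values) > 0 else sd
    if spread == 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * n ** (-1 / 5)


def kde_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) evaluated on a fixed grid.

    Computed by histogram binning plus Gaussian smoothing, which is exact up
    to grid resolution and independent of sample size.
    """
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    hist, _ = np.histogram(values, bins=edges)
    bw = _silverman_bw(values)
    dens = ndimage.gaussian_filter1d(hist.astype(float), sigma=max(bw / step, 1e-9))
    norm = np.trapezoid(dens, grid)
    return dens / norm if norm > 0 else dens


def sensitivity(
    mask: BinaryMask,
    nominal_sizes_um=DEFAULT_MASK_SIZES_UM,
    quantity: str = "phi",
    domain: np.ndarray | None = None,
    grid_points: int = 512,
) -> SensitivityResult:
    """Mask-size sensitivity: per-size KDE curves plus an L1 convergence metric.

    Sizes are processed in ascending order; ``l1_successive[i]`` is the L1
    distance between the KDE for size i and size i+1 (small = converged).
    """
    sizes = tuple(sorted(float(s) for s in nominal_sizes_um))
    if len(sizes) < 2:
        raise ConfigurationError("sensitivity requires at least 2 mask sizes")
    if quantity not in ("phi", "eta"):
        raise ConfigurationError(f"unsupported sensitivity quantity {quantity!r}")

    kernels = [make_kernel(s, mask.spacing_um) for s in sizes]
    fld = surface_field(mask) if quantity == "eta" else None
    maps = []
    for kern in kernels:
        if quantity == "phi":
            maps.append(porosity_map(mask, kern, domain))
        else:
            maps.append(surface_density_map(fld, mask, kern, domain))
    if quantity == "phi":
        grid = np.linspace(0.0, 1.0, grid_points)
    else:
        hi = max(float(np.nanmax(m.field)) for m in maps if m.support.any())
        grid = np.linspace(0.0, hi * 1.05 + 1e-12, grid_points)

    densities = np.stack([kde_curve(m.values, grid) for m in maps])
    l1 = np.array([
        np.trapezoid(np.abs(densities[i + 1] - densities[i]), grid)
        for i in range(len(sizes) - 1)
    ])
    return SensitivityResult(sizes, kernels, grid, densities, l1)
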