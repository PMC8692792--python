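"""Volume I/O, noise reduction, contrast enhancement, Otsu segmentation.

Supported formats are multi-page TIFF (with a mandatory JSON sidecar holding
the voxel spacing and anatomical axis labels) and NIfTI-1 (spacing from the
header zooms; labels embedded in the ``descrip`` field on write).  Spacing
is never silently assumed: a TIFF without a sidecar is a metadata error, an
anisotropic NIfTI is an unsupported input.

The preparation chain mirrors standard micro-CT practice: median then
Wiener filtering for noise, a white-top-hat / black-bottom-hat combination
plus optional histogram equalization for contrast, and Otsu thresholding on
a 256-bin histogram over the observed intensity range.  All filters operate
in 3D.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile
from scipy import ndimage, signal
from skimage import exposure
from skimage.filters import threshold_otsu

from .core import ANATOMICAL_AXES, BinaryMask, VolumeImage
from .errors import (
    ConfigurationError,
    MetadataError,
    SegmentationError,
    UnsupportedInputError,
)

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def read_volume(path, sidecar=None) -> VolumeImage:
    """Read a 3D grayscale volume from TIFF (+ JSON sidecar) or NIfTI-1."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise UnsupportedInputError(
                f"anisotropic voxel spacing {tuple(zooms)} is not supported"
            )
        spacing = float(zooms[0])
        if spacing <= 0:
            raise MetadataError(f"non-positive spacing in NIfTI header: {spacing}")
        labels = None
        descrip = img.header["descrip"].tobytes().decode("ascii", "ignore").rstrip("\x00")
        if descrip.startswith("axes="):
            labels = tuple(descrip[len("axes="):].split(","))
        if sidecar is not None:
            meta = json.loads(Path(sidecar).read_text())
            labels = tuple(meta.get("axis_labels", labels or ANATOMICAL_AXES))
        if labels is None:
            warnings.warn("NIfTI carries no axis labels; assuming the default order")
            labels = ANATOMICAL_AXES
        return VolumeImage(np.asarray(img.dataobj).astype(np.float64), spacing, labels)

    if name.endswith((".tif", ".tiff")):
        sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(
                f"TIFF volume {path} has no JSON sidecar ({sidecar}); voxel "
                "spacing must be supplied explicitly, never assumed"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing_um" not in meta:
            raise MetadataError(f"sidecar {sidecar} lacks 'spacing_um'")
        spacing = float(meta["spacing_um"])
        labels = tuple(meta.get("axis_labels", ANATOMICAL_AXES))
        return VolumeImage(tifffile.imread(str(path)).astype(np.float64), spacing, labels)

    raise UnsupportedInputError(f"unrecognized volume format: {path}")


def write_volume(volume: VolumeImage, path, extra_meta: dict | None = None) -> Path:
    """Write a volume losslessly; returns the main output path."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float64), affine=None)
        img.header.set_zooms((volume.spacing_um,) * 3)
        img.header["descrip"] = ("axes=" + ",".join(volume.axis_labels)).encode("ascii")
        nib.save(img, str(path))
        return path
    if name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), np.asarray(volume.voxels, dtype=np.float64))
        meta = {
            "spacing_um": volume.spacing_um,
            "axis_labels": list(volume.axis_labels),
            "provenance": extra_meta or {},
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
        return path
    raise UnsupportedInputError(f"unrecognized volume format: {path}")


def write_mask(mask: BinaryMask, path, extra_meta: dict | None = None) -> Path:
    """Write a binary mask as uint8 TIFF with its JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), mask.voxels)
    meta = {
        "spacing_um": mask.spacing_um,
        "axis_labels": list(mask.axis_labels),
        "provenance": extra_meta or {},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_mask(path, sidecar=None) -> BinaryMask:
    v = read_volume(path, sidecar)
    return BinaryMask(v.voxels.astype(np.uint8), v.spacing_um, axis_labels=v.axis_labels)


# --------------------------------------------------------------------------
# preparation chain


def denoise(v: VolumeImage, median_radius_vox: int = 1, wiener_window_vox: int = 3) -> VolumeImage:
    """Median then Wiener filtering; a radius/window of 0 disables a stage."""
    if median_radius_vox < 0 or wiener_window_vox < 0:
        raise ConfigurationError("filter radii must be >= 0")
    out = np.asarray(v.voxels, dtype=np.float64)
    if median_radius_vox > 0:
        size = 2 * median_radius_vox + 1
        if any(size > s for s in out.shape):
            raise ConfigurationError("median window larger than volume")
        out = ndimage.median_filter(out, size=size)
    if wiener_window_vox > 0:
        if any(wiener_window_vox > s for s in out.shape):
            raise ConfigurationError("Wiener window larger than volume")
        if np.ptp(out) > 0:  # Wiener on a constant is the identity; skip the 0/0
            out = signal.wiener(out, mysize=wiener_window_vox)
            out = np.nan_to_num(out, nan=float(np.nanmean(out)))
    return VolumeImage(out, v.spacing_um, v.axis_labels)


def enhance(v: VolumeImage, tophat_radius_vox: int = 2, equalize: bool = False) -> VolumeImage:
    """Contrast enhancement: input + white-top-hat − black-bottom-hat.

    The top-hat pair sharpens bright tissue ridges against dark airspace;
    optional histogram equalization (output rescaled to the input range)
    follows.  A radius of 0 with equalization off is the identity.
    """
    if tophat_radius_vox < 0:
        raise ConfigurationError("tophat radius must be >= 0")
    out = np.asarray(v.voxels, dtype=np.float64)
    if tophat_radius_vox > 0:
        size = 2 * tophat_radius_vox + 1
        if any(size > s for s in out.shape):
            raise ConfigurationError("top-hat window larger than volume")
        wth = ndimage.white_tophat(out, size=size)
        bth = ndimage.black_tophat(out, size=size)
        out = out + wth - bth
    if equalize:
        lo, hi = float(out.min()), float(out.max())
        if hi > lo:
            eq = exposure.equalize_hist(out)
            out = lo + eq * (hi - lo)
        # constant volume: degenerate histogram, leave unchanged
    return VolumeImage(out, v.spacing_um, v.axis_labels)


def segment_otsu(v: VolumeImage, polarity: str = "tissue-bright") -> tuple[float, BinaryMask]:
    """Otsu threshold on a 256-bin histogram; returns (threshold, mask).

    ``polarity`` states which phase is bright so the output honours the
    tissue = 1 convention regardless of the scanner's contrast convention.
    """
    if polarity not in ("tissue-bright", "tissue-dark"):
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    vox = np.asarray(v.voxels, dtype=np.float64)
    if float(vox.min()) == float(vox.max()):
        raise SegmentationError("constant-intensity volume cannot be thresholded")
    thr = float(threshold_otsu(vox, nbins=256))
    bright = vox > thr
    tissue = bright if polarity == "tissue-bright" else ~bright
    return thr, BinaryMask(tissue.astype(np.uint8), v.spacing_um, axis_labels=v.axis_labels)


def otsu_criterion(v: VolumeImage) -> float:
    """Between-class variance at the Otsu threshold (separability measure)."""
    vox = np.asarray(v.voxels, dtype=np.float64).ravel()
    thr = float(threshold_otsu(vox, nbins=256))
    lo, hi = vox[vox <= thr], vox[vox > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0, w1 = lo.size / vox.size, hi.size / vox.size
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def lung_domain(mask: BinaryMask, closing_radius_um: float = 30.0) -> np.ndarray:
    """Analysis domain: closed, hole-filled largest connected tissue component.

    Excludes exterior air so that map and ROI computations never see the
    space around the specimen.
    """
    tissue = mask.tissue
    if not tissue.any():
        raise SegmentationError("empty tissue mask has no lung domain")
    labels, n = ndimage.label(tissue, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = labels == int(np.argmax(counts))
    else:
        keep = labels > 0
    r_vox = int(round(closing_radius_um / mask.spacing_um))
    if r_vox > 0:
        from skimage.morphology import ball

        structure = ball(r_vox)
        pad = r_vox + 1
        padded = np.pad(keep, pad, constant_values=False)
        padded = ndimage.binary_closing(padded, structure=structure)
        keep = padded[pad:-pad, pad:-pad, pad:-pad]
    return ndimage.binary_fill_holes(keep)
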