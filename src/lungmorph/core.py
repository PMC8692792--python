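"""Core gridded containers shared by every pipeline stage.

Two containers cover the whole pipeline: :class:`VolumeImage` for grayscale
micro-CT data and :class:`BinaryMask` for the segmented tissue/air field.
Both carry an isotropic voxel spacing in micrometres and an ordered triple of
anatomical axis labels so that regional analyses (ventral–dorsal ROIs,
apical–basal RVE zones) never rely on array-order conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Canonical anatomical axis names, in the package's default array order.
ANATOMICAL_AXES = ("ventral-dorsal", "apical-basal", "left-right")


def _check_axis_labels(labels) -> tuple[str, str, str]:
    labels = tuple(labels)
    if len(labels) != 3 or len(set(labels)) != 3:
        raise ConfigurationError(f"need three distinct axis labels, got {labels!r}")
    for lab in labels:
        if lab not in ANATOMICAL_AXES:
            raise ConfigurationError(
                f"unknown axis label {lab!r}; expected one of {ANATOMICAL_AXES}"
            )
    return labels


def axis_index(labels, name: str) -> int:
    """Array axis carrying the anatomical direction *name*."""
    labels = tuple(labels)
    if name not in labels:
        raise ConfigurationError(f"axis {name!r} absent from labels {labels!r}")
    return labels.index(name)


@dataclass
class VolumeImage:
    """3D grayscale scalar field with isotropic voxel spacing in μm."""

    voxels: np.ndarray
    spacing_um: float
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError("VolumeImage requires a 3D array")
        if not self.spacing_um > 0:
            raise ConfigurationError("spacing_um must be positive")
        self.axis_labels = _check_axis_labels(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axis(self, name: str) -> int:
        return axis_index(self.axis_labels, name)


@dataclass
class BinaryMask:
    """Tissue/air labelling: tissue = 1, air = 0, plus a lung-domain support.

    ``domain`` marks the voxels that belong to the lung (or phantom box);
    analyses are restricted to it.  When omitted it defaults to the full grid.
    """

    voxels: np.ndarray
    spacing_um: float
    domain: np.ndarray | None = None
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ConfigurationError("BinaryMask requires a 3D array")
        if v.dtype != np.uint8:
            uniq = np.unique(v)
            if not np.isin(uniq, (0, 1)).all():
                raise ConfigurationError("mask voxels must be 0 (air) or 1 (tissue)")
            v = v.astype(np.uint8)
        self.voxels = v
        if not self.spacing_um > 0:
            raise ConfigurationError("spacing_um must be positive")
        if self.domain is None:
            self.domain = np.ones(v.shape, dtype=bool)
        else:
            self.domain = np.asarray(self.domain, dtype=bool)
            if self.domain.shape != v.shape:
                raise ConfigurationError("domain shape must match mask shape")
        self.axis_labels = _check_axis_labels(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def tissue(self) -> np.ndarray:
        return self.voxels.astype(bool)

    @property
    def air(self) -> np.ndarray:
        """Air voxels inside the analysis domain."""
        return (~self.voxels.astype(bool)) & self.domain

    def axis(self, name: str) -> int:
        return axis_index(self.axis_labels, name)

    def porosity(self) -> float:
        """Air fraction of the domain (airspace volume / domain volume)."""
        n = int(self.domain.sum())
        if n == 0:
            raise ConfigurationError("empty domain")
        return float(self.air.sum()) / n


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean fields (1.0 = identical)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
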