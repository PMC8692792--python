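"""Equal-volume regional ROIs and the study's statistical comparisons.

The lung domain is split into ``n_regions`` (default 10) contiguous
equal-volume slabs of advancing planes along the ventral–dorsal axis; maps
are summarized per ROI, groups are compared with Bonferroni-corrected
two-sided Mann–Whitney U tests, per-lung regional variability is assessed
with one-way ANOVA (after a D'Agostino–Pearson normality check when the
sample size permits it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import axis_index
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    GridMismatchError,
    InsufficientSampleError,
)
from .maps import ParameterMap


@dataclass
class ROIPartition:
    """Equal-volume slab partition of a domain along one anatomical axis."""

    axis: int
    axis_label: str
    n_regions: int
    labels: np.ndarray  # int grid: 1..n over the domain, 0 outside
    per_region_voxels: np.ndarray
    plane_regions: np.ndarray  # region index (0-based) of each plane


def partition_rois(
    domain: np.ndarray,
    axis,
    n_regions: int = 10,
    axis_labels=None,
) -> ROIPartition:
    """Partition a domain into equal-volume contiguous plane slabs.

    Planes along ``axis`` (an array axis or an anatomical label resolved via
    ``axis_labels``) are assigned greedily so cumulative in-domain voxel
    counts hit the k/n quantiles; every region's volume is within one
    plane's worth of voxels of the ideal equal share (the tightest balance
    a contiguous plane partition can guarantee).
    """
    domain = np.asarray(domain, dtype=bool)
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if isinstance(axis, str):
        if axis_labels is None:
            raise ConfigurationError("axis_labels needed to resolve an anatomical axis name")
        label = axis
        ax = axis_index(axis_labels, axis)
    else:
        ax = int(axis)
        label = axis_labels[ax] if axis_labels is not None else f"axis{ax}"
    total = int(domain.sum())
    if total < n_regions:
        raise ConfigurationError(
            f"domain has {total} voxels, fewer than {n_regions} regions"
        )

    plane_counts = domain.sum(axis=tuple(a for a in range(3) if a != ax))
    n_planes = domain.shape[ax]
    plane_regions = np.empty(n_planes, dtype=int)
    r, cum = 0, 0
    for p in range(n_planes):
        plane_regions[p] = r
        cum += int(plane_counts[p])
        while r < n_regions - 1 and cum >= total * (r + 1) / n_regions:
            r += 1

    shape = [1, 1, 1]
    shape[ax] = n_planes
    labels = np.where(domain, (plane_regions + 1).reshape(shape), 0)
    per_region = np.bincount(labels.ravel(), minlength=n_regions + 1)[1:]
    return ROIPartition(ax, label, n_regions, labels, per_region, plane_regions)


@dataclass
class RegionalSummary:
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    quantity: str
    empty_regions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": np.arange(1, len(self.means) + 1),
            "mean": self.means,
            "sd": self.sds,
            "n_voxels": self.counts,
        })


def regional_summary(pmap: ParameterMap, part: ROIPartition) -> RegionalSummary:
    """Per-ROI mean ± sample sd of a map over its supported voxels."""
    if pmap.field.shape != part.labels.shape:
        raise GridMismatchError("map and partition are on different grids")
    n = part.n_regions
    means = np.full(n, np.nan)
    sds = np.full(n, np.nan)
    counts = np.zeros(n, dtype=np.int64)
    for r in range(n):
        vals = pmap.field[(part.labels == r + 1) & pmap.support]
        counts[r] = vals.size
        if vals.size:
            means[r] = vals.mean()
            sds[r] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return RegionalSummary(means, sds, counts, pmap.quantity, np.flatnonzero(counts == 0))


def section_roi_values(
    pmap: ParameterMap,
    part: ROIPartition,
    section_axis: int,
    n_sections: int = 3,
) -> np.ndarray:
    """Per-(section, ROI) mean map values, shape (n_sections, n_regions).

    Sections are equal thirds (by default) along a second anatomical axis;
    this is the sampling layout used for per-lung regional variability
    analysis (each ROI contributes one value per section).
    """
    if section_axis == part.axis:
        raise ConfigurationError("section axis must differ from the ROI axis")
    bounds = np.round(np.linspace(0, pmap.field.shape[section_axis], n_sections + 1)).astype(int)
    out = np.full((n_sections, part.n_regions), np.nan)
    for s in range(n_sections):
        sl = [slice(None)] * 3
        sl[section_axis] = slice(bounds[s], bounds[s + 1])
        sl = tuple(sl)
        f = pmap.field[sl]
        sup = pmap.support[sl]
        lab = part.labels[sl]
        for r in range(part.n_regions):
            vals = f[(lab == r + 1) & sup]
            if vals.size:
                out[s, r] = vals.mean()
    return out


# --------------------------------------------------------------------------
# hypothesis tests


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact for small tie-free samples.

    Exact null distribution when both sides have n < 8 and there are no
    ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("empty sample in Mann–Whitney test")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) < 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_bonferroni(
    samples_by_group_and_roi: dict,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons per ROI with Bonferroni correction.

    ``samples_by_group_and_roi`` maps group → {roi → 1D samples}; each cell
    needs >= 3 observations.  ``n_comparisons`` defaults to the number of
    group pairs (the multiple-group correction); the returned table carries
    raw p-values, the corrected threshold and significance flags.
    """
    groups = list(samples_by_group_and_roi)
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups")
    pairs = list(itertools.combinations(groups, 2))
    if n_comparisons is None:
        n_comparisons = len(pairs)
    threshold = alpha / n_comparisons
    rows = []
    for ga, gb in pairs:
        rois = sorted(set(samples_by_group_and_roi[ga]) & set(samples_by_group_and_roi[gb]))
        for roi in rois:
            x = np.asarray(samples_by_group_and_roi[ga][roi], dtype=float)
            y = np.asarray(samples_by_group_and_roi[gb][roi], dtype=float)
            if x.size < 3 or y.size < 3:
                raise ConfigurationError(
                    f"cell ({ga}, {roi}) or ({gb}, {roi}) has fewer than 3 observations"
                )
            u, p = mann_whitney_u(x, y)
            rows.append({
                "roi": roi, "group_a": ga, "group_b": gb, "U": u,
                "p_raw": p, "alpha": alpha, "threshold": threshold,
                "significant": p <= threshold,
            })
    return pd.DataFrame(rows)


def normality_dagostino(sample) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus K² normality test (validity floor n >= 20)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 20:
        raise InsufficientSampleError(
            f"D'Agostino–Pearson requires n >= 20, got {sample.size}"
        )
    k2, p = stats.normaltest(sample)
    return float(k2), float(p)


def anova_sections(values_by_section) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across sections/regions.

    Accepts a mapping label → samples or a sequence of sample arrays.
    Identical groups give F = 0; zero within-group variance with unequal
    means is a degenerate input (F would be infinite).
    """
    if isinstance(values_by_section, dict):
        groups = [np.asarray(v, dtype=float) for v in values_by_section.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_section]
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs at least two sections")
    if any(g.size < 2 for g in groups):
        raise ConfigurationError("every section needs at least two values")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        raise DegenerateInputError(
            "zero within-group variance with unequal means (infinite F)"
        )
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def roi_variability_anova(
    pmap: ParameterMap,
    part: ROIPartition,
    section_axis: int,
    n_sections: int = 3,
) -> tuple[float, float]:
    """Per-lung regional-variability ANOVA: groups = ROIs, samples = sections."""
    vals = section_roi_values(pmap, part, section_axis, n_sections)
    groups = [vals[:, r][~np.isnan(vals[:, r])] for r in range(part.n_regions)]
    groups = [g for g in groups if g.size >= 2]
    return anova_sections(groups)


# --------------------------------------------------------------------------
# group summary table


_QUANTITIES = {
    "rho_per_mm": "Surface-to-volume ratio (mm^-1)",
    "mean_diameter_um": "Mean alveolar diameter (um)",
    "wall_thickness_um": "Alveolar wall thickness (um)",
    "phi": "Porosity",
    "eta_per_mm": "Alveolar surface density (mm^-1)",
}


def group_table(records, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean ± sample sd table plus pairwise Mann–Whitney flags.

    ``records`` is an iterable of :class:`~lungmorph.rve.MorphometryRecord`.
    Returns ``(summary, comparisons)``; comparisons use Bonferroni over the
    group pairs within each quantity.
    """
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise ConfigurationError("no records")
    groups = sorted(df["group_label"].unique())
    rows = []
    for g in groups:
        sub = df[df["group_label"] == g]
        row = {"group": g, "n": len(sub)}
        for qty in _QUANTITIES:
            vals = sub[qty].dropna()
            row[f"{qty}_mean"] = vals.mean()
            row[f"{qty}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    summary = pd.DataFrame(rows)

    comp_rows = []
    pairs = list(itertools.combinations(groups, 2))
    n_comp = max(len(pairs), 1)
    for qty in _QUANTITIES:
        for ga, gb in pairs:
            x = df.loc[df["group_label"] == ga, qty].dropna().to_numpy()
            y = df.loc[df["group_label"] == gb, qty].dropna().to_numpy()
            if x.size < 3 or y.size < 3:
                continue
            u, p = mann_whitney_u(x, y)
            comp_rows.append({
                "quantity": qty, "group_a": ga, "group_b": gb, "U": u,
                "p_raw": p, "threshold": alpha / n_comp,
                "significant": p <= alpha / n_comp,
            })
    return summary, pd.DataFrame(comp_rows)
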