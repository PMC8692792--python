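"""ROI partitioning and the statistical test battery with independent oracles."""

import itertools
import math

import numpy as np
import pytest

import lungmorph as lm
from lungmorph.maps import MaskKernel, ParameterMap
from lungmorph.phantoms import saf_like_profile
from lungmorph.rve import MorphometryRecord

from conftest import make_foam

SPACING = 4.0


def constant_map(shape, value, support=None):
    support = np.ones(shape, dtype=bool) if support is None else support
    fld = np.where(support, float(value), np.nan)
    return ParameterMap(fld, "phi", MaskKernel(12.0, 3, SPACING), support, SPACING,
                        "dimensionless")


class TestPartition:
    def test_uniform_cuboid_exact_planes(self):
        dom = np.ones((100, 12, 12), dtype=bool)
        part = lm.partition_rois(dom, 0, 10)
        assert np.all(np.bincount(part.plane_regions) == 10)
        assert np.all(part.per_region_voxels == 100 * 12 * 12 // 10)

    def test_hemispherical_domain_balanced(self):
        z, y, x = np.indices((60, 60, 60))
        dom = ((z - 59.0) ** 2 + (y - 30.0) ** 2 + (x - 30.0) ** 2) <= 29.0**2
        part = lm.partition_rois(dom, 0, 10)
        plane_counts = dom.sum(axis=(1, 2))
        dev = np.abs(part.per_region_voxels - dom.sum() / 10).max()
        assert dev <= plane_counts.max()

    @pytest.mark.parametrize("seed", range(20))
    def test_random_domains_balanced_within_one_plane(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(24, 48, size=3))
        centre = rng.uniform(0.3, 0.7, size=3) * shape
        radius = rng.uniform(0.3, 0.45) * min(shape)
        idx = np.indices(shape)
        dom = sum((idx[a] - centre[a]) ** 2 for a in range(3)) <= radius**2
        axis = int(rng.integers(0, 3))
        part = lm.partition_rois(dom, axis, 10)
        plane_counts = dom.sum(axis=tuple(a for a in range(3) if a != axis))
        dev = np.abs(part.per_region_voxels - dom.sum() / 10).max()
        assert dev <= plane_counts.max()
        assert part.per_region_voxels.sum() == dom.sum()

    def test_anatomical_axis_resolution(self):
        dom = np.ones((20, 30, 40), dtype=bool)
        part = lm.partition_rois(dom, "left-right", 10, lm.ANATOMICAL_AXES)
        assert part.axis == 2
        with pytest.raises(lm.ConfigurationError):
            lm.partition_rois(dom, "left-right", 10)  # no labels supplied

    def test_zero_regions_rejected(self):
        with pytest.raises(lm.ConfigurationError):
            lm.partition_rois(np.ones((10, 10, 10), dtype=bool), 0, 0)


class TestRegionalSummary:
    def test_constant_map(self):
        pmap = constant_map((40, 20, 20), 0.42)
        part = lm.partition_rois(np.ones((40, 20, 20), dtype=bool), 0, 10)
        summ = lm.regional_summary(pmap, part)
        assert np.allclose(summ.means, 0.42)
        assert np.allclose(summ.sds, 0.0)
        assert summ.empty_regions.size == 0

    def test_uniform_foam_regions_on_target(self):
        mask, truth = make_foam(box_um=(400.0, 360.0, 360.0), seed=12)
        pmap = lm.porosity_map(mask, lm.make_kernel(35.0, SPACING))
        part = lm.partition_rois(pmap.support, 0, 10)
        summ = lm.regional_summary(pmap, part)
        assert np.all(np.abs(summ.means - 0.35) <= 0.02)

    def test_concave_profile_recovered(self):
        mask, truth = make_foam(
            box_um=(400.0, 360.0, 360.0),
            radius=lm.RadiusDistribution(25.0, 0.75, 15.0, 27.5),
            profile=saf_like_profile, seed=13,
        )
        pmap = lm.porosity_map(mask, lm.make_kernel(35.0, SPACING))
        part = lm.partition_rois(pmap.support, 0, 10)
        summ = lm.regional_summary(pmap, part)
        assert np.all(np.abs(summ.means - truth.per_slab_porosity) <= 0.03)
        peak = int(np.argmax(summ.means))
        assert 3 <= peak <= 6

    def test_grid_mismatch_rejected(self):
        pmap = constant_map((20, 20, 20), 0.5)
        part = lm.partition_rois(np.ones((30, 20, 20), dtype=bool), 0, 10)
        with pytest.raises(lm.GridMismatchError):
            lm.regional_summary(pmap, part)


def exhaustive_mannwhitney_p(x, y):
    """Enumerate all label arrangements: exact two-sided U-test p-value."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + \
            0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    n2 = len(y)
    mean_u = n1 * n2 / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_textbook_separated_triplets(self):
        u, p = lm.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert exhaustive_mannwhitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = lm.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            pooled = rng.permutation(np.arange(1.0, 2 * n + 1))  # tie-free
            x, y = pooled[:n], pooled[n:]
            _, p = lm.mann_whitney_u(x, y)
            assert p == pytest.approx(exhaustive_mannwhitney_p(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(lm.ConfigurationError):
            lm.mann_whitney_u([], [1, 2, 3])

    def test_bonferroni_flags(self):
        rng = np.random.default_rng(0)
        samples = {
            "SAF": {1: rng.normal(0.51, 0.02, 9), 2: rng.normal(0.51, 0.02, 9)},
            "MAF": {1: rng.normal(0.65, 0.02, 9), 2: rng.normal(0.51, 0.02, 9)},
            "HMDS": {1: rng.normal(0.65, 0.02, 9), 2: rng.normal(0.51, 0.02, 9)},
        }
        df = lm.mannwhitney_bonferroni(samples, alpha=0.05)
        assert set(df["threshold"]) == {0.05 / 3}
        pair = df[["group_a", "group_b"]].apply(frozenset, axis=1)
        sep = df[(pair == frozenset({"MAF", "SAF"})) & (df.roi == 1)]
        assert bool(sep["significant"].iloc[0])
        same = df[(pair == frozenset({"MAF", "SAF"})) & (df.roi == 2)]
        assert not bool(same["significant"].iloc[0])

    def test_bonferroni_threshold_arithmetic(self):
        # p = 0.01 vs alpha/n = 0.05/3: significant
        assert 0.01 <= 0.05 / 3

    def test_family_wise_error_controlled(self):
        # 10 null comparisons per family, 1000 replicates: FWER <= 0.05
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            flagged = False
            for _ in range(10):
                x = rng.normal(size=9)
                y = rng.normal(size=9)
                _, p = lm.mann_whitney_u(x, y)
                if p <= 0.05 / 10:
                    flagged = True
                    break
            hits += flagged
        assert hits / n_rep <= 0.05


class TestNormality:
    def test_validity_floor(self):
        with pytest.raises(lm.InsufficientSampleError):
            lm.normality_dagostino(np.arange(8))

    def test_level_on_normal_draws(self):
        rng = np.random.default_rng(7)
        passes = sum(lm.normality_dagostino(rng.normal(size=500))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_power_on_skewed_draws(self):
        rng = np.random.default_rng(8)
        rejects = sum(lm.normality_dagostino(rng.exponential(size=500))[1] < 0.05
                      for _ in range(100))
        assert rejects >= 95


class TestAnova:
    def test_hand_computed_f(self):
        f, p = lm.anova_sections([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)  # SSB = 6, SSW = 6, df = (2, 6)
        assert 0 < p < 1

    def test_identical_groups_f_zero(self):
        f, p = lm.anova_sections([[2, 2, 2], [2, 2, 2]])
        assert (f, p) == (0.0, 1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(lm.DegenerateInputError):
            lm.anova_sections([[1, 1], [2, 2]])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejects = sum(
            lm.anova_sections([rng.normal(size=5) for _ in range(3)])[1] < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejects / 1000 <= 0.07


class TestGroupTable:
    @staticmethod
    def record(group, rho=60.0, phi=0.6, dia=40.0, wall=7.0):
        return MorphometryRecord(rho_per_mm=rho, phi=phi, eta_per_mm=rho * phi,
                                 mean_diameter_um=dia, wall_thickness_um=wall,
                                 group_label=group, subject_id="s1",
                                 zone_label="mid")

    def test_identical_records_zero_sd(self):
        summary, _ = lm.group_table([self.record("A") for _ in range(5)])
        assert summary.loc[0, "phi_sd"] == 0.0
        assert summary.loc[0, "n"] == 5

    def test_sample_sd(self):
        summary, _ = lm.group_table([self.record("A", rho=2.0),
                                     self.record("A", rho=4.0),
                                     self.record("A", rho=4.0)])
        vals = np.array([2.0, 4.0, 4.0])
        assert summary.loc[0, "rho_per_mm_mean"] == pytest.approx(vals.mean())
        assert summary.loc[0, "rho_per_mm_sd"] == pytest.approx(vals.std(ddof=1))

    def test_separated_groups_flagged(self):
        rng = np.random.default_rng(1)
        recs = [self.record("lo", phi=float(rng.normal(0.30, 0.01))) for _ in range(9)]
        recs += [self.record("hi", phi=float(rng.normal(0.40, 0.01))) for _ in range(9)]
        _, comparisons = lm.group_table(recs)
        row = comparisons[comparisons["quantity"] == "phi"].iloc[0]
        assert row["significant"]


class TestProfileDetection:
    """End-to-end regional pipeline on small phantoms (single-seed smoke;
    the replicated detection-rate study lives in the acceptance checks)."""

    @staticmethod
    def run(seed, profile):
        spec = lm.PhantomSpec(
            box_um=(400.0, 360.0, 360.0), spacing_um=SPACING,
            radius=lm.RadiusDistribution(25.0, 0.75, 15.0, 27.5),
            profile=profile, seed=seed,
        )
        mask, _ = lm.generate_sphere_foam(spec)
        pmap = lm.porosity_map(mask, lm.make_kernel(35.0, SPACING))
        part = lm.partition_rois(pmap.support, 0, 10)
        return lm.roi_variability_anova(pmap, part, section_axis=1)

    def test_concave_profile_flagged(self):
        _, p = self.run(21, saf_like_profile)
        assert p < 0.05

    def test_uniform_profile_not_flagged(self):
        _, p = self.run(22, None)
        assert p >= 0.05
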