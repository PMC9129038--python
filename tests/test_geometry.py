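"""Geometry metrics against analytic shapes and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import nucleofish as nf
from nucleofish.geometry import SPHERE_SHELL_DEPTH_FRACTIONS, shell_voxel_counts

from conftest import (SPACING, brute_force_signed_distance, make_ellipsoid_mask,
                      make_sphere_mask, random_blob_mask)

HALF_DIAG = 0.5 * nf.voxel_diagonal(SPACING)


class TestSignedBorderDistance:
    def test_sphere_centre_is_radius(self):
        mask, centre = make_sphere_mask(radius_um=1.0)
        d = nf.signed_border_distance(centre, mask)
        assert d == pytest.approx(1.0, abs=HALF_DIAG)

    def test_outside_point_is_negative(self):
        mask, centre = make_sphere_mask(radius_um=1.0)
        point = centre + np.array([0.0, 0.0, 1.2])  # 0.2 um beyond surface
        d = nf.signed_border_distance(point, mask)
        assert d == pytest.approx(-0.2, abs=HALF_DIAG)

    def test_ellipsoid_matches_border_scan(self):
        mask, centre = make_ellipsoid_mask((1.0, 1.5, 2.0))
        point = centre + np.array([0.0, 0.0, 1.0])
        d = nf.signed_border_distance(point, mask)
        assert d == pytest.approx(brute_force_signed_distance(point, mask),
                                  abs=1e-9)

    def test_oracle_equivalence_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            mask = random_blob_mask(rng, max_shape=24)
            extent = (np.array(mask.mask.shape) - 1) * np.array(SPACING)
            for _ in range(4):
                p = rng.uniform(0, 1, 3) * extent
                assert nf.signed_border_distance(p, mask) == pytest.approx(
                    brute_force_signed_distance(p, mask), abs=1e-9)

    def test_anisotropy_doubling_z(self):
        # a distance purely along z doubles exactly when dz doubles
        for dz in (0.15, 0.30):
            mask, centre = make_sphere_mask(1.0, spacing=(dz, 0.1, 0.1))
            p = centre + np.array([0.9, 0.0, 0.0])
            expected = brute_force_signed_distance(p, mask)
            assert nf.signed_border_distance(p, mask) == pytest.approx(
                expected, abs=1e-9)

    def test_out_of_bounds_raises(self):
        mask, centre = make_sphere_mask(1.0)
        with pytest.raises(ValueError, match="outside"):
            nf.signed_border_distance(centre + 100.0, mask)


class TestLocalRadius:
    def test_sphere_any_interior_spot(self):
        mask, centre = make_sphere_mask(1.0)
        for offset in ([0.3, 0.0, 0.0], [0.0, -0.4, 0.3], [0.2, 0.2, 0.2]):
            r = nf.local_radius(centre + np.array(offset), mask)
            assert r == pytest.approx(1.0, abs=HALF_DIAG)

    def test_ellipsoid_major_axis(self):
        mask, centre = make_ellipsoid_mask((1.0, 1.5, 2.0))
        r = nf.local_radius(centre + np.array([0.0, 0.0, 1.0]), mask)
        assert r == pytest.approx(2.0, abs=HALF_DIAG)

    def test_coincident_spot_equivalent_sphere(self):
        mask, centre = make_sphere_mask(1.0)
        r = nf.local_radius(centre, mask)
        assert r == pytest.approx(mask.equivalent_radius_um, abs=1e-9)
        assert r == pytest.approx(1.0, abs=HALF_DIAG)


class TestRelativeDistance:
    @pytest.mark.parametrize("d, r, expected",
                             [(1.0, 1.0, 1.0), (0.0, 2.5, 0.0),
                              (0.5, 2.0, 0.25), (-0.2, 2.0, -0.1)])
    def test_arithmetic(self, d, r, expected):
        assert nf.relative_distance(d, r) == pytest.approx(expected)

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            nf.relative_distance(1.0, 0.0)


class TestNuclearVolume:
    def test_solid_block(self):
        block = np.ones((10, 10, 10), bool)
        mask = nf.NucleusMask(block, (0.15, 0.1, 0.1))
        assert nf.nuclear_volume(mask) == pytest.approx(1.5)

    def test_sphere_analytic(self):
        mask, _ = make_sphere_mask(1.0)
        analytic = 4.0 / 3.0 * np.pi
        # voxelization error scales with surface area x voxel size
        assert nf.nuclear_volume(mask) == pytest.approx(analytic, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nf.NucleusMask(np.zeros((5, 5, 5), bool), SPACING)


class TestEqualVolumeShells:
    def test_sphere_analytic_thresholds(self):
        mask, _ = make_sphere_mask(1.0)
        part = nf.equal_volume_shells(mask)
        t1_frac, t2_frac = SPHERE_SHELL_DEPTH_FRACTIONS
        assert part.t1 == pytest.approx(t1_frac, abs=1.5 * HALF_DIAG)
        assert part.t2 == pytest.approx(t2_frac, abs=1.5 * HALF_DIAG)

    def test_thirds_and_conservation_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mask = random_blob_mask(rng, max_shape=32)
            try:
                part = nf.equal_volume_shells(mask)
            except ValueError:
                continue  # mask legitimately too small for three shells
            counts = shell_voxel_counts(mask, part)
            total = sum(counts.values())
            assert total == int(mask.mask.sum())
            for c in counts.values():
                assert c / total == pytest.approx(1 / 3, abs=0.02)

    def test_negative_distance_is_outer(self):
        mask, _ = make_sphere_mask(1.0)
        part = nf.equal_volume_shells(mask)
        assert part.assign(-0.1) == "outer"
        assert part.assign(0.9) == "inner"

    def test_tiny_mask_raises(self):
        mask = nf.NucleusMask(np.ones((1, 2, 2), bool), SPACING)
        with pytest.raises(ValueError, match="shells"):
            nf.equal_volume_shells(mask)


class TestEllipsoidFallback:
    def test_fixed_point_on_ellipsoid(self):
        mask, _ = make_ellipsoid_mask((1.0, 1.5, 2.0))
        fitted = nf.ellipsoid_fallback(mask)
        overlap = (mask.mask & fitted.mask).sum() / (mask.mask | fitted.mask).sum()
        assert overlap > 0.93
        assert fitted.provenance == "ellipsoid-fallback"

    def test_volume_matched(self):
        rng = np.random.default_rng(2)
        mask = random_blob_mask(rng, max_shape=30)
        fitted = nf.ellipsoid_fallback(mask)
        assert fitted.volume_um3 == pytest.approx(mask.volume_um3, rel=0.05)

    def test_bay_spot_becomes_nonnegative(self):
        # sphere with a wedge bay removed; a spot inside the bay is outside
        # the raw mask but inside the fitted ellipsoid
        mask, centre = make_sphere_mask(1.0, pad=6)
        m = mask.mask.copy()
        half = np.array(m.shape) // 2
        m[half[0] - 1: half[0] + 2, half[1] - 1: half[1] + 2, half[2]:] = False
        bay_mask = nf.NucleusMask(m, SPACING)
        spot = centre + np.array([0.0, 0.0, 0.5])
        raw_d = nf.signed_border_distance(spot, bay_mask)
        fb_d = nf.signed_border_distance(spot, nf.ellipsoid_fallback(bay_mask))
        assert raw_d < 0
        assert fb_d >= 0

    def test_planar_mask_rejected(self):
        m = np.zeros((5, 9, 9), bool)
        m[2] = True
        with pytest.raises(ValueError, match="degenerate"):
            nf.ellipsoid_fallback(nf.NucleusMask(m, SPACING))


class TestSpotPairDistance:
    def test_basic(self):
        assert nf.spot_pair_distance([0, 0, 0], [0, 0, 0]) == 0.0
        assert nf.spot_pair_distance([0, 0, 0], [0, 0, 0.3]) == pytest.approx(0.3)


class TestNearFar:
    def test_two_alleles(self):
        df = pd.DataFrame({"cell_id": ["c", "c"], "allele_id": ["a1", "a2"],
                           "distance_um": [2.0, 1.0]})
        out = nf.rank_near_far(df)
        assert list(out["near_far"]) == ["far", "near"]

    def test_single_allele(self):
        df = pd.DataFrame({"cell_id": ["c"], "allele_id": ["a1"],
                           "distance_um": [1.0]})
        assert nf.rank_near_far(df)["near_far"].iloc[0] == "single"

    def test_tie_flagged_broken_by_allele_id(self):
        df = pd.DataFrame({"cell_id": ["c", "c"], "allele_id": ["a2", "a1"],
                           "distance_um": [1.0, 1.0]})
        out = nf.rank_near_far(df)
        assert out["tie"].all()
        assert out.loc[out["allele_id"] == "a1", "near_far"].iloc[0] == "near"

    def test_matches_explicit_sort_many_cells(self):
        rng = np.random.default_rng(3)
        n = 1000
        df = pd.DataFrame({
            "cell_id": np.repeat([f"c{i}" for i in range(n)], 2),
            "allele_id": ["a1", "a2"] * n,
            "distance_um": rng.uniform(0, 4, 2 * n),
        })
        out = nf.assign_near_far(df)
        for _, g in out.groupby("cell_id"):
            srt = g.sort_values("distance_um")
            assert list(srt["near_far"]) == ["near", "far"]

    def test_three_records_rejected(self):
        df = pd.DataFrame({"cell_id": ["c"] * 3, "allele_id": list("abc"),
                           "distance_um": [1, 2, 3]})
        with pytest.raises(ValueError, match="merged"):
            nf.rank_near_far(df)
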