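"""Triple-correlation maps, significance, conditional density, oracles."""

import numpy as np
import pytest

from g4smlm.fields import ROI, LocalizationField
from g4smlm.synthetic import SceneSpec, generate_point_field, generate_triplet_scene
from g4smlm.triple_correlation import (
    TCTriplet,
    TripletFrequencyResult,
    brute_force_triplets,
    compute_tc_map,
    conditional_density,
    find_tc_triplets,
    r3_transform,
    tc_null_maps,
    triplet_frequency,
    z_map,
)


def csr_trio(seed, density=20.0, side=6000.0):
    return tuple(
        generate_point_field(density, side, channel=c + 1, seed=seed * 10 + c)
        for c in range(3)
    )


@pytest.fixture(scope="module")
def planted_tc(planted_scene):
    (f1, f2, f3), truth = planted_scene
    observed = compute_tc_map(f1, f2, f3)
    nulls = tc_null_maps(f1, f2, f3, n_rand=20, seed=70)
    return (f1, f2, f3), observed, nulls


class TestTransform:
    @pytest.mark.parametrize(
        "r1,r2,dtheta_deg,expected",
        [
            (100.0, 100.0, 120.0, 100.0),  # equilateral
            (100.0, 100.0, 0.0, 200.0),    # collinear, same direction
            (100.0, 100.0, 180.0, 0.0),    # collinear, opposite
            (30.0, 40.0, 90.0, 50.0),      # right angle
        ],
    )
    def test_printed_formula(self, r1, r2, dtheta_deg, expected):
        assert r3_transform(r1, r2, np.deg2rad(dtheta_deg)) == pytest.approx(
            expected, abs=1e-9
        )


class TestTCMap:
    def test_csr_fields_near_zero(self):
        """Independent CSR channels give f ~ 0: |z| <= 3 in >= 99% of
        scanned cells (30-null ensemble keeps the sd estimate tight)."""
        from g4smlm.triple_correlation import _scan_mask

        f1, f2, f3 = csr_trio(5)
        observed = compute_tc_map(f1, f2, f3)
        nulls = tc_null_maps(f1, f2, f3, n_rand=30, seed=50)
        z = z_map(observed, nulls)
        valid = np.isfinite(observed.f3) & _scan_mask(z.shape, True)
        frac_within = np.mean(np.abs(z[valid]) <= 3.0)
        assert frac_within >= 0.99

    def test_planted_peak_within_one_bin(self, planted_tc):
        _, observed, nulls = planted_tc
        triplets = find_tc_triplets(observed, nulls)
        assert triplets, "planted scene produced no significant triplet"
        top = triplets[0]
        for r in (top.r1_nm, top.r2_nm, top.r3_nm):
            assert abs(r - 100.0) <= observed.bin_width_nm

    def test_species_exchange_symmetry(self):
        f1, f2, f3 = csr_trio(6, density=30.0)
        m23 = compute_tc_map(f1, f2, f3)
        m32 = compute_tc_map(f1, f3, f2)
        a, b = m23.f3, np.transpose(m32.f3, (1, 0, 2))
        mask = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(a[mask], b[mask], rtol=1e-8, atol=1e-12)

    def test_empty_channel_rejected(self):
        f1, f2, _ = csr_trio(7)
        empty = LocalizationField(np.empty((0, 2)), ROI.square(6000.0), channel=3)
        with pytest.raises(ValueError, match="fewer"):
            compute_tc_map(f1, f2, empty)

    def test_rmax_exceeding_roi_rejected(self):
        f1, f2, f3 = csr_trio(8)
        with pytest.raises(ValueError, match="half"):
            compute_tc_map(f1, f2, f3, r_max_nm=3000.0)

    def test_null_seed_contract(self):
        f1, f2, f3 = csr_trio(9)
        n1 = tc_null_maps(f1, f2, f3, n_rand=3, seed=1)
        n2 = tc_null_maps(f1, f2, f3, n_rand=3, seed=1)
        n3 = tc_null_maps(f1, f2, f3, n_rand=3, seed=2)
        np.testing.assert_array_equal(n1[0].f3, n2[0].f3)
        assert not np.array_equal(n1[0].f3, n3[0].f3, equal_nan=True)

    def test_grid_mismatch_rejected(self):
        f1, f2, f3 = csr_trio(10)
        observed = compute_tc_map(f1, f2, f3, bin_width_nm=20.0)
        nulls = tc_null_maps(f1, f2, f3, n_rand=2, seed=0, bin_width_nm=30.0)
        with pytest.raises(ValueError, match="grid"):
            find_tc_triplets(observed, nulls)


class TestConditionalDensity:
    def test_independent_probe_near_zero(self):
        """With CSR channel 3 the fluctuation product has no structure, so
        C3 at a channel-1/2-supported geometry stays near zero."""
        spec = SceneSpec(
            n_triplets=60, detection_efficiency=(0.9, 0.9, 0.0),
            background_density=(10.0, 10.0, 30.0), seed=60,
        )
        (f1, f2, f3), _ = generate_triplet_scene(spec)
        m = compute_tc_map(f1, f2, f3)
        # pick the cell at the planted channel-1/2 spacing (100 nm)
        i = j = int(100.0 / m.bin_width_nm)
        k = int(100.0 / m.bin_width_nm)
        trip = TCTriplet(
            r1_nm=m.r_centers_nm[i], r2_nm=m.r_centers_nm[j],
            r3_nm=m.r3_centers_nm[k], f=0.0, z=0.0, index=(i, j, k),
        )
        c3 = conditional_density(f1, f2, f3, trip, tc_map=m)
        # planted-probe scenes at this geometry give C3 of hundreds per µm²
        assert abs(c3) < 100.0

    def test_probe_occupancy_ratio_recovered(self):
        """Doubling the channel-3 molecules per site doubles C3."""
        c3s = {}
        for occ in (5.0, 10.0):
            vals = []
            for rep in range(3):
                spec = SceneSpec(
                    n_triplets=60, molecules_per_site=(8.0, 8.0, occ),
                    background_density=(10.0, 10.0, 10.0), seed=61 + rep,
                )
                (f1, f2, f3), _ = generate_triplet_scene(spec)
                m = compute_tc_map(f1, f2, f3)
                nulls = tc_null_maps(f1, f2, f3, n_rand=10, seed=62 + rep)
                trips = find_tc_triplets(m, nulls)
                assert trips
                vals.append(conditional_density(f1, f2, f3, trips[0], tc_map=m))
            c3s[occ] = np.mean(vals)
        assert c3s[10.0] / c3s[5.0] == pytest.approx(2.0, rel=0.25)

    def test_probe_background_invariance(self):
        """C3 is a fluctuation statistic: uniform channel-3 background
        shifts rho3 but not the conditional density at the pattern."""
        vals = {}
        for bg in (10.0, 20.0):
            got = []
            for rep in range(3):
                spec = SceneSpec(
                    n_triplets=60, background_density=(10.0, 10.0, bg),
                    seed=65 + rep,
                )
                (f1, f2, f3), _ = generate_triplet_scene(spec)
                m = compute_tc_map(f1, f2, f3)
                nulls = tc_null_maps(f1, f2, f3, n_rand=10, seed=66 + rep)
                trips = find_tc_triplets(m, nulls)
                assert trips
                got.append(conditional_density(f1, f2, f3, trips[0], tc_map=m))
            vals[bg] = np.mean(got)
        assert vals[20.0] == pytest.approx(vals[10.0], rel=0.35)


class TestBruteForce:
    def test_exact_triplet_counted_once(self):
        roi = ROI.square(2000.0)
        p1 = LocalizationField(np.array([[0.0, 0.0]]), roi, channel=1)
        p2 = LocalizationField(np.array([[100.0, 0.0]]), roi, channel=2)
        p3 = LocalizationField(np.array([[50.0, 86.602540378]]), roi, channel=3)
        assert brute_force_triplets(p1, p2, p3, (100.0, 100.0, 100.0), 1.0) == 1

    def test_wrong_geometry_not_counted(self):
        roi = ROI.square(2000.0)
        p1 = LocalizationField(np.array([[0.0, 0.0]]), roi, channel=1)
        p2 = LocalizationField(np.array([[100.0, 0.0]]), roi, channel=2)
        p3 = LocalizationField(np.array([[50.0, 86.602540378]]), roi, channel=3)
        assert brute_force_triplets(p1, p2, p3, (200.0, 200.0, 200.0), 5.0) == 0

    def test_empty_channel_zero(self):
        roi = ROI.square(2000.0)
        p1 = LocalizationField(np.array([[0.0, 0.0]]), roi, channel=1)
        empty = LocalizationField(np.empty((0, 2)), roi, channel=2)
        assert brute_force_triplets(p1, empty, p1, (100.0, 100.0, 100.0), 5.0) == 0

    def test_tolerance_required_positive(self):
        roi = ROI.square(2000.0)
        p = LocalizationField(np.array([[0.0, 0.0]]), roi)
        with pytest.raises(ValueError):
            brute_force_triplets(p, p, p, (100.0, 100.0, 100.0), 0.0)


class TestFrequency:
    def test_definition(self):
        roi = ROI.square(2000.0)
        p1 = LocalizationField(np.array([[0.0, 0.0]]), roi, channel=1)
        p2 = LocalizationField(np.array([[100.0, 0.0]]), roi, channel=2)
        p3 = LocalizationField(np.array([[50.0, 86.602540378]]), roi, channel=3)
        trip = TCTriplet(100.0, 100.0, 100.0, f=1.0, z=5.0, index=(0, 0, 0))
        res = triplet_frequency((p1, p2, p3), [trip], reference_pattern_count=20,
                                tolerance_nm=1.0)
        assert res == TripletFrequencyResult(0.05, 1, 20)

    def test_no_significant_triplet_zero(self):
        roi = ROI.square(2000.0)
        p = LocalizationField(np.array([[0.0, 0.0]]), roi)
        res = triplet_frequency((p, p, p), [], reference_pattern_count=100)
        assert res.frequency == 0.0

    def test_zero_reference_rejected(self):
        roi = ROI.square(2000.0)
        p = LocalizationField(np.array([[0.0, 0.0]]), roi)
        with pytest.raises(ValueError):
            triplet_frequency((p, p, p), [], reference_pattern_count=0)
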