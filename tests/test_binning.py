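import numpy as np
import pytest

from gsphere import (
    GSphere, bin_series, build_geodesic, difference, facet_table,
    gsphere_from_json, gsphere_to_json, lifestyle_curve, normalize, summation,
)
from gsphere.binning import GLOBAL, PER_FACET, RAW
from gsphere.kinematics import UnitPostureSeries
from gsphere.synth import gravity_vector
from conftest import INTERIOR_POSTURE, random_unit_vectors


def posture_from_units(u):
    u = np.asarray(u, float)
    return UnitPostureSeries(ux=u[:, 0], uy=u[:, 1], uz=u[:, 2],
                             length_g=np.ones(len(u)),
                             excluded=np.zeros(len(u), bool))


def random_gsphere(sphere, rng, n=5000, n_bins=10):
    u = random_unit_vectors(rng, n)
    return bin_series(posture_from_units(u), rng.uniform(0, 4, n), sphere,
                      n_bins=n_bins, bin_range=(0.0, 4.0))


@pytest.fixture
def identical_posture(sphere2):
    u = np.tile(gravity_vector(**INTERIOR_POSTURE), (100, 1))
    return posture_from_units(u)


class TestBinSeries:
    def test_identical_samples_fill_one_facet(self, sphere2, identical_posture):
        g = bin_series(identical_posture, np.zeros(100), sphere2)
        assert (g.counts > 0).sum() == 1
        assert g.counts.max() == 100

    def test_counts_conserve_samples(self, sphere2, rng):
        g = random_gsphere(sphere2, rng, n=3000)
        assert g.counts.sum() == 3000
        assert g.hist.sum() == 3000

    def test_excluded_samples_skipped(self, sphere2):
        u = np.tile(gravity_vector(**INTERIOR_POSTURE), (10, 1))
        p = posture_from_units(u)
        p.excluded[:4] = True
        p.ux[:4] = np.nan
        g = bin_series(p, np.zeros(10), sphere2)
        assert g.counts.sum() == 6 and g.n_samples == 6

    def test_attribute_clamping_to_end_bins(self, sphere2, identical_posture):
        vals = np.full(100, -1.0)
        g = bin_series(identical_posture, vals, sphere2, n_bins=5, bin_range=(0, 1))
        fid = int(np.argmax(g.counts))
        assert g.hist[fid, 0] == 100
        vals = np.full(100, 99.0)
        g = bin_series(identical_posture, vals, sphere2, n_bins=5, bin_range=(0, 1))
        assert g.hist[fid, -1] == 100

    def test_half_open_bins(self, sphere2, identical_posture):
        vals = np.full(100, 0.2)  # exactly on the edge between bins 0 and 1
        g = bin_series(identical_posture, vals, sphere2, n_bins=5, bin_range=(0, 1))
        fid = int(np.argmax(g.counts))
        assert g.hist[fid, 1] == 100

    def test_channel_means_recover_posture(self, sphere2, identical_posture):
        g = bin_series(identical_posture, np.full(100, 0.3), sphere2)
        fid = int(np.argmax(g.counts))
        expect = gravity_vector(**INTERIOR_POSTURE)
        np.testing.assert_allclose(
            [g.channel_means["ux"][fid], g.channel_means["uy"][fid],
             g.channel_means["uz"][fid]], expect, atol=1e-12)
        assert g.channel_means["VeDBA"][fid] == pytest.approx(0.3)

    def test_bad_inputs(self, sphere2, identical_posture):
        with pytest.raises(ValueError):
            bin_series(identical_posture, np.zeros(7), sphere2)
        with pytest.raises(ValueError):
            bin_series(identical_posture, np.zeros(100), sphere2, n_bins=0)
        with pytest.raises(ValueError):
            bin_series(identical_posture, np.zeros(100), sphere2, bin_range=(2, 2))


class TestNormalize:
    def test_global_percentages(self, sphere2, rng):
        g = normalize(random_gsphere(sphere2, rng), GLOBAL)
        assert g.counts.sum() == pytest.approx(100.0, abs=1e-9)
        assert g.hist.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_facet_example_75_25(self, sphere2):
        a = np.tile(gravity_vector(pitch=-16, roll=18), (75, 1))
        b = np.tile(gravity_vector(pitch=44, roll=18), (25, 1))
        g = normalize(bin_series(posture_from_units(np.vstack([a, b])),
                                 np.zeros(100), sphere2), GLOBAL)
        assert sorted(g.counts[g.counts > 0]) == [25.0, 75.0]

    def test_per_facet_histograms_total_100(self, sphere2, rng):
        g = normalize(random_gsphere(sphere2, rng), PER_FACET)
        pop = g.counts > 0
        np.testing.assert_allclose(g.hist[pop].sum(axis=1), 100.0, atol=1e-9)
        assert np.all(g.hist[~pop] == 0)

    def test_per_facet_example_224(self, sphere2, identical_posture):
        vals = np.array([0.1] * 25 + [0.3] * 25 + [0.5] * 50)
        g = bin_series(identical_posture, vals, sphere2, n_bins=3, bin_range=(0, 0.6))
        g = normalize(g, PER_FACET)
        fid = int(np.argmax(g.counts))
        np.testing.assert_allclose(g.hist[fid], [25, 25, 50])

    def test_renormalizing_with_different_mode_rejected(self, sphere2, rng):
        g = normalize(random_gsphere(sphere2, rng), GLOBAL)
        with pytest.raises(ValueError, match="already normalized"):
            normalize(g, PER_FACET)


class TestSphereAlgebra:
    def test_self_difference_is_zero(self, sphere2, rng):
        g = normalize(random_gsphere(sphere2, rng), GLOBAL)
        d = difference(g, g)
        assert np.all(d.hist == 0) and np.all(d.counts == 0)
        assert d.provenance == "operation"

    def test_difference_matches_loop_oracle(self, sphere2, rng):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        gb = normalize(random_gsphere(sphere2, rng, n=3000), GLOBAL)
        d = difference(ga, gb)
        for f in range(0, sphere2.n_facets, 13):
            for b in range(ga.n_bins):
                assert d.hist[f, b] == abs(ga.hist[f, b] - gb.hist[f, b])
                assert d.signed_hist[f, b] == ga.hist[f, b] - gb.hist[f, b]

    def test_difference_symmetric_in_magnitude(self, sphere2, rng):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        gb = normalize(random_gsphere(sphere2, rng, n=2000), GLOBAL)
        np.testing.assert_array_equal(difference(ga, gb).hist, difference(gb, ga).hist)

    def test_summation_commutative_and_mass_additive(self, sphere2, rng):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        gb = normalize(random_gsphere(sphere2, rng, n=2000), GLOBAL)
        s1, s2 = summation(ga, gb), summation(gb, ga)
        np.testing.assert_array_equal(s1.hist, s2.hist)
        assert s1.hist.sum() == pytest.approx(200.0, abs=1e-9)

    def test_zero_sphere_is_summation_identity(self, sphere2, rng):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        zero = difference(ga, ga)
        np.testing.assert_allclose(summation(ga, zero).hist, ga.hist, atol=1e-12)

    def test_mismatched_inputs_rejected(self, sphere2, sphere3, rng):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        gb = normalize(random_gsphere(sphere3, rng), GLOBAL)
        with pytest.raises(ValueError, match="incompatible"):
            difference(ga, gb)
        gc = normalize(random_gsphere(sphere2, rng, n_bins=5), GLOBAL)
        with pytest.raises(ValueError, match="incompatible"):
            difference(ga, gc)

    def test_raw_inputs_rejected(self, sphere2, rng):
        ga = random_gsphere(sphere2, rng)
        with pytest.raises(ValueError, match="normalize"):
            difference(ga, ga)


class TestLifestyle:
    def test_single_facet_curve(self, sphere3, identical_posture):
        g = bin_series(identical_posture, np.full(100, 0.5), sphere3)
        c = lifestyle_curve(g)
        np.testing.assert_allclose(c.coverage_percent, [0, 100 / 1280])
        np.testing.assert_allclose(c.time_percent, [0, 100])
        np.testing.assert_allclose(c.dba_percent, [0, 100])

    def test_two_state_hand_computed_shares(self, sphere2):
        # 90% of time at a low-DBA posture, 10% at a high-DBA posture
        a = np.tile(gravity_vector(pitch=-16, roll=18), (900, 1))
        b = np.tile(gravity_vector(pitch=44, roll=18), (100, 1))
        dba = np.concatenate([np.full(900, 0.1), np.full(100, 0.9)])
        g = bin_series(posture_from_units(np.vstack([a, b])), dba, sphere2)
        c = lifestyle_curve(g)
        # rank by count: rest facet first -> time jumps 90 then 10
        np.testing.assert_allclose(c.time_percent, [0, 90, 100])
        # DBA mass: 900*0.1 = 90 vs 100*0.9 = 90 -> 50% each
        np.testing.assert_allclose(c.dba_percent, [0, 50, 100])

    def test_uniform_occupancy_is_linear(self, sphere2, rng):
        # equal mass in k facets, equal mean DBA -> both curves linear
        k = 8
        fids = rng.choice(sphere2.n_facets, k, replace=False)
        u = sphere2.centers[fids]
        pts = np.repeat(u, 50, axis=0)
        g = bin_series(posture_from_units(pts), np.full(len(pts), 0.5), sphere2)
        c = lifestyle_curve(g)
        np.testing.assert_allclose(np.diff(c.time_percent), 100 / k, atol=1e-9)
        np.testing.assert_allclose(np.diff(c.dba_percent), 100 / k, atol=1e-9)

    def test_monotone_and_bounded(self, sphere2, rng):
        g = random_gsphere(sphere2, rng)
        c = lifestyle_curve(g)
        for y in (c.time_percent, c.dba_percent):
            assert np.all(np.diff(y) >= -1e-12)
            assert y[0] == 0 and y[-1] == pytest.approx(100.0)
        occupied = int((g.counts > 0).sum())
        assert c.coverage_percent[-1] == pytest.approx(100.0 * occupied / sphere2.n_facets)

    def test_empty_sphere_rejected(self, sphere2, rng):
        g = normalize(random_gsphere(sphere2, rng), GLOBAL)
        zero = difference(g, g)
        with pytest.raises(ValueError, match="empty"):
            lifestyle_curve(zero)


class TestSerialization:
    def test_json_round_trip(self, sphere2, rng, tmp_path):
        g = normalize(random_gsphere(sphere2, rng), GLOBAL)
        g2 = gsphere_from_json(gsphere_to_json(g, tmp_path / "g.json"), sphere2)
        np.testing.assert_array_equal(g2.counts, g.counts)
        np.testing.assert_array_equal(g2.hist, g.hist)
        assert g2.normalization == GLOBAL and g2.n_samples == g.n_samples

    def test_signed_layers_round_trip(self, sphere2, rng, tmp_path):
        ga = normalize(random_gsphere(sphere2, rng), GLOBAL)
        gb = normalize(random_gsphere(sphere2, rng, n=2000), GLOBAL)
        d = difference(ga, gb)
        d2 = gsphere_from_json(gsphere_to_json(d, tmp_path / "d.json"), sphere2)
        np.testing.assert_allclose(d2.signed_hist, d.signed_hist, atol=1e-15)

    def test_facet_table_shape(self, sphere2, rng):
        g = random_gsphere(sphere2, rng, n_bins=6)
        tab = facet_table(g)
        assert len(tab) == int((g.counts > 0).sum())
        assert {"facet", "count", "mean_ux", "bin_0", "bin_5"} <= set(tab.columns)
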