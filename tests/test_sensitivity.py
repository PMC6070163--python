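"""CDPS statistic: pairwise deltas, grayscale normalization, regression."""

import numpy as np
import pytest

import cvdcmap as cm
from cvdcmap import colorspace as cs
from cvdcmap import sensitivity as sn


def closed_form_ols(x, y):
    """Independent simple-regression oracle (slope, r^2)."""
    x, y = np.asarray(x), np.asarray(y)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    yhat = y.mean() + slope * (x - x.mean())
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, 1 - ss_res / ss_tot


class TestDataDeltas:
    @pytest.mark.parametrize(
        "transect, expected",
        [
            ([0.0, 1.0], [1.0]),
            ([0.0, 0.5, 1.0], [0.5, 1.0, 0.5]),
            ([0.3, 0.3, 0.3], [0.0, 0.0, 0.0]),
        ],
    )
    def test_enumeration(self, transect, expected):
        assert sn.data_deltas(transect) == pytest.approx(expected)

    def test_pair_count(self):
        t = sn.uniform_transect(64)
        assert len(sn.data_deltas(t)) == 64 * 63 // 2


class TestPerceptualDeltas:
    def test_black_white_pair_is_full_ucs_distance(self, gray):
        d = sn.perceptual_deltas([0.0, 1.0], gray)
        expected = cs.delta(
            cs.srgb_to_ucs([0.0, 0.0, 0.0]), cs.srgb_to_ucs([1.0, 1.0, 1.0])
        )
        assert d == pytest.approx([expected])

    def test_degenerate_single_color_map_gives_zeros(self):
        flat = cm.RGBColormap(np.tile([0.4, 0.4, 0.4], (8, 1)))
        d = sn.perceptual_deltas(sn.uniform_transect(16), flat)
        assert np.all(d == 0)

    def test_pair_order_matches_data_deltas(self, rng, gray):
        t = np.sort(rng.random(12))
        dd = sn.data_deltas(t)
        # nearest-index gray lookup makes each perceptual delta a
        # monotone function of the data delta along the same pair order
        pd = sn.perceptual_deltas(t, gray)
        order = np.argsort(dd)
        assert np.all(np.diff(pd[order]) > -1.0)


class TestCDPS:
    def test_gray_on_itself_has_unit_slope(self, gray):
        res = sn.cdps(sn.uniform_transect(64), gray)
        assert res.m == pytest.approx(1.0, abs=1e-12)
        assert res.r2 > 0.999
        assert res.gray_slope > 0
        assert len(res.pairs) == 64 * 63 // 2

    def test_matches_closed_form_regression(self, viridis):
        t = sn.uniform_transect(32)
        res = sn.cdps(t, viridis)
        dd = sn.data_deltas(t)
        pd = sn.perceptual_deltas(t, viridis) / res.gray_slope
        slope, r2 = closed_form_ols(dd, pd)
        assert res.m == pytest.approx(slope, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_slope_scales_with_perceptual_stretch(self):
        # doubling every perceptual delta doubles m and leaves r2 alone
        rng = np.random.default_rng(5)
        dd = rng.random(100)
        pd = 2.5 * dd + rng.normal(0, 0.05, 100)
        m1, r1 = closed_form_ols(dd, pd)
        m2, r2 = closed_form_ols(dd, 2 * pd)
        assert m2 == pytest.approx(2 * m1)
        assert r2 == pytest.approx(r1)

    def test_r2_invariant_under_pair_permutation(self, viridis, rng):
        t = sn.uniform_transect(24)
        dd = sn.data_deltas(t)
        pd = sn.perceptual_deltas(t, viridis)
        perm = rng.permutation(len(dd))
        a = closed_form_ols(dd, pd)
        b = closed_form_ols(dd[perm], pd[perm])
        assert a == pytest.approx(b)

    def test_constant_transect_is_degenerate(self, gray):
        with pytest.raises(sn.DegenerateRegressionError):
            sn.cdps(np.full(8, 0.5), gray)

    def test_jet_less_uniform_than_optimized(self, jet, viridis_report):
        t = sn.uniform_transect(64)
        assert sn.cdps(t, jet).r2 < sn.cdps(t, viridis_report.final).r2


class TestAdjacentDeltaProfile:
    def test_two_color_map_has_zero_imperfection(self):
        two = cm.fixture("two_point_degenerate")
        deltas, imp = sn.adjacent_delta_profile(two)
        assert len(deltas) == 1
        assert imp == 0.0

    def test_jet_far_less_uniform_than_optimized_map(self, jet, viridis_report):
        _, imp_jet = sn.adjacent_delta_profile(jet)
        _, imp_opt = sn.adjacent_delta_profile(viridis_report.final)
        assert imp_jet > 4 * imp_opt

    def test_cvd_simulation_changes_profile(self, viridis, deuter100):
        _, imp_normal = sn.adjacent_delta_profile(viridis)
        _, imp_cvd = sn.adjacent_delta_profile(viridis, deuter100)
        assert imp_normal != imp_cvd
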