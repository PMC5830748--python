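from __future__ import annotations

import numpy as np
import pytest

from isoniche import niche

from _oracles import hull_area_bruteforce


def _rotate(xy: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return xy @ np.array([[c, -s], [s, c]]).T


class TestLaymanMetrics:
    def test_unit_square_hand_geometry(self, unit_square):
        m = niche.layman_metrics(unit_square)
        assert m.nr == 1.0 and m.cr == 1.0
        assert m.ta == pytest.approx(1.0)
        assert m.cd == pytest.approx(np.sqrt(0.5))
        assert m.mnnd == pytest.approx(1.0)
        assert m.sdnnd == pytest.approx(0.0)

    def test_collinear_points_flagged_degenerate(self):
        m = niche.layman_metrics(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert m.ta == 0.0 and m.degenerate_hull
        assert m.nr == 2.0 and m.cr == 2.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            niche.layman_metrics([[0.0, 0.0]])

    def test_hull_matches_bruteforce_oracle_small_n(self, rng):
        for _ in range(50):
            n = rng.integers(3, 13)
            xy = rng.normal(size=(n, 2))
            m = niche.layman_metrics(xy)
            assert m.ta == pytest.approx(hull_area_bruteforce(xy), abs=1e-9)

    def test_translation_invariance(self, rng):
        xy = rng.normal(size=(25, 2))
        shifted = xy + np.array([5.0, -3.0])
        a, b = niche.niche_metrics(xy), niche.niche_metrics(shifted)
        for attr in ("nr", "cr", "ta", "cd", "mnnd", "sdnnd", "sea", "seac"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-9)

    def test_rotation_invariance_of_geometric_metrics(self, rng):
        xy = rng.normal(size=(25, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        rot = _rotate(xy, 0.7)
        a, b = niche.niche_metrics(xy), niche.niche_metrics(rot)
        for attr in ("ta", "cd", "mnnd", "sdnnd", "sea"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-9)
        # axis-aligned ranges are correctly *not* invariant
        assert not np.isclose(a.nr, b.nr)


class TestStandardEllipse:
    def test_det_identity_and_correction(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            xy = rng.normal(size=(n, 2)) @ rng.normal(size=(2, 2))
            sea, seac = niche.standard_ellipse(xy)
            s = np.cov(xy, rowvar=False, ddof=1)
            assert sea == pytest.approx(np.pi * np.sqrt(np.linalg.det(s)), abs=1e-12)
            assert seac == pytest.approx(sea * (n - 1) / (n - 2), abs=1e-12)

    def test_whitened_sample_gives_pi(self, rng):
        xy = rng.normal(size=(60, 2))
        xy = xy - xy.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(xy, rowvar=False, ddof=1))
        white = xy @ np.linalg.inv(chol).T
        sea, _ = niche.standard_ellipse(white)
        assert sea == pytest.approx(np.pi, abs=1e-9)

    def test_three_points_double_correction(self, rng):
        xy = rng.normal(size=(3, 2))
        sea, seac = niche.standard_ellipse(xy)
        assert seac == pytest.approx(2.0 * sea)

    def test_area_scales_quadratically(self, rng):
        xy = rng.normal(size=(20, 2))
        sea1, _ = niche.standard_ellipse(xy)
        sea2, _ = niche.standard_ellipse(2.0 * xy)
        assert sea2 == pytest.approx(4.0 * sea1)

    def test_degenerate_covariance_reports_zero(self):
        xy = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        sea, seac = niche.standard_ellipse(xy)
        assert sea == 0.0 and seac == 0.0


class TestBootstrap:
    def test_resample_size_is_minimum_group_n(self, rng):
        groups = {
            lab: rng.normal(size=(n, 2))
            for lab, n in zip("abcd", (15, 23, 52, 21))
        }
        out = niche.bootstrap_metrics(groups, reps=50, rng=1)
        assert out["c"]["TA"].resample_n == 15
        assert out["a"]["NR"].reps == 50

    def test_identical_points_give_all_zero_draws(self):
        groups = {"g": np.tile([[1.0, 2.0]], (10, 1))}
        out = niche.bootstrap_metrics(groups, reps=30, rng=0)
        for summary in out["g"].values():
            assert np.all(summary.draws == 0.0)

    def test_same_seed_bit_identical(self, rng):
        groups = {"a": rng.normal(size=(12, 2)), "b": rng.normal(size=(18, 2))}
        r1 = niche.bootstrap_metrics(groups, reps=40, rng=7)
        r2 = niche.bootstrap_metrics(groups, reps=40, rng=7)
        for lab in groups:
            for met in niche.LAYMAN_NAMES:
                np.testing.assert_array_equal(r1[lab][met].draws, r2[lab][met].draws)

    def test_interval_nesting(self, rng):
        groups = {"a": rng.normal(size=(20, 2))}
        s = niche.bootstrap_metrics(groups, reps=200, rng=3)["a"]["CD"]
        (l50, h50), (l75, h75), (l95, h95) = (
            s.intervals[50], s.intervals[75], s.intervals[95]
        )
        assert l95 <= l75 <= l50 <= h50 <= h75 <= h95

    def test_bad_reps_rejected(self, rng):
        with pytest.raises(ValueError):
            niche.bootstrap_metrics({"a": rng.normal(size=(5, 2))}, reps=0)


class TestBayesianSea:
    def test_seeded_determinism(self, rng):
        xy = rng.normal(size=(30, 2))
        a = niche.bayesian_sea(xy, n_draws=500, rng=11)
        b = niche.bayesian_sea(xy, n_draws=500, rng=11)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_scale_equivariance_with_scaled_prior(self, rng):
        xy = rng.normal(size=(25, 2))
        base = niche.bayesian_sea(xy, n_draws=400, rng=5)
        prior4 = niche.NiwPrior(scale_eps=4e-3)
        scaled = niche.bayesian_sea(2.0 * xy, n_draws=400, prior=prior4, rng=5)
        np.testing.assert_allclose(scaled.draws, 4.0 * base.draws, rtol=1e-10)

    def test_draws_positive_and_intervals_nested(self, rng):
        p = niche.bayesian_sea(rng.normal(size=(15, 2)), n_draws=1000, rng=2)
        assert np.all(p.draws > 0)
        assert p.intervals[50][0] >= p.intervals[95][0]
        assert p.intervals[50][1] <= p.intervals[95][1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            niche.bayesian_sea([[0, 0], [1, 1]])

    def test_hdr_interval_no_wider_than_percentile(self, rng):
        xy = rng.normal(size=(20, 2))
        pct = niche.bayesian_sea(xy, n_draws=2000, rng=9)
        hdr = niche.bayesian_sea(xy, n_draws=2000, rng=9, hdr=True)
        for level in niche.INTERVAL_LEVELS:
            w_p = pct.intervals[level][1] - pct.intervals[level][0]
            w_h = hdr.intervals[level][1] - hdr.intervals[level][0]
            assert w_h <= w_p + 1e-12


class TestCompareSea:
    def _posterior(self, draws, label="g"):
        draws = np.asarray(draws, float)
        return niche.PosteriorSeaDraws(
            label=label, draws=draws, mean=float(draws.mean()), intervals={}
        )

    def test_identical_draws_give_half(self):
        p = self._posterior([1.0, 2.0, 3.0])
        assert niche.compare_sea(p, p).p_exceed == 0.5

    def test_disjoint_supports(self):
        hi = self._posterior([10.0, 11.0], "hi")
        lo = self._posterior([1.0, 2.0, 3.0], "lo")
        c = niche.compare_sea(hi, lo)
        assert c.p_exceed == 1.0 and c.significant

    def test_exceedance_probabilities_sum_to_one(self, rng):
        a = self._posterior(rng.gamma(2.0, size=101), "a")
        b = self._posterior(rng.gamma(2.0, size=57), "b")
        assert niche.compare_sea(a, b).p_exceed + niche.compare_sea(b, a).p_exceed == (
            pytest.approx(1.0)
        )

    def test_pairwise_count(self, rng):
        ps = [self._posterior(rng.gamma(2.0, size=50), lab) for lab in "abc"]
        assert len(niche.pairwise_sea(ps)) == 3
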