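"""Null-model calibration: size regressions, Z-scores, threshold scan."""

import numpy as np
import pytest

from wes.evaluate import f1_threshold_scan
from wes.null import (NullModel, choose_z_threshold, fit_null, protein_seed,
                      sample_background_indices, sample_random_raw_scores,
                      z_score)


class TestSampling:
    def test_draw_size_and_range(self):
        idx = sample_background_indices(200, 50, seed=3)
        assert idx.size == 50
        assert np.unique(idx).size == 50
        assert idx.min() >= 0 and idx.max() < 200

    def test_seed_reproducibility(self):
        a = sample_background_indices(500, 50, seed=9)
        b = sample_background_indices(500, 50, seed=9)
        assert (a == b).all()

    def test_background_too_small_fatal(self):
        with pytest.raises(ValueError):
            sample_background_indices(30, 50, seed=0)

    def test_protein_seed_stable_and_order_free(self):
        assert protein_seed(7, "P001") == protein_seed(7, "P001")
        assert protein_seed(7, "P001") != protein_seed(7, "P002")
        assert 0 <= protein_seed(123456, "X") < 2**31

    def test_raw_scores_from_sim_matrix(self):
        sims = np.array([[0.9, 0.5], [0.2, 0.1]])
        raw = sample_random_raw_scores(sims, s_cut=0.4)
        assert raw == pytest.approx([1.4, 0.0])


class TestFitNull:
    def test_coefficient_recovery_known_line(self):
        # planted mu = 0.2*size + 1, sigma = 0.05*size + 0.3 plus noise
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(5, 60, 30).astype(float)
            mu = 0.2 * sizes + 1 + rng.normal(0, 0.05, sizes.size)
            sd = 0.05 * sizes + 0.3 + rng.normal(0, 0.02, sizes.size)
            nm = fit_null(sizes, mu, sd)
            # 3-standard-error band from the OLS design
            X = np.column_stack([sizes, np.ones_like(sizes)])
            resid = mu - X @ [nm.alpha1, nm.beta1]
            cov = np.linalg.inv(X.T @ X) * (resid @ resid) / (sizes.size - 2)
            se_slope = np.sqrt(cov[0, 0])
            if abs(nm.alpha1 - 0.2) <= 3 * se_slope:
                hits += 1
            assert nm.r2_mu > 0.99
        assert hits >= 4  # 3-SE misses should be rare

    def test_two_point_exact_interpolation(self):
        nm = fit_null([10, 20], [3.0, 5.0], [0.5, 0.9])
        assert nm.r2_mu == pytest.approx(1.0)
        assert nm.predict_mu(10) == pytest.approx(3.0)
        assert nm.predict_mu(20) == pytest.approx(5.0)

    def test_noise_free_r2_one(self):
        sizes = np.array([5.0, 10, 20, 40])
        nm = fit_null(sizes, 0.3 * sizes + 2, 0.1 * sizes + 0.4)
        assert nm.r2_mu == pytest.approx(1.0)
        assert nm.r2_sigma == pytest.approx(1.0)

    def test_singular_design_fatal(self):
        with pytest.raises(ValueError, match="singular"):
            fit_null([10, 10, 10], [1, 2, 3], [0.1, 0.2, 0.3])


class TestZScore:
    def make_null(self):
        return NullModel(channel="binary", alpha1=0.2, beta1=1.0,
                         alpha2=0.05, beta2=0.3)

    def test_raw_at_mean_is_zero(self):
        nm = self.make_null()
        assert z_score(nm.predict_mu(20), nm, 20) == pytest.approx(0.0)

    def test_one_sigma_above_is_one(self):
        nm = self.make_null()
        raw = nm.predict_mu(20) + nm.predict_sigma(20)
        assert z_score(raw, nm, 20) == pytest.approx(1.0)

    def test_sigma_floor_applies(self):
        nm = NullModel(channel="binary", alpha1=0.0, beta1=0.0,
                       alpha2=-1.0, beta2=0.0, sigma_floor=1e-6)
        with pytest.warns(UserWarning, match="floored"):
            z = z_score(1.0, nm, 5)
        assert z == pytest.approx(1.0 / 1e-6)

    def test_strictly_increasing_in_raw(self):
        nm = self.make_null()
        zs = [z_score(r, nm, 15) for r in np.linspace(0, 10, 25)]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_null_sample_standardised_when_line_exact(self, rng):
        # null raw scores generated from the fitted line's own moments
        nm = self.make_null()
        size = 30
        raws = rng.normal(nm.predict_mu(size), nm.predict_sigma(size), 50)
        z = nm.z(raws, size)
        assert abs(z.mean()) < 3 / np.sqrt(50)
        assert abs(z.std(ddof=1) - 1) < 0.35


class TestThresholdScan:
    def test_perfect_separation_f1_one(self):
        t, f1 = choose_z_threshold([5.0, 6.0, -1.0, -2.0], [1, 1, 0, 0])
        assert f1 == 1.0
        assert -1.0 <= t < 5.0

    def test_boundary_threshold_under_tie_rule(self):
        scores = np.array([2.5, 3.0, 1.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        t, f1 = choose_z_threshold(scores, labels)
        assert f1 == 1.0
        assert t == 2.0  # largest negative score, the smallest perfect cut

    def test_single_pair_each_class(self):
        t, f1 = choose_z_threshold([4.0, 0.0], [1, 0])
        assert f1 == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            s = rng.normal(size=30)
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            t, f1 = f1_threshold_scan(s, y)
            best = -1.0
            best_t = None
            for cand in sorted(np.unique(s)):
                pred = s > cand
                tp = int((pred & (y == 1)).sum())
                fp = int((pred & (y == 0)).sum())
                fn = int((~pred & (y == 1)).sum())
                f = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
                if f > best:
                    best, best_t = f, cand
            assert f1 == pytest.approx(best)
            assert t == pytest.approx(best_t)
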