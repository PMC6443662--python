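import numpy as np
import pytest

from ubfret import (
    SimConfig,
    StateModel,
    em_fit,
    gen_burst_efficiencies,
    histogram_r2,
    replicate_summary,
    select_k,
)
from ubfret.mixture import MixtureFit, mixture_pdf


def gaussian_sample(center, width, n, seed):
    return np.clip(np.random.default_rng(seed).normal(center, width, n), 0, 1)


def grid_loglik(x, widths, n_coarse=51, n_fine=61, n_weight=41):
    """Enumeration oracle for a two-component mixture with known widths:
    coarse global grid over (c1, c2, w1), then a fine local grid around the
    coarse optimum.  Independent of the EM code path."""

    def lnl(c1, c2, w1):
        # c1/c2/w1 broadcast over a trailing sample axis
        p = w1[..., None] * np.exp(-0.5 * ((x - c1[..., None]) / widths[0]) ** 2) / (
            widths[0] * np.sqrt(2 * np.pi)
        ) + (1 - w1[..., None]) * np.exp(-0.5 * ((x - c2[..., None]) / widths[1]) ** 2) / (
            widths[1] * np.sqrt(2 * np.pi)
        )
        return np.log(np.maximum(p, 1e-300)).sum(axis=-1)

    def best_on(c1s, c2s, w1s):
        C1, C2, W1 = np.meshgrid(c1s, c2s, w1s, indexing="ij")
        scores = lnl(C1, C2, W1)
        i = np.unravel_index(np.argmax(scores), scores.shape)
        return scores[i], C1[i], C2[i], W1[i]

    c_axis = np.linspace(0, 1, n_coarse)
    w_axis = np.linspace(0.02, 0.98, n_weight)
    _, c1, c2, w1 = best_on(c_axis, c_axis, w_axis)
    fine = lambda c: np.linspace(max(c - 0.03, 0), min(c + 0.03, 1), n_fine)
    wfine = np.linspace(max(w1 - 0.05, 0.01), min(w1 + 0.05, 0.99), n_fine)
    score, *_ = best_on(fine(c1), fine(c2), wfine)
    return score


class TestEmFit:
    def test_single_component_recovers_center(self):
        x = gaussian_sample(0.5, 0.05, 5000, seed=2)
        fit = em_fit(x, 1, seed=0)
        assert fit.centers[0] == pytest.approx(0.5, abs=0.003)
        assert fit.weights[0] == 1.0

    def test_single_component_matches_closed_form_mle(self):
        """k=1 has a closed-form MLE; EM must land on it."""
        x = gaussian_sample(0.4, 0.08, 2000, seed=3)
        fit = em_fit(x, 1, seed=0)
        mu, sigma = x.mean(), x.std()
        lnl_closed = -0.5 * len(x) * (np.log(2 * np.pi * sigma**2) + 1)
        assert fit.centers[0] == pytest.approx(mu, abs=1e-6)
        assert fit.widths[0] == pytest.approx(sigma, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(lnl_closed, abs=1e-3)

    def test_symmetric_two_component_weights(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(0.2, 0.05, 2500), rng.normal(0.8, 0.05, 2500)]
        ).clip(0, 1)
        fit = em_fit(x, 2, seed=0)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.03)
        assert fit.centers == pytest.approx([0.8, 0.2], abs=0.01)

    def test_three_state_recovery_triplicate(self, three_state_model):
        """Triplicate-averaged populations recover the generating
        48/39/13% weights within 5 points (replicated-measurement
        protocol)."""
        fits = []
        for rep in range(3):
            cfg = SimConfig(n_bursts=5000, seed=40 + rep, noise_model="gaussian")
            eff = gen_burst_efficiencies(three_state_model, cfg)["efficiency"]
            fits.append(em_fit(eff, 3, seed=rep, restarts=5))
        summary = replicate_summary(fits)
        assert summary.populations_mean == pytest.approx([0.48, 0.39, 0.13], abs=0.05)
        assert summary.centers_mean == pytest.approx([0.74, 0.57, 0.23], abs=0.01)

    def test_loglik_monotone(self, burst_sample):
        fit = em_fit(burst_sample, 3, seed=1)
        assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_matches_grid_search_oracle(self):
        """EM with fixed widths agrees with a dense (c1, c2, w) enumeration
        to within 0.1 nats on a small two-component sample."""
        rng = np.random.default_rng(8)
        widths = np.array([0.07, 0.07])
        x = np.concatenate(
            [rng.normal(0.65, widths[0], 120), rng.normal(0.3, widths[1], 80)]
        ).clip(0, 1)
        fit = em_fit(x, 2, seed=0, fix_widths=widths, tol=1e-10)
        oracle = grid_loglik(x, widths)
        assert abs(fit.log_likelihood - oracle) <= 0.1
        assert fit.log_likelihood >= oracle - 1e-6  # EM can only do better

    def test_matches_sklearn_cross_check(self, burst_sample):
        """Independent EM implementation (scikit-learn) reaches the same
        likelihood per sample."""
        sklearn = pytest.importorskip("sklearn.mixture")
        fit = em_fit(burst_sample, 3, seed=0)
        gm = sklearn.GaussianMixture(
            n_components=3, n_init=5, random_state=0, tol=1e-6, max_iter=500
        ).fit(burst_sample.reshape(-1, 1))
        assert fit.log_likelihood / fit.n_samples == pytest.approx(
            gm.score(burst_sample.reshape(-1, 1)), abs=2e-3
        )

    def test_weight_normalisation_and_sorting(self, burst_sample):
        fit = em_fit(burst_sample, 3, seed=5)
        assert float(np.sum(fit.weights)) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(fit.centers) < 0)

    def test_clipping_recorded(self):
        x = np.concatenate([gaussian_sample(0.5, 0.05, 500, 0), [-0.2, 1.4]])
        fit = em_fit(x, 1, seed=0)
        assert fit.n_clipped == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            em_fit(np.linspace(0, 1, 25), 3)


class TestSelectK:
    def test_single_gaussian_prefers_one(self):
        x = gaussian_sample(0.5, 0.07, 3000, seed=6)
        best_k, fits = select_k(x, range(1, 5), seed=0, restarts=5)
        assert best_k == 1
        assert [f.k for f in fits] == [1, 2, 3, 4]

    def test_three_state_selected(self, burst_sample):
        best_k, _ = select_k(burst_sample, range(1, 6), seed=0)
        assert best_k == 3

    def test_bic_penalises_harder_than_aic(self):
        """At n = 50 (ln n > 2) BIC never selects more components than AIC."""
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(0.45, 0.06, 20), rng.normal(0.55, 0.06, 20), rng.normal(0.65, 0.06, 10)]
        ).clip(0, 1)
        k_bic, _ = select_k(x, range(1, 4), criterion="bic", seed=0, restarts=5)
        k_aic, _ = select_k(x, range(1, 4), criterion="aic", seed=0, restarts=5)
        assert k_bic <= k_aic

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.linspace(0, 1, 100), [])


class TestHistogramR2:
    def test_good_fit_high_r2(self, three_state_model):
        cfg = SimConfig(n_bursts=50_000, seed=12, noise_model="gaussian")
        eff = gen_burst_efficiencies(three_state_model, cfg)["efficiency"]
        fit = em_fit(eff, 3, seed=0, restarts=5)
        assert histogram_r2(fit, eff) >= 0.98
        # binning robustness
        assert histogram_r2(fit, eff, n_bins=5) >= 0.9
        assert histogram_r2(fit, eff, n_bins=50) >= 0.9

    def test_wrong_fit_negative_r2(self):
        x = gaussian_sample(0.9, 0.03, 2000, seed=13)
        bogus = MixtureFit(
            k=1, centers=np.array([0.05]), widths=np.array([0.03]),
            weights=np.array([1.0]), log_likelihood=0.0, bic=0.0, aic=0.0,
            n_samples=2000, converged=True, n_iter=1,
        )
        assert histogram_r2(bogus, x) < 0

    def test_empty_rejected(self):
        fit = MixtureFit(
            k=1, centers=np.array([0.5]), widths=np.array([0.05]),
            weights=np.array([1.0]), log_likelihood=0.0, bic=0.0, aic=0.0,
            n_samples=0, converged=True, n_iter=1,
        )
        with pytest.raises(ValueError):
            histogram_r2(fit, np.array([]))


class TestReplicateSummary:
    @staticmethod
    def _fit(centers, weights):
        centers = np.asarray(centers, dtype=float)
        weights = np.asarray(weights, dtype=float)
        return MixtureFit(
            k=len(centers), centers=centers, widths=np.full(len(centers), 0.07),
            weights=weights, log_likelihood=0.0, bic=0.0, aic=0.0,
            n_samples=100, converged=True, n_iter=1,
        )

    def test_identical_replicates_zero_sd(self):
        fits = [self._fit([0.7, 0.2], [0.6, 0.4])] * 3
        s = replicate_summary(fits)
        assert s.centers_sd == pytest.approx(0.0, abs=1e-12)
        assert s.populations_sd == pytest.approx(0.0, abs=1e-12)
        assert s.n_replicates == 3

    def test_component_order_invariance(self):
        a = self._fit([0.7, 0.2], [0.6, 0.4])
        b = self._fit([0.2, 0.7], [0.4, 0.6])  # same mixture, swapped order
        sa = replicate_summary([a, a])
        sb = replicate_summary([a, b])
        assert sa.centers_mean == pytest.approx(sb.centers_mean)
        assert sa.populations_mean == pytest.approx(sb.populations_mean)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            replicate_summary([self._fit([0.7, 0.2], [0.6, 0.4]), self._fit([0.5], [1.0])])


def test_mixture_pdf_normalises():
    grid = np.linspace(-1, 2, 30_000)
    pdf = mixture_pdf(grid, [0.3, 0.7], [0.05, 0.1], [0.4, 0.6])
    assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-6)
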