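"""Mixture decomposition: noise fit, tail fit, threshold, K-W fit, totals."""

import numpy as np
import pytest

from kwbind import (
    BindingHistogram,
    BindingMixtureModel,
    GDPParams,
    KWParams,
    MixtureConfig,
    TruncationWindow,
    analyze_library,
    back_extrapolate,
    estimate_alpha,
    estimate_threshold,
    fit_kw,
    fit_noise,
    fit_tgdp_tail,
    gdp_pmf,
    kw_p0,
    kw_pmf_zero_truncated,
    subtract_noise,
    totals,
)
from kwbind.mixture import NoiseFit, PipelineError


def hist_from_counts(counts: dict[int, int], M=None) -> BindingHistogram:
    return BindingHistogram(counts, M=M)


class TestFitNoise:
    def test_exact_exponential_recovery(self):
        h = hist_from_counts({1: 8, 2: 4, 3: 2, 4: 1})
        nf = fit_noise(h, MixtureConfig(noise_fit_range=(1, 4)))
        assert nf.params.d == pytest.approx(np.log(2), rel=1e-10)
        assert nf.params.amplitude == pytest.approx(8.0, rel=1e-10)

    def test_poisson_jitter_within_3se(self):
        rng = np.random.default_rng(11)
        d_true, n1 = 1.05, 100_000
        m = np.arange(1, 9)
        expected = n1 * np.exp(-d_true * (m - 1))
        counts = rng.poisson(expected)
        h = hist_from_counts({int(mm): int(c) for mm, c in zip(m, counts)})
        nf = fit_noise(h, MixtureConfig(noise_fit_range=(1, 8)))
        assert abs(nf.params.d - d_true) < 3 * max(nf.se_d, 1e-4)

    def test_needs_three_points(self):
        with pytest.raises(PipelineError):
            fit_noise(hist_from_counts({1: 5, 2: 3}),
                      MixtureConfig(noise_fit_range=(1, 8)))


class TestFitTGDPTail:
    def test_noise_free_recovery(self):
        params = GDPParams(k=2.5, beta=5.0)
        window = TruncationWindow(10, 300)
        pmf = gdp_pmf(params, window)
        counts = np.zeros(300)
        counts[9:300] = 50_000 * pmf.probs
        fit = fit_tgdp_tail(counts, window, MixtureConfig(seed=0))
        assert fit.params.k == pytest.approx(2.5, rel=0.01)
        assert fit.params.beta == pytest.approx(5.0, rel=0.01)

    def test_multinomial_within_3se(self):
        params = GDPParams(k=1.81, beta=8.0)
        window = TruncationWindow(11, 312)
        pmf = gdp_pmf(params, window)
        rng = np.random.default_rng(5)
        sample = rng.multinomial(10_000, pmf.probs)
        counts = np.zeros(312)
        counts[10:312] = sample
        fit = fit_tgdp_tail(counts, window, MixtureConfig(seed=5))
        assert abs(fit.params.k - 1.81) < 3 * fit.se_k
        assert abs(fit.params.beta - 8.0) < 3 * fit.se_beta

    def test_degenerate_tail_errors(self):
        counts = np.zeros(20)
        counts[14:17] = [5, 4, 3]
        with pytest.raises(PipelineError):
            fit_tgdp_tail(counts, TruncationWindow(15, 20), MixtureConfig())


class TestBackExtrapolate:
    def test_tail_reproduced_and_anchored(self):
        params = GDPParams(k=2.0, beta=3.0)
        pred = back_extrapolate(params, norm=1000.0, tail_start=10, J=200)
        assert pred[9:].sum() == pytest.approx(1000.0, abs=1e-6)
        # shape on the tail matches the truncated pmf
        tail_pmf = gdp_pmf(params, TruncationWindow(1, 200)).probs[9:]
        np.testing.assert_allclose(pred[9:], 1000.0 * tail_pmf / tail_pmf.sum(),
                                   rtol=1e-10)

    def test_head_matches_generator_expectation(self):
        """Extrapolating a truncated pure-GDP sample recovers the full shape."""
        params = GDPParams(k=2.2, beta=4.0)
        full = gdp_pmf(params, TruncationWindow(1, 150))
        n_total = 40_000
        expected_counts = n_total * full.probs
        tail_norm = expected_counts[7:].sum()
        pred = back_extrapolate(params, tail_norm, tail_start=8, J=150)
        np.testing.assert_allclose(pred, expected_counts, rtol=1e-8)


class TestEstimateThreshold:
    def _noise(self, d, amplitude):
        from kwbind.distributions import ExpNoiseParams

        return NoiseFit(ExpNoiseParams(d=d, amplitude=amplitude),
                        se_d=0.0, se_amplitude=0.0, n_points=4)

    def test_zero_noise_gives_t1(self):
        noise = self._noise(np.log(2), 1e-12)
        t, curve = estimate_threshold(noise, np.full(30, 10.0), 0.95)
        assert t == 1
        assert curve[1] > 0.999

    def test_hand_computed_small_case(self):
        # noise 8,4,2,1,... (d=ln2, A=8); specific flat 1 per bin, J=10
        noise = self._noise(np.log(2), 8.0)
        spec = np.ones(10)
        t, curve = estimate_threshold(noise, spec, 0.5)
        m = np.arange(1, 11)
        noise_tail = np.cumsum((8 * 0.5 ** (m - 1))[::-1])[::-1]
        spec_tail = np.cumsum(spec[::-1])[::-1]
        expected_t = int(m[np.argmax(spec_tail / (spec_tail + noise_tail) >= 0.5)])
        assert t == expected_t
        # Sp is non-decreasing when noise decays faster than the specific part
        sp = np.array([curve[int(i)] for i in m])
        assert np.all(np.diff(sp) >= -1e-12)

    def test_unreachable_target_reports_max(self):
        noise = self._noise(0.1, 1e6)
        with pytest.raises(PipelineError, match="max achievable"):
            estimate_threshold(noise, np.ones(5), 0.99)


class TestSubtractNoise:
    def test_noise_only_input_clips_to_zero(self):
        h = hist_from_counts({1: 8, 2: 4, 3: 2, 4: 1})
        nf = fit_noise(h, MixtureConfig(noise_fit_range=(1, 4)))
        restored, clipped = subtract_noise(h, nf)
        assert np.all(restored <= 1e-6)

    def test_additive_mixture_restores_tail(self):
        m = np.arange(1, 41)
        noise_c = 1e6 * np.exp(-1.05 * (m - 1))
        spec_c = 20_000.0 * m ** -2.0
        h = hist_from_counts(
            {int(mm): int(round(n)) for mm, n in zip(m, noise_c + spec_c)})
        nf = fit_noise(h, MixtureConfig(noise_fit_range=(1, 6)))
        restored, _ = subtract_noise(h, nf)
        np.testing.assert_allclose(restored[14:], spec_c[14:], rtol=0.05)


class TestAlphaAndTotals:
    def test_alpha_bounds_and_published_ratio(self):
        assert estimate_alpha(100.0, 100.0) == 1.0
        # tail-only specific fragment share of the reference library
        assert estimate_alpha(297493, 8424102) == pytest.approx(0.0353, abs=5e-4)
        with pytest.raises(ValueError):
            estimate_alpha(10.0, 0.0)

    @pytest.mark.parametrize("ns,p0,ntot,se", [
        (40891, 0.2, 51114, 80.0),
        (19160, 0.32, 28176, 68.0),
        (8393, 0.15, 9874, 85.0),
        (100, 0.0, 100, 100.0),
    ])
    def test_totals_accounting(self, ns, p0, ntot, se):
        got_ntot, got_n0, got_se = totals(ns, p0)
        assert got_ntot == ntot
        assert got_se == pytest.approx(se)
        assert got_n0 == round(p0 * ntot)

    def test_totals_rejects_p0_one(self):
        with pytest.raises(ValueError):
            totals(100, 1.0)


class TestFitKW:
    def test_exact_zero_truncated_recovery(self):
        params = KWParams(0.999, 6.618, 8.292)
        zt = kw_pmf_zero_truncated(params, 500)
        counts = 1e6 * zt.probs
        fit = fit_kw(counts, MixtureConfig(seed=0))
        assert abs(fit.p0 - kw_p0(params)) < 0.01

    def test_multinomial_recovery(self):
        params = KWParams(0.999, 6.618, 8.292)
        zt = kw_pmf_zero_truncated(params, 2000)
        rng = np.random.default_rng(17)
        sample = rng.multinomial(50_000, zt.probs / zt.probs.sum())
        fit = fit_kw(sample.astype(float), MixtureConfig(seed=17))
        assert abs(fit.p0 - kw_p0(params)) < 0.02

    def test_boundary_theta_allowed(self):
        """Waring-case data must be fittable without excluding theta = 1."""
        params = KWParams(1.0, 2.0, 4.0)
        zt = kw_pmf_zero_truncated(params, 800)
        fit = fit_kw(1e5 * zt.probs, MixtureConfig(seed=1))
        assert abs(fit.p0 - 0.5) < 0.02

    def test_too_few_bins(self):
        with pytest.raises(PipelineError):
            fit_kw(np.array([5.0, 3.0, 2.0, 0.0]), MixtureConfig())


class TestAnalyzeLibrary:
    def test_accounting_identities(self, small_library):
        h = small_library.histogram
        res = analyze_library(h, MixtureConfig(seed=7))
        assert res.N1 + res.N2 == res.N == h.N
        assert res.M1 + res.M2 == h.fragment_mass
        assert res.Se == pytest.approx((1 - res.p0) * 100)
        assert abs(res.Ntot - (res.N0 + round(res.Ns1 + res.Ns2))) <= 1
        assert 0 <= res.p0 < 1
        assert res.Ns == pytest.approx(res.Ns1 + res.Ns2)

    def test_gdp_approximates_kw_tail(self, small_library):
        """The fitted GDP is an adequate stand-in for the K-W tail."""
        res = analyze_library(small_library.histogram, MixtureConfig(seed=7))
        assert res.gdp.gof_pvalue > 0.01

    def test_pure_specific_library_threshold_one(self, nanog_kw):
        from kwbind.simulate import synth_library
        from kwbind import ExpNoiseParams

        lib = synth_library(nanog_kw, 20_000, ExpNoiseParams(d=1.05), 0,
                            seed=9)
        res = analyze_library(
            lib.histogram, MixtureConfig(seed=9, noise_fit_range=(1, 4)))
        # nearly all fragment mass is attributed to the specific component
        # and the exclusion zone is minimal; a small nominal noise term
        # remains because sampling fluctuations are indistinguishable from
        # faint background
        assert res.alpha > 0.9
        assert res.t <= 8
        assert res.N2 / res.N > 0.3


class TestEstimatorInterface:
    def test_sklearn_conventions(self, small_library):
        est = BindingMixtureModel(random_state=3)
        params = est.get_params()
        assert params["sp_target"] == 0.95
        est.set_params(sp_target=0.9)
        assert est.sp_target == 0.9

        X = small_library.histogram.expand().reshape(-1, 1)
        est = BindingMixtureModel(random_state=3).fit(X)
        for attr in ("threshold_", "p0_", "n_total_", "sensitivity_",
                     "alpha_", "result_"):
            assert hasattr(est, attr)
        labels = est.predict(np.array([[1], [est.threshold_], [50]]))
        assert labels.tolist() == [0, 1, 1]

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            BindingMixtureModel().predict(np.array([[3]]))

    def test_matches_function_pipeline(self, small_library):
        h = small_library.histogram
        est = BindingMixtureModel(random_state=7).fit_histogram(h)
        res = analyze_library(h, MixtureConfig(seed=7))
        assert est.threshold_ == res.t
        assert est.p0_ == pytest.approx(res.p0)
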