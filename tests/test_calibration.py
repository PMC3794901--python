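import json
import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from hpalign.align import SearchParams
from hpalign.calibration import (
    BackgroundFrequencies,
    CalibrationConfig,
    CalibrationError,
    InvChiSqFit,
    ProbabilityModel,
    bin_scores,
    build_model,
    fit_inv_chisq,
    fit_length_laws,
    model_params,
    p_value,
    random_sequence,
    sample_scores,
    scaled_inv_chisq_cdf,
    scaled_inv_chisq_pdf,
    scaled_inv_chisq_rvs,
)
from hpalign.profiles import load_scale


def closed_form_pdf(s, nu, sigma2):
    """The density written out explicitly, as an independent cross-check."""
    half = nu / 2.0
    return (
        (nu * sigma2 / 2.0) ** half
        / special.gamma(half)
        * s ** (-(1.0 + half))
        * math.exp(-nu * sigma2 / (2.0 * s))
    )


class TestBackgroundFrequencies:
    def test_robinson_robinson_sums_to_one(self):
        freqs = BackgroundFrequencies.robinson_robinson()
        assert freqs.probs.sum() == pytest.approx(1.0, abs=1e-9)
        # spot values from the published table
        assert freqs.freq["L"] == pytest.approx(0.09019)
        assert freqs.freq["W"] == pytest.approx(0.01330)

    def test_invalid_sum_rejected(self):
        bad = {a: 0.06 for a in "ACDEFGHIKLMNPQRSTVWY"}
        with pytest.raises(ValueError, match="sum to 1"):
            BackgroundFrequencies(freq=bad)


class TestRandomSequence:
    def test_zero_length_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 1"):
            random_sequence(0, BackgroundFrequencies.uniform(), rng)

    def test_degenerate_frequencies(self, rng):
        freqs = {a: 0.0 for a in "ACDEFGHIKLMNPQRSTVWY"}
        freqs["A"] = 1.0
        assert random_sequence(5, BackgroundFrequencies(freq=freqs), rng) == "AAAAA"

    def test_empirical_frequencies_within_binomial_error(self):
        rng = np.random.default_rng(4)
        freqs = BackgroundFrequencies.robinson_robinson()
        n = 100_000
        seq = random_sequence(n, freqs, rng)
        for letter in "LWAC":
            p = freqs.freq[letter]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(seq.count(letter) / n - p) < 3 * se

    def test_reproducible_under_seed(self):
        freqs = BackgroundFrequencies.robinson_robinson()
        s1 = random_sequence(50, freqs, np.random.default_rng(9))
        s2 = random_sequence(50, freqs, np.random.default_rng(9))
        assert s1 == s2


class TestScaledInvChiSq:
    @pytest.mark.parametrize("nu,sigma2", [(10, 0.5), (50, 0.01), (3, 2.0)])
    def test_pdf_matches_closed_form(self, nu, sigma2):
        for s in (0.001, 0.05, 0.3, 1.0, 7.5):
            assert scaled_inv_chisq_pdf(s, nu, sigma2) == pytest.approx(
                closed_form_pdf(s, nu, sigma2), rel=1e-12
            )

    def test_pdf_normalizes(self):
        total, _ = integrate.quad(
            lambda s: scaled_inv_chisq_pdf(s, 10, 0.5), 0.0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_closed_form(self):
        nu, sigma2 = 10.0, 0.5
        grid = np.linspace(1e-3, 3.0, 200_001)
        argmax = grid[np.argmax(scaled_inv_chisq_pdf(grid, nu, sigma2))]
        assert argmax == pytest.approx(nu * sigma2 / (nu + 2), abs=1e-4)

    def test_tails_vanish(self):
        assert scaled_inv_chisq_pdf(1e-12, 10, 0.5) == pytest.approx(0.0, abs=1e-30)
        assert scaled_inv_chisq_pdf(1e12, 10, 0.5) == pytest.approx(0.0, abs=1e-30)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            scaled_inv_chisq_pdf(-1.0, 10, 0.5)
        with pytest.raises(ValueError):
            scaled_inv_chisq_pdf(1.0, -10, 0.5)


class TestBinScores:
    def test_forty_scores_two_bins(self, rng):
        bins = bin_scores(rng.uniform(1, 2, size=40), min_count=20)
        assert bins.counts.tolist() == [20, 20]
        assert bins.edges[0] == 0.0 and bins.edges[-1] == np.inf

    def test_counts_conserved_and_floor_respected(self, rng):
        scores = rng.uniform(0.5, 3.0, size=1000)
        bins = bin_scores(scores, min_count=20)
        assert bins.counts.sum() == 1000
        assert (bins.counts >= 20).all()

    def test_remainder_absorbed_by_last_bin(self, rng):
        bins = bin_scores(rng.uniform(1, 2, size=50), min_count=20)
        assert bins.counts.tolist() == [20, 30]

    def test_too_few_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 40"):
            bin_scores(rng.uniform(1, 2, size=30), min_count=20)


class TestFitInvChiSq:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(45)
        nu, sigma2 = 50.0, 0.01
        draws = scaled_inv_chisq_rvs(nu, sigma2, 20_000, rng)
        fit = fit_inv_chisq(bin_scores(draws), len(draws), L=100)
        assert fit.nu == pytest.approx(nu, rel=0.10)
        assert fit.sigma2 == pytest.approx(sigma2, rel=0.10)
        assert fit.accepted

    def test_misspecified_distribution_rejected(self):
        rng = np.random.default_rng(43)
        draws = rng.uniform(0.5, 1.5, size=5000)
        fit = fit_inv_chisq(bin_scores(draws), len(draws))
        assert not fit.accepted

    def test_self_consistency_over_replicates(self):
        rng = np.random.default_rng(44)
        n_ok = 0
        for _ in range(50):
            draws = scaled_inv_chisq_rvs(30.0, 0.05, 2000, rng)
            fit = fit_inv_chisq(bin_scores(draws), len(draws))
            refit_draws = scaled_inv_chisq_rvs(fit.nu, fit.sigma2, 2000, rng)
            refit = fit_inv_chisq(bin_scores(refit_draws), len(refit_draws))
            n_ok += refit.gof_p >= 0.05
        assert n_ok >= 45

    def test_too_few_bins_rejected(self, rng):
        bins = bin_scores(rng.uniform(1, 2, size=60), min_count=20)
        with pytest.raises(ValueError, match="4 bins"):
            fit_inv_chisq(bins, 60)


class TestFitLengthLaws:
    @staticmethod
    def _fits(lengths, nus, sigma2s):
        return [
            InvChiSqFit(L=L, nu=n, sigma2=s, gof_p=0.5, accepted=True)
            for L, n, s in zip(lengths, nus, sigma2s)
        ]

    def test_noiseless_slope_recovery(self):
        lengths = np.array([50, 100, 150, 200, 300])
        fits = self._fits(lengths, 0.5 * lengths, np.full(5, 0.01))
        laws = fit_length_laws(fits)
        assert laws.m == pytest.approx(0.5, abs=1e-12)
        assert laws.r2_nu == pytest.approx(1.0, abs=1e-12)

    def test_sigma2_inverse_problem(self):
        a, b, c = 0.16, -1.04, 38.9
        lengths = np.array([30, 60, 100, 150, 220, 300, 400])
        sigma2s = np.exp(a + b * np.log(lengths + c))
        laws = fit_length_laws(self._fits(lengths, 0.5 * lengths, sigma2s))
        assert laws.a == pytest.approx(a, rel=0.05, abs=0.01)
        assert laws.b == pytest.approx(b, rel=0.05)
        assert laws.c == pytest.approx(c, rel=0.05)
        assert laws.r2_sigma2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_accepted_fits_rejected(self):
        fits = self._fits([50, 100], [25, 50], [0.1, 0.1])
        with pytest.raises(CalibrationError, match="accepted fits"):
            fit_length_laws(fits)

    def test_few_fits_flagged_low_confidence(self):
        lengths = np.array([50, 100, 200])
        sigma2s = np.exp(0.2 - 1.0 * np.log(lengths + 20.0))
        with pytest.warns(UserWarning, match="low-confidence"):
            laws = fit_length_laws(self._fits(lengths, 0.4 * lengths, sigma2s))
        assert laws.m == pytest.approx(0.4, abs=1e-9)


def _table_model(m=0.497609, a=0.160379, b=-1.04167, c=38.9045):
    return ProbabilityModel(
        data_type="hydropathy",
        m=m, a=a, b=b, c=c,
        params=SearchParams(),
        avg_window=15,
        scale_name="kyte_doolittle",
    )


class TestModelEvaluation:
    def test_nu_law(self):
        model = _table_model(m=0.5)
        nu, _ = model_params(100, model)
        assert nu == pytest.approx(50.0)

    def test_sigma2_law_direct_evaluation(self):
        model = _table_model()
        _, sigma2 = model_params(100, model)
        assert sigma2 == pytest.approx(
            math.exp(0.160379 - 1.04167 * math.log(138.9045)), rel=1e-12
        )

    def test_sigma2_decreasing_in_length_when_b_negative(self):
        model = _table_model()
        s2 = [model_params(L, model)[1] for L in (50, 100, 200, 400)]
        assert all(x > y for x, y in zip(s2, s2[1:]))

    def test_p_value_monotone_decreasing(self):
        model = _table_model()
        scores = np.linspace(0.001, 0.1, 50)
        ps = model.p_value(scores, 100)
        assert (np.diff(ps) < 0).all()

    def test_p_value_limits(self):
        model = _table_model()
        assert model.p_value(math.inf, 100) == 0.0
        assert model.p_value(1e9, 100) == pytest.approx(0.0, abs=1e-12)

    def test_p_value_at_median_is_half(self):
        model = _table_model()
        nu, sigma2 = model_params(100, model)
        median = stats.invgamma(a=nu / 2, scale=nu * sigma2 / 2).median()
        assert model.p_value(median, 100) == pytest.approx(0.5, abs=1e-9)

    def test_probability_integral_transform_uniform(self):
        model = _table_model()
        rng = np.random.default_rng(7)
        nu, sigma2 = model_params(100, model)
        draws = scaled_inv_chisq_rvs(nu, sigma2, 20_000, rng)
        ps = model.p_value(draws, 100)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            _table_model().p_value(0.0, 100)

    def test_domain_error_when_length_shift_invalid(self):
        model = _table_model(c=-50.0)
        with pytest.raises(ValueError, match="outside the model domain"):
            model_params(40, model)

    def test_params_mismatch_is_hard_error(self):
        model = _table_model()
        with pytest.raises(ValueError, match="recalibrate"):
            model.check_params(SearchParams(C=0.3))


class TestSampleScores:
    def test_reproducible_and_single_record(self, kd):
        params = SearchParams()
        samples = [
            sample_scores([40], 3, kd, 15, params, np.random.default_rng(5))
            for _ in range(2)
        ]
        assert np.array_equal(samples[0].s, samples[1].s)
        assert np.array_equal(samples[0].L, samples[1].L)
        assert len(samples[0]) <= 3

    def test_exact_matches_excluded(self, rng):
        # a one-letter alphabet makes every profile flat: all pairs are
        # exact matches and must be excluded as infinite-score
        freqs = {a: 0.0 for a in "ACDEFGHIKLMNPQRSTVWY"}
        freqs["A"] = 1.0
        sample = sample_scores(
            [40], 5, load_scale(), 15, SearchParams(),
            rng, freqs=BackgroundFrequencies(freq=freqs),
        )
        assert len(sample) == 0
        assert sample.n_exact == 5

    def test_short_profile_length_skipped(self, kd, rng):
        with pytest.warns(UserWarning, match="skipped"):
            sample = sample_scores([3, 40], 2, kd, 15, SearchParams(), rng)
        assert sample.profile_lengths == (40,)


class TestBuildModel:
    def test_smoke_and_determinism(self):
        cfg = CalibrationConfig(
            profile_lengths=(40, 60), pairs_per_length=300, seed=11
        )
        m1 = build_model(cfg)
        m2 = build_model(cfg)
        assert m1.to_dict() == m2.to_dict()
        assert m1.m > 0
        assert all(f.nu > 0 and f.sigma2 > 0 for f in m1.per_length_fits)

    def test_round_trip_json(self, tmp_path, small_model):
        path = tmp_path / "model.json"
        small_model.save(path)
        back = ProbabilityModel.load(path)
        assert back.to_dict() == small_model.to_dict()
        assert json.loads(path.read_text())["schema"] == 1

    def test_small_model_sane(self, small_model):
        lo, hi = small_model.fitted_length_range
        assert 0 < lo < hi
        assert small_model.m > 0
        # p-values behave inside the calibrated range
        mid = (lo + hi) // 2
        assert 0 < p_value(10.0, int(mid), small_model) <= 1

    def test_insufficient_data_raises(self):
        cfg = CalibrationConfig(profile_lengths=(8,), pairs_per_length=30, seed=1)
        with pytest.raises(CalibrationError):
            build_model(cfg)
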