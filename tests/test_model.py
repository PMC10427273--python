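import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit

from lyricbias.covariates import Design, DesignConfig, DesignRow
from lyricbias.model import (
    CoefSummary,
    ConvergenceWarning,
    FitResult,
    ModelSpec,
    PriorConfig,
    SamplerConfig,
    fit,
    log_likelihood,
    log_prior,
    odds_interpretation,
    summarize,
)


def make_row(song_id="r", k=3, W=10, success=0.0, prestige=0.0, unbiased=0.0,
             rank=None, artist_idx=0, genre_idx=None, year_idx=0):
    return DesignRow(song_id, k, W, success, prestige, unbiased, rank,
                     artist_idx, genre_idx, year_idx)


def make_design(rows, polarity="positive", genre_levels=(), year_levels=None):
    n_artists = max(r.artist_idx for r in rows) + 1
    n_years = max(r.year_idx for r in rows) + 1
    return Design(
        rows=list(rows),
        polarity=polarity,
        artist_levels=[f"a{i}" for i in range(n_artists)],
        genre_levels=list(genre_levels),
        year_levels=list(year_levels or range(n_years)),
        config=DesignConfig(),
    )


class TestLogLikelihood:
    def test_closed_form_at_half(self):
        rows = [make_row(k=0, W=10)]
        ll = log_likelihood({"alpha": 0.0, "beta": {}}, rows)
        assert ll[0] == pytest.approx(10 * math.log(0.5))

    def test_binomial_identity_vs_bernoulli(self):
        # aggregated = sum of W Bernoulli terms + log C(W, k)
        rows = [make_row(k=4, W=9, unbiased=0.7)]
        params = {"alpha": -0.3, "beta": {"unbiased": 0.5}}
        ll = log_likelihood(params, rows)[0]
        eta = -0.3 + 0.5 * 0.7
        p = expit(eta)
        bernoulli = 4 * math.log(p) + 5 * math.log(1 - p)
        assert ll == pytest.approx(bernoulli + math.log(math.comb(9, 4)))

    def test_random_instances_match_naive_oracle(self, rng):
        for _ in range(50):
            W = int(rng.integers(1, 30))
            k = int(rng.integers(0, W + 1))
            alpha = float(rng.normal())
            b = float(rng.normal())
            x = float(rng.normal())
            a_art = rng.normal(size=3)
            a_year = rng.normal(size=2)
            ai = int(rng.integers(3))
            yi = int(rng.integers(2))
            rows = [make_row(k=k, W=W, unbiased=x, artist_idx=ai, year_idx=yi)]
            ll = log_likelihood(
                {"alpha": alpha, "beta": {"unbiased": b},
                 "a_artist": a_art, "a_year": a_year},
                rows,
            )[0]
            p = expit(alpha + b * x + a_art[ai] + a_year[yi])
            naive = math.log(math.comb(W, k)) + k * math.log(p) + (W - k) * math.log1p(-p)
            assert ll == pytest.approx(naive, rel=1e-9)

    def test_impossible_k_at_p_zero_is_neg_inf(self):
        rows = [make_row(k=1, W=5)]
        ll = log_likelihood({"alpha": -np.inf, "beta": {}}, rows)
        assert ll[0] == -np.inf

    def test_consistent_k_at_p_zero_is_zero(self):
        rows = [make_row(k=0, W=5)]
        ll = log_likelihood({"alpha": -np.inf, "beta": {}}, rows)
        assert ll[0] == pytest.approx(0.0)

    def test_row_split_changes_only_binomial_constant(self):
        whole = [make_row("w", k=6, W=20, unbiased=0.4)]
        parts = [
            make_row("p1", k=2, W=8, unbiased=0.4),
            make_row("p2", k=4, W=12, unbiased=0.4),
        ]
        deltas = []
        for alpha, b in [(0.3, -0.2), (-1.0, 0.9)]:
            params = {"alpha": alpha, "beta": {"unbiased": b}}
            deltas.append(
                log_likelihood(params, parts).sum() - log_likelihood(params, whole).sum()
            )
        # parameter-independent constant
        assert deltas[0] == pytest.approx(deltas[1])
        expected = (
            math.log(math.comb(8, 2)) + math.log(math.comb(12, 4))
            - math.log(math.comb(20, 6))
        )
        assert deltas[0] == pytest.approx(expected)

    def test_mle_is_pooled_proportion(self):
        rows = [make_row(f"r{i}", k=k, W=10) for i, k in enumerate([2, 3, 5, 4])]
        total_k, total_w = 14, 40
        alphas = np.linspace(-3, 3, 2001)
        totals = [log_likelihood({"alpha": a, "beta": {}}, rows).sum() for a in alphas]
        best = alphas[int(np.argmax(totals))]
        assert expit(best) == pytest.approx(total_k / total_w, abs=1e-3)


class TestLogPrior:
    def test_value_at_prior_means(self):
        spec = ModelSpec(polarity="positive", effects=("success",))
        value = log_prior({"alpha": 0.0, "beta": {"success": 0.0}}, spec)
        expected = (
            -math.log(1.5) - 0.5 * math.log(2 * math.pi)
            - math.log(1.0) - 0.5 * math.log(2 * math.pi)
        )
        assert value == pytest.approx(expected)

    def test_group_terms(self):
        spec = ModelSpec(polarity="positive")
        a = np.array([0.1, -0.2])
        sigma = 0.7
        value = log_prior({"alpha": 0.0, "a_artist": a, "sigma_artist": sigma}, spec)
        expected = (
            -math.log(1.5) - 0.5 * math.log(2 * math.pi)
            - sigma  # Exponential(1) log density
            + sum(
                -0.5 * (x / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
                for x in a
            )
        )
        assert value == pytest.approx(expected)

    def test_nonpositive_sigma_is_neg_inf(self):
        spec = ModelSpec(polarity="positive")
        assert log_prior({"alpha": 0.0, "sigma_artist": 0.0}, spec) == -np.inf
        assert log_prior({"alpha": 0.0, "sigma_artist": -1.0}, spec) == -np.inf

    def test_larger_slope_magnitude_decreases_prior(self):
        spec = ModelSpec(polarity="positive", effects=("success",))
        small = log_prior({"alpha": 0.0, "beta": {"success": 0.4}}, spec)
        large = log_prior({"alpha": 0.0, "beta": {"success": 0.8}}, spec)
        assert large < small

    def test_two_parameter_density_integrates_to_one(self):
        spec = ModelSpec(polarity="positive", effects=("success",))

        def density(b, a):
            return math.exp(log_prior({"alpha": a, "beta": {"success": b}}, spec))

        total, _ = integrate.dblquad(density, -12, 12, -8, 8)
        assert total == pytest.approx(1.0, abs=1e-4)


def _simulated_design(rng, n_years=8, n_songs=40, n_artists=8, W=60,
                      alpha=-2.0, beta=0.5, sigma_artist=0.3, sigma_year=0.15):
    x_year = rng.normal(0, 1, n_years)
    a_art = rng.normal(0, sigma_artist, n_artists)
    a_year = rng.normal(0, sigma_year, n_years)
    rows = []
    for y in range(n_years):
        for j in range(n_songs):
            a = int(rng.integers(n_artists))
            p = expit(alpha + beta * x_year[y] + a_art[a] + a_year[y])
            rows.append(
                make_row(f"s{y}-{j}", k=int(rng.binomial(W, p)), W=W,
                         unbiased=float(x_year[y]), artist_idx=a, year_idx=y)
            )
    return make_design(rows)


FAST = SamplerConfig(chains=2, draws=200, warmup=300, path_length=3.0,
                     ess_threshold=50.0, rhat_threshold=1.05)


class TestFit:
    def test_intercept_only_recovers_pooled_proportion(self, rng):
        rows = [
            make_row(f"r{i}", k=int(rng.binomial(50, 0.3)), W=50,
                     artist_idx=i % 4, year_idx=i % 3)
            for i in range(120)
        ]
        design = make_design(rows)
        q = sum(r.k for r in rows) / sum(r.W for r in rows)
        spec = ModelSpec(polarity="positive", effects=(),
                         groups=("artist", "year"), sampler=FAST)
        result = fit(spec, design, seed=5)
        alpha_mean = result.stacked("alpha").mean()
        assert expit(alpha_mean) == pytest.approx(q, abs=0.02)

    def test_same_seed_identical_draws(self, rng):
        design = _simulated_design(rng, n_years=5, n_songs=15)
        spec = ModelSpec(polarity="positive", effects=("unbiased",),
                         groups=("artist", "year"), sampler=FAST)
        a = fit(spec, design, seed=77)
        b = fit(spec, design, seed=77)
        assert np.array_equal(a.stacked("alpha"), b.stacked("alpha"))
        assert np.array_equal(a.loglik_matrix, b.loglik_matrix)

    def test_different_seed_different_draws(self, rng):
        design = _simulated_design(rng, n_years=5, n_songs=15)
        spec = ModelSpec(polarity="positive", effects=("unbiased",),
                         groups=("artist", "year"), sampler=FAST)
        a = fit(spec, design, seed=77)
        b = fit(spec, design, seed=78)
        assert not np.array_equal(a.stacked("alpha"), b.stacked("alpha"))

    def test_slope_recovery_exogenous_covariate(self, rng):
        design = _simulated_design(rng, beta=0.5)
        spec = ModelSpec(polarity="positive", effects=("unbiased",),
                         groups=("artist", "year"), sampler=FAST)
        result = fit(spec, design, seed=3)
        draws = result.stacked("beta_unbiased")
        lo, hi = np.quantile(draws, [0.055, 0.945])
        assert lo < 0.5 < hi

    def test_constant_covariate_is_error(self):
        rows = [make_row(f"r{i}", k=2, W=10, unbiased=1.0, artist_idx=i % 2,
                         year_idx=i % 2) for i in range(8)]
        design = make_design(rows)
        spec = ModelSpec(polarity="positive", effects=("unbiased",),
                         groups=("artist", "year"), sampler=FAST)
        with pytest.raises(ValueError, match="unbiased"):
            fit(spec, design, seed=1)

    def test_single_level_group_is_error(self):
        rows = [make_row(f"r{i}", k=2, W=10, artist_idx=0, year_idx=i % 3)
                for i in range(9)]
        design = make_design(rows)
        spec = ModelSpec(polarity="positive", groups=("artist", "year"), sampler=FAST)
        with pytest.raises(ValueError, match="artist"):
            fit(spec, design, seed=1)

    def test_genre_dropped_when_absent(self, rng):
        design = _simulated_design(rng, n_years=4, n_songs=12)
        spec = ModelSpec(polarity="positive", effects=(),
                         groups=("artist", "genre", "year"), sampler=FAST)
        result = fit(spec, design, seed=9)
        assert result.groups_used == ("artist", "year")
        assert "sigma_genre" not in result.posterior

    def test_loglik_matrix_shape(self, rng):
        design = _simulated_design(rng, n_years=4, n_songs=10)
        spec = ModelSpec(polarity="positive", effects=("unbiased",),
                         groups=("artist", "year"), sampler=FAST)
        result = fit(spec, design, seed=2)
        assert result.loglik_matrix.shape == (400, len(design))
        assert np.isfinite(result.loglik_matrix).all()

    def test_poor_sampling_warns(self, rng):
        design = _simulated_design(rng, n_years=4, n_songs=10)
        strict = SamplerConfig(chains=2, draws=120, warmup=150,
                               ess_threshold=1e6, rhat_threshold=1.0)
        spec = ModelSpec(polarity="positive", effects=(),
                         groups=("artist", "year"), sampler=strict)
        with pytest.warns(ConvergenceWarning):
            fit(spec, design, seed=2)


class TestSummarize:
    def _fit_result(self, draws_by_name):
        posterior = {
            name: np.asarray(d, dtype=float).reshape(1, -1)
            for name, d in draws_by_name.items()
        }
        n = next(iter(posterior.values())).shape[1]
        return FitResult(
            posterior=posterior,
            log_lik=np.zeros((1, n, 1)),
            diagnostics={},
            spec=ModelSpec(polarity="positive"),
            seed=0,
            groups_used=(),
        )

    def test_symmetric_draws_do_not_exclude_zero(self, rng):
        draws = rng.normal(0, 1, 4000)
        (summary,) = summarize(self._fit_result({"alpha": draws}))
        assert not summary.excludes_zero

    def test_all_positive_draws_exclude_zero(self, rng):
        draws = rng.uniform(0.5, 1.0, 500)
        (summary,) = summarize(self._fit_result({"alpha": draws}))
        assert summary.excludes_zero

    def test_bounds_match_order_statistics(self, rng):
        draws = rng.normal(2.0, 3.0, 1001)
        (summary,) = summarize(self._fit_result({"alpha": draws}), ci_mass=0.89)
        srt = np.sort(draws)
        assert summary.lower == pytest.approx(np.quantile(srt, 0.055))
        assert summary.upper == pytest.approx(np.quantile(srt, 0.945))
        assert summary.lower <= summary.mean <= summary.upper

    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize(self._fit_result({"alpha": rng.normal(size=50)}))


class TestOddsInterpretation:
    def test_paper_reading_of_small_coefficient(self):
        assert odds_interpretation(0.04) == pytest.approx(4.08, abs=0.01)

    def test_zero(self):
        assert odds_interpretation(0.0) == 0.0

    def test_negative(self):
        assert odds_interpretation(-0.02) == pytest.approx(-1.98, abs=0.01)

    def test_exact_formula(self):
        assert odds_interpretation(0.3) == pytest.approx(100 * (math.exp(0.3) - 1))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            odds_interpretation(float("nan"))
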