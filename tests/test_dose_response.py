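"""Sigmoid dose-response model: priors, partition, fitting, hypotheses."""

import math

import numpy as np
import pytest

from netpharm.calibration import FAST_SAMPLER, SBC_Y0_PRIOR
from netpharm.dose_response import (
    DoseResponseDataset,
    DoseResponseResults,
    SamplerConfig,
    SigmoidDoseResponseModel,
    destandardize,
    fold_change_prior,
    hypothesis_partition,
    sigmoid_mean,
    simulate_dataset,
    standardize,
)


def make_dataset(y, x=(1.0, 3.0, 10.0), reps=None, direction="decrease"):
    y = tuple(y)
    if reps is None:
        reps = len(y) // len(x)
    return DoseResponseDataset(
        drug="d",
        assay="a",
        direction_of_benefit=direction,
        concentrations_uM=tuple(np.repeat(x, reps)),
        bioactivity=y,
    )


class TestStandardize:
    def test_sd_five_gives_factor_two(self, rng):
        y = rng.normal(0, 1, size=30)
        y = 5.0 * (y - y.mean()) / y.std(ddof=1) + 50
        ds = standardize(make_dataset(y, x=(1, 3, 10), reps=10))
        assert ds.scale_factor == pytest.approx(2.0)
        assert np.std(ds.y, ddof=1) == pytest.approx(10.0)

    def test_sd_ten_unchanged(self, rng):
        y = rng.normal(0, 1, size=30)
        y = 10.0 * (y - y.mean()) / y.std(ddof=1) + 50
        ds = standardize(make_dataset(y, reps=10))
        assert np.allclose(ds.y, y)

    def test_constant_y_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(make_dataset([3.0] * 6, reps=2))

    def test_round_trip_machine_precision(self, rng):
        y = 7.0 * rng.normal(size=12) + 40
        ds = make_dataset(y, reps=4)
        back = destandardize(standardize(ds))
        assert np.allclose(back.y, y, rtol=1e-14)
        assert back.scale_factor == 1.0


class TestPrior:
    def test_mean_is_one(self):
        assert fold_change_prior().mean() == pytest.approx(1.0)

    def test_normalized(self):
        assert fold_change_prior().cdf(np.inf) == 1.0

    def test_quantiles_match_incomplete_gamma_inversion(self):
        from scipy.special import gammaincinv

        prior = fold_change_prior()
        for q in (0.2, 0.8):
            # invert the regularized incomplete gamma directly
            want = gammaincinv(5.0, q) / 5.0
            assert prior.ppf(q) == pytest.approx(want, rel=1e-12)


class TestHypothesisPartition:
    @pytest.mark.parametrize("direction", ["increase", "decrease"])
    def test_prior_masses(self, direction):
        part = hypothesis_partition(direction)
        p, n, a = part.prior_masses()
        assert p == pytest.approx(0.2, abs=1e-9)
        assert n == pytest.approx(0.6, abs=1e-9)
        assert a == pytest.approx(0.2, abs=1e-9)

    def test_directions_swap_tails_neutral_invariant(self):
        dec = hypothesis_partition("decrease")
        inc = hypothesis_partition("increase")
        assert dec.lower == inc.lower and dec.upper == inc.upper
        fc = np.array([0.2, 1.0, 3.0])
        p_dec, n_dec, a_dec = dec.classify(fc)
        p_inc, n_inc, a_inc = inc.classify(fc)
        assert (n_dec == n_inc).all()
        assert (p_dec == a_inc).all() and (a_dec == p_inc).all()

    def test_monte_carlo_frequencies(self):
        draws = fold_change_prior().rvs(size=10**6, random_state=7)
        prot, neut, adv = hypothesis_partition("decrease").classify(draws)
        assert prot.mean() == pytest.approx(0.2, abs=0.01)
        assert neut.mean() == pytest.approx(0.6, abs=0.01)
        assert adv.mean() == pytest.approx(0.2, abs=0.01)


class TestModelAlgebra:
    def test_mean_at_ec50_is_midpoint(self, rng):
        for _ in range(20):
            y0, y1 = rng.uniform(1, 50, size=2)
            k = rng.uniform(0.1, 10)
            ec50 = rng.uniform(-1, 2)
            got = sigmoid_mean(np.array([ec50]), y0, y1, k, ec50)[0]
            assert got == pytest.approx((y0 + y1) / 2, rel=1e-12)

    def test_flat_curve_when_fc_is_one(self):
        x = np.linspace(-2, 3, 50)
        mu = sigmoid_mean(x, 30.0, 30.0, 5.0, 0.5)
        assert np.allclose(mu, 30.0)

    def test_heteroscedastic_noise_scales_with_mean(self, rng):
        # doubling mu doubles the noise sd, on the model's own simulator
        n = 10**4
        y_small = simulate_dataset(
            "d", "a", "decrease", (1.0, 1.0001), n // 2, 20.0, 1.0, 1.0, 0.0, 0.1, rng
        )
        rng2 = np.random.default_rng(99)
        y_big = simulate_dataset(
            "d", "a", "decrease", (1.0, 1.0001), n // 2, 40.0, 1.0, 1.0, 0.0, 0.1, rng2
        )
        sd_small = np.std(y_small.y, ddof=1)
        sd_big = np.std(y_big.y, ddof=1)
        assert sd_big / sd_small == pytest.approx(2.0, rel=0.1)

    def test_simulator_noiseless_limit(self, rng):
        ds = simulate_dataset(
            "d", "a", "decrease", (1, 3, 10), 2, 30.0, 0.5, 2.0, 0.5, 0.0, rng
        )
        mu = sigmoid_mean(np.log10(ds.x), 30.0, 15.0, 2.0, 0.5)
        assert np.allclose(ds.y, mu)

    def test_simulator_variance_moment_check(self, rng):
        sigma, y0 = 0.1, 25.0
        ds = simulate_dataset(
            "d", "a", "decrease", (1.0, 1.0001), 10**4 // 2, y0, 1.0, 1.0, 0.0,
            sigma, rng,
        )
        assert np.var(ds.y, ddof=1) == pytest.approx((sigma * y0) ** 2, rel=0.1)

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(ValueError, match="non-positive"):
            simulate_dataset(
                "d", "a", "decrease", (1, 3, 10), 2, -5.0, 0.5, 2.0, 0.5, 0.1, rng
            )


class TestFit:
    def test_deterministic_under_seed(self, rng):
        ds = simulate_dataset(
            "d", "a", "decrease", (1, 3, 10), 3, 30.0, 0.4, 2.0, 0.5, 0.05, rng
        )
        m = SigmoidDoseResponseModel(ds, y0_prior=SBC_Y0_PRIOR)
        cfg = SamplerConfig(draws=200, warmup=200, walkers=16, seed=42)
        r1 = m.fit(cfg)
        r2 = m.fit(cfg)
        assert np.array_equal(r1.chain, r2.chain)

    def test_fc_sample_identity(self, rng):
        ds = simulate_dataset(
            "d", "a", "decrease", (1, 3, 10), 3, 30.0, 0.4, 2.0, 0.5, 0.05, rng
        )
        res = SigmoidDoseResponseModel(ds).fit(
            SamplerConfig(draws=200, warmup=200, walkers=16, seed=0)
        )
        assert np.allclose(res.samples("y1"), res.samples("fc") * res.samples("y0"))

    def test_parameter_recovery_median_of_medians(self):
        # strong-signal datasets at FC_true = 0.3: median posterior FC close
        medians = []
        rng = np.random.default_rng(2024)
        for _ in range(20):
            ds = simulate_dataset(
                "d", "a", "decrease", (1, 3, 10), 5, 30.0, 0.3, 3.0, 0.5, 0.02, rng
            )
            res = SigmoidDoseResponseModel(ds, y0_prior=SBC_Y0_PRIOR).fit(
                SamplerConfig(
                    draws=FAST_SAMPLER.draws,
                    warmup=FAST_SAMPLER.warmup,
                    walkers=FAST_SAMPLER.walkers,
                    thin=FAST_SAMPLER.thin,
                    seed=int(rng.integers(2**31)),
                )
            )
            medians.append(float(np.median(res.fold_change)))
        assert 0.2 <= np.median(medians) <= 0.45

    def test_posterior_interval_covers_flat_truth(self):
        # FC_true = 1 (flat): the 5-95% interval should usually contain 1
        rng = np.random.default_rng(77)
        covered = 0
        n_rep = 20
        for _ in range(n_rep):
            ds = simulate_dataset(
                "d", "a", "decrease", (1, 3, 10), 5, 30.0, 1.0, 2.0, 0.5, 0.05, rng
            )
            res = SigmoidDoseResponseModel(ds, y0_prior=SBC_Y0_PRIOR).fit(
                SamplerConfig(
                    draws=FAST_SAMPLER.draws,
                    warmup=FAST_SAMPLER.warmup,
                    walkers=FAST_SAMPLER.walkers,
                    thin=FAST_SAMPLER.thin,
                    seed=int(rng.integers(2**31)),
                )
            )
            lo, hi = np.quantile(res.fold_change, [0.05, 0.95])
            covered += lo <= 1.0 <= hi
        assert covered >= int(0.9 * n_rep) - 1


class TestCheckFit:
    def _results_with_chain(self, chain):
        ds = make_dataset([20.0, 21, 19, 18, 22, 20], reps=2)
        m = SigmoidDoseResponseModel(ds)
        return DoseResponseResults(m, chain, SamplerConfig(diag_chains=4))

    def test_ideal_diagnostics_pass(self, rng):
        chain = rng.normal(10, 1, size=(8, 500, 5))
        chain[:, :, 1] = np.abs(chain[:, :, 1]) / 10  # fc positive
        res = self._results_with_chain(chain)
        assert res.check_fit().passed

    def test_injected_rhat_failure(self, rng):
        chain = rng.normal(10, 1, size=(8, 500, 5))
        chain[:4, :, 0] += 50.0  # half the walkers on a shifted mode
        res = self._results_with_chain(chain)
        check = res.check_fit()
        assert not check.passed
        assert any("rhat(y0)" in r for r in check.reasons)

    def test_well_specified_fits_pass_at_default_settings(self):
        rng = np.random.default_rng(5150)
        n_pass = 0
        for _ in range(5):
            ds = simulate_dataset(
                "d", "a", "decrease", (1, 3, 10), 5, 30.0, 0.4, 2.0, 0.5, 0.05, rng
            )
            res = SigmoidDoseResponseModel(ds, y0_prior=SBC_Y0_PRIOR).fit(
                SamplerConfig(seed=int(rng.integers(2**31)))
            )
            n_pass += res.check_fit().passed
        assert n_pass >= 4


class TestHypothesisTest:
    def _results_with_fc(self, fc_values, direction="decrease"):
        fc = np.asarray(fc_values, dtype=float)
        chain = np.zeros((1, len(fc), 5))
        chain[0, :, 0] = 30.0
        chain[0, :, 1] = fc
        chain[0, :, 2] = 1.0
        chain[0, :, 3] = 0.5
        chain[0, :, 4] = 0.1
        ds = make_dataset([20.0, 21, 19, 18, 22, 20], reps=2, direction=direction)
        m = SigmoidDoseResponseModel(ds)
        return DoseResponseResults(m, chain, SamplerConfig(diag_chains=1))

    def test_all_neutral_gives_bf_zero_grade_none(self):
        res = self._results_with_fc([1.0] * 100)
        ht = res.hypothesis_test()
        assert ht.p_neutral == 1.0 and ht.bf == 0.0
        assert ht.evidence_grade == "none"

    def test_equal_odds(self):
        part = hypothesis_partition("decrease")
        below = part.lower / 2
        res = self._results_with_fc([below] * 50 + [1.0] * 50)
        ht = res.hypothesis_test()
        assert ht.bf == pytest.approx(1.0)
        assert ht.two_log_bf == pytest.approx(0.0)

    def test_probabilities_sum_to_one(self, rng):
        res = self._results_with_fc(rng.gamma(5, 0.2, size=1000))
        ht = res.hypothesis_test()
        assert ht.p_protective + ht.p_neutral + ht.p_adverse == pytest.approx(
            1.0, abs=1e-9
        )

    def test_no_neutral_samples_flags_infinite_bf(self):
        part = hypothesis_partition("decrease")
        res = self._results_with_fc([part.lower / 2] * 100)
        ht = res.hypothesis_test()
        assert ht.bf_infinite and math.isinf(ht.bf)

    def test_grades_boundaries(self):
        from netpharm.dose_response import _evidence_grade

        assert _evidence_grade(2.0) == "none"
        assert _evidence_grade(2.1) == "moderate"
        assert _evidence_grade(6.1) == "strong"
        assert _evidence_grade(10.1) == "very strong"


class TestDatasetValidation:
    def test_needs_two_distinct_concentrations(self):
        with pytest.raises(ValueError):
            make_dataset([1.0, 2.0], x=(5.0,), reps=2)

    def test_positive_concentrations(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(
                drug="d",
                assay="a",
                direction_of_benefit="decrease",
                concentrations_uM=(0.0, 1.0),
                bioactivity=(1.0, 2.0),
            )
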