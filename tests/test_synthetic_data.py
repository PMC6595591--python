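"""Generator, calibration and composite-construction tests."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import ranklab
from ranklab.synthetic_data import (
    CalibrationResult,
    ScenarioA,
    ScenarioB,
    calibrate_intercept,
    calibrate_tau,
    compose_ordinal,
    marginal_prevalence,
    seed_sequence,
    simulate_binary_dataset,
    simulate_composite_dataset,
    simulate_hospital_effects,
    tau_from_icc,
    write_dataset_csv,
)
from ranklab.rankability import icc_latent


class TestTauIccConversion:
    def test_zero(self):
        assert tau_from_icc(0.0) == 0.0

    def test_closed_form_half(self):
        assert tau_from_icc(0.5) == pytest.approx(np.pi * np.sqrt(1 / 3), abs=1e-12)

    def test_round_trip_on_grid(self):
        for icc in np.arange(0.0, 0.2401, 0.02):
            assert icc_latent(tau_from_icc(icc) ** 2) == pytest.approx(icc, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.01, 1.0, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            tau_from_icc(bad)


class TestComposeOrdinal:
    # severity mapping: 5 = most severe present, 1 = none
    EXPECTED = {
        (0, 0, 0): 1,
        (0, 0, 1): 2,
        (0, 1, 0): 3,
        (0, 1, 1): 4,
        (1, 0, 0): 5,
        (1, 0, 1): 5,
        (1, 1, 0): 5,
        (1, 1, 1): 5,
    }

    def test_exhaustive_mapping(self):
        for (y1, y2, y3), level in self.EXPECTED.items():
            assert compose_ordinal(y1, y2, y3) == level

    def test_partition_and_reachability(self):
        levels = {compose_ordinal(*combo) for combo in self.EXPECTED}
        assert levels == {1, 2, 3, 4, 5}

    def test_level5_iff_y1(self):
        y1, y2, y3 = np.array([1, 0, 1, 0]), np.array([1, 1, 0, 0]), np.array([0, 1, 1, 0])
        out = compose_ordinal(y1, y2, y3)
        assert np.array_equal(out == 5, y1 == 1)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            compose_ordinal(2, 0, 0)


class TestMarginalPrevalence:
    def test_symmetry_gives_half(self):
        for tau, a1 in [(0.0, 0.0), (0.7, 0.3), (1.5, -1.0)]:
            assert marginal_prevalence(0.0, a1, tau) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_is_expit(self):
        assert marginal_prevalence(-1.3, 0.0, 0.0) == expit(-1.3)

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(2024)
        n = 10_000_000
        draws = expit(-2.0 + np.sqrt(0.5**2 + 1.0**2) * rng.standard_normal(n))
        mc = draws.mean()
        se = draws.std() / np.sqrt(n)
        assert abs(marginal_prevalence(-2.0, 1.0, 0.5) - mc) < 3 * se

    def test_quadrature_converged(self):
        # default rule vs 10x denser, over a parameter grid
        for a0 in (-3.0, -1.0, 0.5):
            for a1 in (-0.25, 0.5, 1.0):
                for tau in (0.1, 0.5, 1.2):
                    assert marginal_prevalence(a0, a1, tau, n_nodes=80) == pytest.approx(
                        marginal_prevalence(a0, a1, tau, n_nodes=800), abs=1e-6
                    )


class TestCalibrateIntercept:
    def test_half_target_is_zero(self):
        assert calibrate_intercept(0.5, -0.25, 0.8) == pytest.approx(0.0, abs=1e-7)

    def test_monte_carlo_oracle(self):
        a0 = calibrate_intercept(0.05, -0.25, 0.5)
        rng = np.random.default_rng(7)
        n = 10_000_000
        prev = expit(a0 + np.sqrt(0.5**2 + 0.25**2) * rng.standard_normal(n)).mean()
        assert prev == pytest.approx(0.05, abs=0.001)

    def test_monotone_in_target(self):
        targets = [0.02, 0.05, 0.1, 0.25, 0.5, 0.8]
        a0s = [calibrate_intercept(t, 0.5, 0.7) for t in targets]
        assert np.all(np.diff(a0s) > 0)

    def test_tolerance_contract(self):
        for t, a1, tau in [(0.05, -0.25, 0.3), (0.25, 1.0, 1.2)]:
            a0 = calibrate_intercept(t, a1, tau)
            assert abs(marginal_prevalence(a0, a1, tau) - t) < 1e-5


class TestHospitalEffects:
    def test_degenerate_cov(self):
        eff = simulate_hospital_effects([1.0, -2.0], np.zeros((2, 2)), 5, 0)
        assert np.allclose(eff.effects, [1.0, -2.0])

    def test_large_sample_correlation(self):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        eff = simulate_hospital_effects([0, 0], cov, 10_000, 123)
        r = np.corrcoef(eff.effects.T)[0, 1]
        assert abs(r - 0.9) < 0.02

    def test_determinism(self):
        a = simulate_hospital_effects([0, 0, 0], np.eye(3), 50, 99).effects
        b = simulate_hospital_effects([0, 0, 0], np.eye(3), 50, 99).effects
        assert np.array_equal(a, b)

    def test_non_psd_rejected_with_eigenvalue(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_hospital_effects([0, 0], cov, 10, 0)


class TestSimulateBinaryDataset:
    def test_row_count_and_uniqueness(self):
        s = ScenarioA(icc=0.1, alpha0=-2, alpha1=0.25, n_hospitals=7, n_per_hospital=13)
        df = simulate_binary_dataset(s, 0)
        assert len(df) == 7 * 13
        assert not df.duplicated(["hospital_id", "patient_id"]).any()
        # hospital-major row order
        assert np.array_equal(df["hospital_id"], np.repeat(np.arange(1, 8), 13))

    def test_symmetric_null_rate(self):
        s = ScenarioA(icc=0.0, alpha0=0.0, alpha1=0.0, n_hospitals=100, n_per_hospital=500)
        df = simulate_binary_dataset(s, 11)
        se = np.sqrt(0.25 / len(df))
        assert abs(df["y1"].mean() - 0.5) < 3 * se

    def test_clustering_raises_between_hospital_variance(self):
        # empirical-logit variance under strong clustering exceeds the null case
        def logit_var(icc, seed):
            s = ScenarioA(icc=icc, alpha0=-3.0, alpha1=0.0, n_hospitals=50, n_per_hospital=200)
            df = simulate_binary_dataset(s, seed)
            rates = df.groupby("hospital_id")["y1"].mean().to_numpy()
            rates = np.clip(rates, 0.5 / 200, 1 - 0.5 / 200)
            return np.var(np.log(rates / (1 - rates)))

        high = [logit_var(0.24, seed_sequence(1, i)) for i in range(20)]
        null = [logit_var(0.0, seed_sequence(2, i)) for i in range(20)]
        assert np.mean(high) > 2 * np.mean(null)

    def test_byte_identical_csv(self):
        s = ScenarioA(icc=0.05, alpha0=-1.5, alpha1=0.25, n_hospitals=5, n_per_hospital=20)
        out = []
        for _ in range(2):
            buf = io.StringIO()
            write_dataset_csv(simulate_binary_dataset(s, 37), buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]
        assert out[0].splitlines()[0] == "hospital_id,patient_id,x,y1"


@pytest.fixture(scope="module")
def default_calibration():
    """Analytic calibration of the default composite scenario at 50x200."""
    s = ScenarioB(n_hospitals=50, n_per_hospital=200)
    comps = [
        calibrate_tau(s.target_rankabilities[k], s.prevalences[k], s.slopes[k],
                      50, 200, method="analytic")
        for k in range(3)
    ]
    return s, CalibrationResult(
        alpha0=[c.alpha0 for c in comps],
        tau=[c.tau for c in comps],
        achieved_prevalences=[c.achieved_prevalence for c in comps],
        achieved_rankabilities=[c.achieved_rankability for c in comps],
    )


class TestSimulateCompositeDataset:
    def test_calibrated_prevalences(self, default_calibration):
        s, cal = default_calibration
        means = np.zeros(3)
        for rep in range(20):
            df = simulate_composite_dataset(s, cal, seed_sequence(5, rep))
            means += [df["y1"].mean(), df["y2"].mean(), df["y3"].mean()]
        means /= 20
        assert np.allclose(means, [0.05, 0.10, 0.25], atol=0.01)

    def test_level5_equals_y1(self, default_calibration):
        s, cal = default_calibration
        df = simulate_composite_dataset(s, cal, 3)
        assert np.array_equal(df["y_ordinal"] == 5, df["y1"] == 1)
        probs = df["y_ordinal"].value_counts(normalize=True)
        assert probs.sum() == pytest.approx(1.0)

    def test_uncorrelated_effects_give_uncorrelated_rates(self, default_calibration):
        s, cal = default_calibration
        s0 = ScenarioB(n_hospitals=50, n_per_hospital=200, re_correlation=0.0)
        corrs = []
        for rep in range(10):
            df = simulate_composite_dataset(s0, cal, seed_sequence(6, rep))
            rates = df.groupby("hospital_id")[["y1", "y2", "y3"]].mean()
            el = np.log(np.clip(rates, 1e-3, 1) / np.clip(1 - rates, 1e-3, 1))
            corrs.append(np.corrcoef(el.T)[np.triu_indices(3, 1)])
        mean_corr = np.mean(corrs, axis=0)
        assert np.all(np.abs(mean_corr) < 0.15)

    def test_determinism(self, default_calibration):
        s, cal = default_calibration
        a = simulate_composite_dataset(s, cal, 9)
        b = simulate_composite_dataset(s, cal, 9)
        pd.testing.assert_frame_equal(a, b)


class TestScenarioValidation:
    def test_correlation_pd_bound(self):
        with pytest.raises(ValueError, match="positive-definite"):
            ScenarioB(re_correlation=-0.6)

    def test_rankability_band_bound(self):
        with pytest.raises(ValueError):
            ScenarioB(target_rankabilities=(0.5, 0.6, 0.75))

    def test_icc_domain(self):
        with pytest.raises(ValueError):
            ScenarioA(icc=1.0, alpha0=0.0, alpha1=0.0)


class TestCalibrateTau:
    def test_analytic_hits_target_expectation(self):
        cal = calibrate_tau(0.4, 0.10, 0.5, 100, 500, method="analytic")
        assert cal.tau > 0
        assert cal.achieved_prevalence == pytest.approx(0.10, abs=1e-5)
        from ranklab.synthetic_data import expected_binary_rankability

        assert expected_binary_rankability(cal.tau, 0.10, 0.5, 500) == pytest.approx(0.4, abs=1e-4)

    def test_simulated_self_consistency(self):
        """Grid-search calibration reproduces its target on fresh replicates."""
        from ranklab.rankability import estimate_rankability
        from ranklab.synthetic_data import _simulate_one_binary

        for target in (0.3, 0.4, 0.5):
            cal = calibrate_tau(target, 0.10, 0.5, 100, 500, seed=100, method="simulate",
                                n_cal_reps=6)
            rhos = []
            for rep in range(8):
                rng = np.random.default_rng(seed_sequence(200, rep))
                df = _simulate_one_binary(cal.alpha0, 0.5, cal.tau, 100, 500, rng)
                rhos.append(estimate_rankability(df, "y1").rho)
            assert np.mean(rhos) == pytest.approx(target, abs=0.05)

    def test_tau_monotone_in_target(self):
        taus = [
            calibrate_tau(t, 0.25, 1.0, 50, 200, seed=5, method="analytic").tau
            for t in (0.2, 0.3, 0.4, 0.5, 0.6)
        ]
        assert np.all(np.diff(taus) > 0)

    def test_small_target_forces_small_tau(self):
        cal = calibrate_tau(0.05, 0.25, 1.0, 50, 200, method="analytic")
        assert cal.tau < 0.1


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    icc=st.floats(0.0, 0.24),
    y=st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)),
)
def test_conversion_and_composition_properties(icc, y):
    assert icc_latent(tau_from_icc(icc) ** 2) == pytest.approx(icc, abs=1e-12)
    level = compose_ordinal(*y)
    assert 1 <= level <= 5
    assert (level == 5) == (y[0] == 1)
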