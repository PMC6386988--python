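"""TP/FP classification, tolerance sweep, material rates and psychometric fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palpsim.phantom import DEFAULT_MATERIALS, Inclusion, Phantom, generate_phantom
from palpsim.psychophysics import (
    PsychometricModel,
    accuracy,
    classify_responses,
    fit_cdf,
    identification_rate_by_material,
    logistic_cdf,
    tolerance_sweep,
)

STIFFNESS_LEVELS = [2.74, 2.88, 3.68, 3.69]


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(seed=42)


class TestClassifyResponses:
    def test_response_at_center_is_tp_at_every_tolerance(self, phantom):
        c0 = phantom.inclusions[0].center_xy
        for tol in (5.0, 10.0, 15.0, 20.0):
            c = classify_responses([c0], phantom, tol)
            assert c.labels == ["TP"]
            assert c.matched_inclusion == [0]

    def test_beyond_tolerance_is_fp(self):
        ph = Phantom(inclusions=[Inclusion((50.0, 50.0), DEFAULT_MATERIALS["SC"])])
        c = classify_responses([(62.0, 50.0)], ph, 10.0)
        assert c.labels == ["FP"]
        assert c.distances[0] == pytest.approx(12.0)

    def test_exactly_at_tolerance_is_tp(self):
        ph = Phantom(inclusions=[Inclusion((50.0, 50.0), DEFAULT_MATERIALS["SC"])])
        c = classify_responses([(60.0, 50.0)], ph, 10.0)
        assert c.labels == ["TP"]

    def test_empty_phantom_all_fp(self):
        ph = Phantom()
        c = classify_responses([(10.0, 10.0), (20.0, 20.0)], ph, 10.0)
        assert c.labels == ["FP", "FP"]

    def test_counts_partition_responses(self, phantom, rng):
        pts = rng.uniform(0, 100, size=(200, 2))
        c = classify_responses(pts, phantom, 10.0)
        assert c.tp_count + c.fp_count == 200
        assert all(d <= 10.0 for d, l in zip(c.distances, c.labels) if l == "TP")

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_tp_monotone_in_tolerance_property(self, seed):
        ph = generate_phantom(seed=17)
        pts = np.random.default_rng(seed).uniform(0, 100, size=(40, 2))
        tps = [classify_responses(pts, ph, tol).tp_count
               for tol in (5.0, 10.0, 15.0, 20.0)]
        assert all(b >= a for a, b in zip(tps, tps[1:]))


class TestAccuracy:
    def test_all_tp_is_one(self, phantom):
        c = classify_responses([phantom.inclusions[0].center_xy] * 4, phantom, 10.0)
        assert accuracy(c) == 1.0

    def test_half_tp_half_fp(self):
        ph = Phantom(inclusions=[Inclusion((50.0, 50.0), DEFAULT_MATERIALS["SC"])])
        c = classify_responses([(50.0, 50.0), (10.0, 10.0)], ph, 10.0)
        assert accuracy(c) == 0.5

    def test_zero_responses_undefined(self, phantom):
        c = classify_responses([], phantom, 10.0)
        with pytest.raises(ValueError):
            accuracy(c)

    def test_literal_definition_collapses_to_one(self):
        # TP / (responses - FP) = TP / TP whenever any TP exists
        ph = Phantom(inclusions=[Inclusion((50.0, 50.0), DEFAULT_MATERIALS["SC"])])
        c = classify_responses([(50.0, 50.0), (10.0, 10.0)], ph, 10.0)
        assert accuracy(c, definition="literal") == 1.0

    def test_accuracy_always_in_unit_interval(self, phantom, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, size=(rng.integers(1, 30), 2))
            a = accuracy(classify_responses(pts, phantom, 10.0))
            assert 0.0 <= a <= 1.0


class TestToleranceSweep:
    def test_responses_at_centers_flat_tp(self, phantom):
        pts = [inc.center_xy for inc in phantom.inclusions]
        curve = tolerance_sweep([pts], phantom)
        assert curve.mean_tp == [12.0] * 4
        assert curve.mean_fp == [0.0] * 4

    def test_scattered_responses_gain_tp_with_tolerance(self, phantom, rng):
        sessions = []
        for _ in range(5):
            centers = np.array([i.center_xy for i in phantom.inclusions])
            pts = centers + rng.normal(0, 4.0, size=centers.shape)
            sessions.append(np.clip(pts, 0, 100))
        curve = tolerance_sweep(sessions, phantom)
        assert curve.mean_tp[-1] > curve.mean_tp[0]
        assert curve.mean_fp[-1] <= curve.mean_fp[0]

    def test_empty_session_list_raises(self, phantom):
        with pytest.raises(ValueError):
            tolerance_sweep([], phantom)


class TestIdentificationRate:
    def test_full_coverage_rates_one(self, phantom):
        pts = [inc.center_xy for inc in phantom.inclusions]
        rates = identification_rate_by_material([pts], phantom, 10.0)
        assert all(v["rate"] == 1.0 for v in rates.values())

    def test_no_responses_rates_zero(self, phantom):
        rates = identification_rate_by_material([[]], phantom, 10.0)
        assert all(v["rate"] == 0.0 for v in rates.values())

    def test_threshold_subject_orders_materials(self, phantom, rng):
        # a subject detecting only above 3 N/mm hits PDMS/SC, misses DS20/DS30
        sessions = []
        for _ in range(3):
            pts = [inc.center_xy for inc in phantom.inclusions
                   if inc.material.stiffness_k > 3.0]
            sessions.append(np.asarray(pts) + rng.normal(0, 1.0, (len(pts), 2)))
        rates = identification_rate_by_material(sessions, phantom, 10.0)
        assert min(rates["PDMS"]["rate"], rates["SC"]["rate"]) > max(
            rates["DS20"]["rate"], rates["DS30"]["rate"]
        )

    def test_empty_phantom_raises(self):
        with pytest.raises(ValueError):
            identification_rate_by_material([[]], Phantom(), 10.0)


def grid_search_oracle(x, y, a_grid, b_grid):
    """Brute-force least-squares minimum of the logistic CDF over a grid."""
    best = (np.inf, None, None)
    for a in a_grid:
        for b in b_grid:
            rss = float(np.sum((logistic_cdf(x, a, b) - y) ** 2))
            if rss < best[0]:
                best = (rss, a, b)
    return best


class TestFitCdf:
    def test_noiseless_recovery_to_solver_tolerance(self):
        x = np.array(STIFFNESS_LEVELS)
        y = logistic_cdf(x, 3.0, 0.3)
        fit = fit_cdf(x, y)
        assert fit.converged
        assert fit.a_thr == pytest.approx(3.0, rel=1e-6)
        assert fit.b_scale == pytest.approx(0.3, rel=1e-6)
        assert fit.rss < 1e-12

    def test_grid_search_oracle_confirms_minimum(self):
        x = np.array(STIFFNESS_LEVELS)
        y = logistic_cdf(x, 3.0, 0.3)
        rss, a_g, b_g = grid_search_oracle(
            x, y, np.linspace(2.5, 3.5, 101), np.linspace(0.05, 1.0, 96)
        )
        fit = fit_cdf(x, y)
        # the solver's optimum is at least as good as the best grid point,
        # and the grid's argmin lies at the generating parameters
        assert fit.rss <= rss + 1e-12
        assert a_g == pytest.approx(3.0, abs=0.01)
        assert b_g == pytest.approx(0.3, abs=0.01)

    def test_midpoint_identity(self):
        x = np.array(STIFFNESS_LEVELS)
        fit = fit_cdf(x, logistic_cdf(x, 3.1, 0.5))
        assert logistic_cdf(fit.a_thr, fit.a_thr, fit.b_scale) == pytest.approx(0.5)

    def test_degenerate_all_equal_rates_flagged(self):
        fit = fit_cdf(np.array(STIFFNESS_LEVELS), np.full(4, 0.5))
        assert not fit.identifiable
        assert not fit.converged

    def test_bernoulli_noise_recovery_bias_small(self):
        # 100 seeded replicates, n = 200 per stimulus level
        x = np.array(STIFFNESS_LEVELS)
        p = logistic_cdf(x, 3.0, 0.3)
        a_hats = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            rates = rng.binomial(200, p) / 200
            a_hats.append(fit_cdf(x, rates).a_thr)
        assert abs(np.mean(a_hats) - 3.0) < 0.1

    def test_recovery_bias_shrinks_with_n(self):
        x = np.array(STIFFNESS_LEVELS)
        p = logistic_cdf(x, 3.0, 0.3)
        bias = {}
        for n in (50, 200, 1000):
            a_hats = []
            for rep in range(60):
                rng = np.random.default_rng(7000 + rep)
                rates = rng.binomial(n, p) / n
                a_hats.append(fit_cdf(x, rates).a_thr)
            bias[n] = abs(np.mean(a_hats) - 3.0)
        assert bias[1000] <= bias[50] + 0.01

    def test_model_input_validation(self):
        with pytest.raises(ValueError):
            PsychometricModel([3.0, 3.0], [0.2, 0.8])
        with pytest.raises(ValueError):
            PsychometricModel([2.0, 3.0], [0.2, 1.8])

    def test_summary_reports_estimates(self):
        x = np.array(STIFFNESS_LEVELS)
        fit = fit_cdf(x, logistic_cdf(x, 3.0, 0.3))
        s = fit.summary()
        assert "a (threshold)" in s and "3.0000" in s
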