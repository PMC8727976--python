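import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventsplit as v
from ventsplit import reference as ref
from ventsplit.errors import DomainError, FitError


def noiseless_set(a, b, flows, diameter=None):
    law_drops = a * flows ** 2 + b * flows
    return v.MeasurementSet(flows=flows, pressure_drops=law_drops,
                            diameter=diameter)


class TestFitQuadraticLaw:
    def test_exact_recovery_from_noiseless_data(self, bench_flows):
        fit = v.fit_quadratic_law(noiseless_set(0.22444, 0.88262, bench_flows))
        assert fit.a == pytest.approx(0.22444, rel=1e-6)
        assert fit.b == pytest.approx(0.88262, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_three_se(self, laws, bench_flows):
        data = v.gen_bench_measurements(laws[2.0], bench_flows, 10,
                                        v.BenchNoiseModel(seed=11))
        fit = v.fit_quadratic_law(data)
        assert abs(fit.a - 0.22444) < 3 * fit.standard_errors[0]
        assert abs(fit.b - 0.88262) < 3 * fit.standard_errors[1]
        assert fit.r_squared >= 0.99

    def test_pure_linear_law_recovers_zero_quadratic_term(self, bench_flows):
        data = v.gen_bench_measurements(
            v.RestrictorLaw(diameter=None, a=0.0, b=0.5), bench_flows, 10,
            v.BenchNoiseModel(seed=5))
        fit = v.fit_quadratic_law(data)
        assert abs(fit.a) < 3 * fit.standard_errors[0]

    def test_nonnegative_constraint_clips_and_refits(self):
        flows = np.array([1.0, 2.0, 3.0, 4.0])
        # slightly concave data that pushes the quadratic term negative
        drops = np.array([1.1, 2.0, 2.8, 3.5])
        unconstrained = v.fit_quadratic_law(
            v.MeasurementSet(flows=flows, pressure_drops=drops))
        assert unconstrained.a < 0
        constrained = v.fit_quadratic_law(
            v.MeasurementSet(flows=flows, pressure_drops=drops),
            constrain_nonnegative=True)
        assert constrained.a == 0.0
        assert constrained.b > 0

    def test_scale_equivariance(self, bench_flows):
        base = noiseless_set(0.04, 0.26, bench_flows)
        scaled = v.MeasurementSet(flows=bench_flows,
                                  pressure_drops=3.0 * base.pressure_drops)
        f1 = v.fit_quadratic_law(base)
        f2 = v.fit_quadratic_law(scaled)
        assert f2.a == pytest.approx(3.0 * f1.a, rel=1e-9)
        assert f2.b == pytest.approx(3.0 * f1.b, rel=1e-9)

    def test_too_few_distinct_flows(self):
        with pytest.raises(FitError):
            v.fit_quadratic_law(v.MeasurementSet(
                flows=np.array([5.0, 5.0, 5.0, 5.0]),
                pressure_drops=np.array([1.0, 1.1, 0.9, 1.0])))

    def test_bootstrap_agrees_with_analytic_se(self, laws, bench_flows):
        data = v.gen_bench_measurements(laws[2.0], bench_flows, 10,
                                        v.BenchNoiseModel(seed=21))
        fit = v.fit_quadratic_law(data)
        boot = v.bootstrap_standard_errors(data, n_boot=200, seed=22)
        assert boot[0] == pytest.approx(fit.standard_errors[0], rel=0.35)
        assert boot[1] == pytest.approx(fit.standard_errors[1], rel=0.35)

    def test_one_se_coverage_near_nominal(self, laws, bench_flows):
        # +/-1 SE intervals should cover the truth ~68% of the time; with
        # 100 replicates the binomial 99% band is roughly [55, 80]
        law = laws[2.0]
        hits_a = hits_b = 0
        n = 100
        for seed in range(n):
            data = v.gen_bench_measurements(law, bench_flows, 10,
                                            v.BenchNoiseModel(seed=seed))
            fit = v.fit_quadratic_law(data)
            hits_a += abs(fit.a - law.a) <= fit.standard_errors[0]
            hits_b += abs(fit.b - law.b) <= fit.standard_errors[1]
        assert 55 <= hits_a <= 80
        assert 55 <= hits_b <= 80


class TestFitPowerLaws:
    def test_reference_coefficients_reproduce_published_model(self, laws):
        model = v.fit_power_laws(
            (d, law.a, law.b) for d, law in laws.items() if d is not None)
        assert model.k_a == pytest.approx(3.55, rel=0.01)
        assert model.m_a == pytest.approx(-4.03, rel=0.01)
        assert model.k_b == pytest.approx(10.27, rel=0.01)
        assert model.m_b == pytest.approx(-3.46, rel=0.01)

    @settings(derandomize=True, max_examples=25)
    @given(k_a=st.floats(0.5, 10), m_a=st.floats(-5, -1),
           k_b=st.floats(0.5, 20), m_b=st.floats(-5, -1))
    def test_exact_round_trip_from_generated_power_law(self, k_a, m_a, k_b,
                                                       m_b):
        model = v.PowerLawModel(k_a=k_a, m_a=m_a, k_b=k_b, m_b=m_b)
        triples = [(d, model.k_a * d ** model.m_a, model.k_b * d ** model.m_b)
                   for d in (2.0, 2.5, 3.0, 3.5, 4.0)]
        refit = v.fit_power_laws(triples)
        assert refit.k_a == pytest.approx(model.k_a, rel=1e-9)
        assert refit.m_a == pytest.approx(model.m_a, abs=1e-9)
        assert refit.k_b == pytest.approx(model.k_b, rel=1e-9)
        assert refit.m_b == pytest.approx(model.m_b, abs=1e-9)

    def test_two_points_interpolate_exactly(self):
        model = v.fit_power_laws([(2.0, 0.2, 0.9), (4.0, 0.0125, 0.1)])
        assert model.k_a * 2.0 ** model.m_a == pytest.approx(0.2, rel=1e-9)
        assert model.k_a * 4.0 ** model.m_a == pytest.approx(0.0125, rel=1e-9)

    def test_nonpositive_coefficients_rejected(self):
        with pytest.raises(DomainError):
            v.fit_power_laws([(2.0, 0.2, 0.9), (4.0, 0.0, 0.1)])


class TestEffectiveDiameter:
    def test_reference_2mm_coefficient_maps_to_2mm(self, power_model):
        assert v.effective_diameter(0.22444, power_model) == pytest.approx(
            2.0, rel=0.01)

    def test_unit_diameter_when_a_equals_prefactor(self, power_model):
        assert v.effective_diameter(power_model.k_a,
                                    power_model) == pytest.approx(1.0)

    def test_end_to_end_recovery_of_undersized_bore(self, power_model,
                                                    bench_flows):
        true_d = 1.69
        law = v.RestrictorLaw(
            diameter=2.0,
            a=power_model.k_a * true_d ** power_model.m_a,
            b=power_model.k_b * true_d ** power_model.m_b)
        data = v.gen_bench_measurements(law, bench_flows, 10,
                                        v.BenchNoiseModel(seed=7))
        fit = v.fit_quadratic_law(data)
        estimate = v.effective_diameter_from_fit(fit, power_model)
        assert estimate == pytest.approx(true_d, rel=0.03)

    def test_nonpositive_a_rejected(self, power_model):
        with pytest.raises(DomainError):
            v.effective_diameter(0.0, power_model)


class TestMeasurementSetCsv:
    def test_round_trip_preserves_metadata(self, tmp_path, laws, bench_flows):
        data = v.gen_bench_measurements(laws[3.0], bench_flows, 4,
                                        v.BenchNoiseModel(seed=1))
        path = tmp_path / "bench.csv"
        data.to_csv(path)
        back = v.MeasurementSet.from_csv(path)
        assert back.diameter == 3.0
        assert back.replicate_count == 4
        assert np.allclose(back.flows, data.flows)
        assert np.allclose(back.pressure_drops, data.pressure_drops)
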