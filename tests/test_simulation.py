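import numpy as np
import pytest

import ventsplit as v
from ventsplit import reference as ref
from ventsplit.errors import ConfigurationError
from ventsplit.simulation import _solve_branch_flow

from conftest import make_branch


class TestImplicitFlowSolve:
    def test_zero_rhs_zero_flow(self, laws):
        assert _solve_branch_flow(0.0, 35.0, laws[2.0], 1e-9, 60) == 0.0

    def test_identity_law_closed_form(self):
        q = _solve_branch_flow(25.0, 35.44, v.RestrictorLaw.identity(),
                               1e-9, 60)
        assert q == pytest.approx(25.0 / 35.44, rel=1e-9)

    @pytest.mark.parametrize("rhs", [0.5, 5.0, 25.0, -10.0])
    def test_residual_vanishes_at_solution(self, laws, rhs):
        law = laws[2.0]
        stiffness = 35.44
        q = _solve_branch_flow(rhs, stiffness, law, 1e-12, 80)
        resid = stiffness * q + v.quadratic_pressure_drop(law, 60 * q) - rhs
        assert abs(resid) < 1e-8

    def test_negative_rhs_gives_negative_flow(self, laws):
        q = _solve_branch_flow(-5.0, 35.44, laws[3.0], 1e-10, 60)
        assert q < 0


class TestSimulateBranch:
    def test_matches_analytic_oracle_without_restrictor(
            self, step_waveform, compliant_patient, circuit):
        branch = v.BranchConfig(label="u", patient=compliant_patient,
                                circuit=circuit)
        result = v.simulate_branch(step_waveform, branch)
        analytic = np.array([
            v.step_response_volume(25.0, float(t), compliant_patient, circuit)
            for t in result.times])
        assert np.max(np.abs(result.volumes - analytic)) < 1e-6
        assert result.end_inspiratory_volume == pytest.approx(0.8084, abs=1e-4)

    def test_waveform_at_peep_gives_no_flow(self, compliant_patient, circuit):
        w = v.PressureWaveform(times=np.linspace(0, 1.25, 100),
                               pressures=np.full(100, 5.0), baseline=5.0)
        branch = v.BranchConfig(label="u", patient=compliant_patient,
                                circuit=circuit)
        result = v.simulate_branch(w, branch)
        assert np.all(result.flows == 0.0)
        assert np.all(result.volumes == 0.0)

    def test_restrictor_reduces_delivered_volume(self, step_waveform, laws):
        unrestricted = make_branch("u", 0.1)
        restricted = make_branch("r", 0.1, laws[2.0])
        v_u = v.simulate_branch(step_waveform, unrestricted)
        v_r = v.simulate_branch(step_waveform, restricted)
        assert v_r.end_inspiratory_volume < v_u.end_inspiratory_volume

    def test_summary_fields_consistent_with_series(self, step_waveform, laws):
        result = v.simulate_branch(step_waveform, make_branch("r", 0.1, laws[3.0]))
        assert result.peak_flow == np.max(result.flows)
        assert result.peak_pressure_drop == np.max(result.restrictor_drops)
        assert result.end_inspiratory_volume == result.volumes[-1]

    def test_volumes_non_decreasing_during_inspiration(self, step_waveform, laws):
        result = v.simulate_branch(step_waveform, make_branch("r", 0.1, laws[2.0]))
        assert np.all(np.diff(result.volumes) >= 0)

    def test_restrictor_only_dissipates(self, laws):
        # drop * flow >= 0 sample-by-sample, even with a rising waveform
        w = v.build_waveform(v.VentilatorSettings(rise_time=0.2), dt=1e-3)
        result = v.simulate_branch(w, make_branch("r", 0.1, laws[2.0]))
        assert np.all(result.restrictor_drops * result.flows >= 0)

    def test_volume_is_trapezoidal_integral_of_flow(self, step_waveform, laws):
        result = v.simulate_branch(step_waveform, make_branch("r", 0.1, laws[3.0]))
        integral = np.concatenate([
            [0.0],
            np.cumsum(0.5 * np.diff(result.times)
                      * (result.flows[1:] + result.flows[:-1]) / 60.0)])
        assert np.max(np.abs(result.volumes - integral)) < 1e-6

    def test_halving_dt_changes_end_volume_below_tenth_percent(self, laws):
        settings = v.VentilatorSettings()
        branch = make_branch("r", 0.1, laws[2.0])
        vols = []
        for dt in (1e-3, 5e-4):
            w = v.build_waveform(settings, dt)
            r = v.simulate_branch(w, branch, solver=v.SolverOptions(dt=dt))
            vols.append(r.end_inspiratory_volume)
        assert abs(vols[1] - vols[0]) / vols[0] < 1e-3


class TestSimulateSplitter:
    def test_unrestricted_branch_invariant_to_partner_restrictor(
            self, step_waveform, laws):
        stiff = make_branch("unrestricted", 0.2)
        ends = set()
        for d in (2.0, 3.0, 4.0, None):
            restricted = make_branch("restricted", 0.1, laws[d])
            results, _ = v.simulate_splitter(step_waveform,
                                             (restricted, stiff))
            ends.add(results[1].end_inspiratory_volume)
        assert len(ends) == 1

    def test_symmetric_branches_identical(self, step_waveform):
        b1 = make_branch("left", 0.1)
        b2 = make_branch("right", 0.1)
        results, _ = v.simulate_splitter(step_waveform, (b1, b2))
        assert np.allclose(results[0].volumes, results[1].volumes)
        assert np.allclose(results[0].flows, results[1].flows)

    def test_end_volume_increases_with_restrictor_diameter(
            self, step_waveform, laws):
        # the qualitative pattern of the published volume rows
        ends = []
        for d in (2.0, 3.0, 4.0, None):
            results, _ = v.simulate_splitter(
                step_waveform,
                (make_branch("restricted", 0.1, laws[d]),
                 make_branch("unrestricted", 0.2)))
            ends.append(results[0].end_inspiratory_volume)
        assert all(a < b for a, b in zip(ends, ends[1:]))

    def test_summary_table_layout(self, step_waveform, laws):
        _, summary = v.simulate_splitter(
            step_waveform, (make_branch("restricted", 0.1, laws[4.0]),
                            make_branch("unrestricted", 0.2)))
        assert list(summary["branch"]) == ["restricted", "unrestricted"]
        assert {"peak_drop_cmH2O", "peak_flow_Lmin",
                "end_inspiratory_volume_L"} <= set(summary.columns)

    def test_duplicate_labels_rejected(self, step_waveform):
        with pytest.raises(ConfigurationError):
            v.simulate_splitter(step_waveform, (make_branch("x", 0.1),
                                                make_branch("x", 0.2)))

    def test_common_resistance_couples_branches(self, step_waveform, laws):
        stiff = make_branch("unrestricted", 0.2)
        restricted_small = make_branch("restricted", 0.1, laws[2.0])
        restricted_none = make_branch("restricted", 0.1)
        r_small, _ = v.simulate_splitter(step_waveform,
                                         (restricted_small, stiff),
                                         common_resistance=2.0)
        r_none, _ = v.simulate_splitter(step_waveform,
                                        (restricted_none, stiff),
                                        common_resistance=2.0)
        # with a shared upstream drop, choking one branch raises the node
        # pressure and the partner's delivered volume
        assert (r_small[1].end_inspiratory_volume
                > r_none[1].end_inspiratory_volume)

    def test_zero_common_resistance_matches_independent(self, step_waveform,
                                                        laws):
        pair = (make_branch("restricted", 0.1, laws[3.0]),
                make_branch("unrestricted", 0.2))
        independent, _ = v.simulate_splitter(step_waveform, pair)
        coupled, _ = v.simulate_splitter(step_waveform, pair,
                                         common_resistance=1e-9)
        assert independent[0].end_inspiratory_volume == pytest.approx(
            coupled[0].end_inspiratory_volume, abs=1e-6)
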