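import math

import numpy as np
import pytest

from kvinact import (
    GatingModel,
    GlycoformMixture,
    MissingSweepError,
    NoPeakAboveLevelError,
    UnanalysableSweepError,
    extract_target_sweep,
    inac_width,
    measure_cell,
    measure_cohort,
    normalize_trace,
    overlay_matrix,
    simulate_cell,
    make_protocol,
)
from kvinact.gating import inactivation_survival
from conftest import ZERO_NOISE, single_component_mixture


def ideal_trace(tau=50.0, onset=100.0, fs_khz=10.0, t_end=600.0):
    """Instant rise at `onset` to 1, exponential decay with time constant tau."""
    t = np.arange(0.0, t_end, 1.0 / fs_khz)
    y = np.where(t < onset, 0.0, np.exp(-(t - onset) / tau))
    return t, y


class TestExtractTargetSweep:
    def test_default_returns_plus80_sweep(self, tiny_protocol):
        cell = simulate_cell(single_component_mixture(), tiny_protocol, ZERO_NOISE)
        t, trace = extract_target_sweep(cell)
        np.testing.assert_array_equal(trace, cell.sweeps[80.0])

    def test_holding_level_sweep_returned_unchanged(self, tiny_protocol):
        cell = simulate_cell(single_component_mixture(), tiny_protocol, ZERO_NOISE)
        _, trace = extract_target_sweep(cell, 0.0)
        np.testing.assert_array_equal(trace, cell.sweeps[0.0])

    def test_absent_potential_error_lists_available_steps(self, tiny_protocol):
        cell = simulate_cell(single_component_mixture(), tiny_protocol, ZERO_NOISE)
        with pytest.raises(MissingSweepError, match=r"80\.0"):
            extract_target_sweep(cell, 75.0)


class TestNormalizeTrace:
    def test_scale_invariance(self):
        t, y = ideal_trace()
        _, n1, i1 = normalize_trace(t, 100.0 * y)
        _, n3, i3 = normalize_trace(t, 300.0 * y)
        np.testing.assert_allclose(n1, n3, atol=1e-12)
        assert i3 == pytest.approx(3.0 * i1)
        assert n1.max() == 1.0

    def test_constant_positive_sweep_normalizes_to_one(self):
        t = np.arange(0.0, 600.0, 0.1)
        _, norm, i_max = normalize_trace(t, np.full_like(t, 42.0))
        assert np.all(norm == 1.0) and i_max == 42.0

    @pytest.mark.parametrize("value", [0.0, -5.0])
    def test_nonpositive_peak_is_unanalysable(self, value):
        t = np.arange(0.0, 600.0, 0.1)
        with pytest.raises(UnanalysableSweepError):
            normalize_trace(t, np.full_like(t, value))

    def test_peak_matches_forward_model_oracle(self):
        # noise-free simulated sweep: in-window peak must equal
        # g_max * max(P_open) * (V - E_K) on the same grid
        proto = make_protocol(step_potentials=[80.0])
        model = GatingModel(g_max=100.0, k=4, lam=0.02, tau_m=2.0)
        cell = simulate_cell(GlycoformMixture.single(model), proto, ZERO_NOISE)
        t, trace = extract_target_sweep(cell)
        _, _, i_max = normalize_trace(t, trace)
        step_t = t[t >= proto.step_onset] - proto.step_onset
        minf = float(model.m_inf(80.0))
        m0 = float(model.m_inf(-90.0))
        m = minf + (m0 - minf) * np.exp(-step_t / model.tau_m)
        p_open = m**model.p * inactivation_survival(step_t, model.k, model.lam)
        expected = model.g_max * p_open.max() * (80.0 - model.e_k)
        assert i_max == pytest.approx(expected, rel=1e-9)

    def test_window_must_fit_sweep(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(Exception, match="window"):
            normalize_trace(t, np.ones_like(t), window=(70.0, 599.0))


class TestInacWidth:
    def test_ideal_exponential_width_matches_closed_form(self):
        t, y = ideal_trace(tau=50.0)
        t_win, norm, _ = normalize_trace(t, y)
        m = inac_width(t_win, norm)
        assert m.inac_width == pytest.approx(50.0 * math.log(1 / 0.7), abs=0.2)
        assert not m.censored

    def test_non_inactivating_trace_censored_at_window_end(self):
        t = np.arange(0.0, 600.0, 0.1)
        y = np.where(t < 100.0, 0.0, 1.0)
        t_win, norm, _ = normalize_trace(t, y)
        m = inac_width(t_win, norm)
        assert m.censored
        assert m.inac_width == pytest.approx(599.0 - m.t_up, abs=1e-9)

    def test_translation_equivariance(self):
        t, y = ideal_trace(onset=100.0)
        _, y30 = ideal_trace(onset=130.0)
        m0 = inac_width(*normalize_trace(t, y)[:2])
        m30 = inac_width(*normalize_trace(t, y30)[:2])
        assert m30.t_up == pytest.approx(m0.t_up + 30.0, abs=0.01)
        assert m30.inac_width == pytest.approx(m0.inac_width, abs=0.01)

    def test_trace_starting_above_level_takes_window_start(self):
        t = np.arange(70.0, 599.05, 0.1)
        y = np.exp(-(t - 70.0) / 100.0)  # already at peak when window opens
        m = inac_width(t, y / y.max())
        assert m.t_up == 70.0

    def test_never_reaching_level_raises(self):
        t = np.arange(70.0, 599.05, 0.1)
        with pytest.raises(NoPeakAboveLevelError):
            inac_width(t, np.full_like(t, 0.5))

    def test_first_up_last_down_bridges_noise_dips(self):
        t = np.arange(70.0, 599.05, 0.1)
        y = np.where((t > 100) & (t < 400), 1.0, 0.0)
        y[(t > 200) & (t < 210)] = 0.2  # brief dip below level
        m = inac_width(t, y)
        assert m.inac_width == pytest.approx(300.0, abs=0.2)
        assert m.n_level_crossings == 4

    def test_lowering_level_never_decreases_width(self):
        proto = make_protocol(step_potentials=[80.0])
        cell = simulate_cell(single_component_mixture(k=4, mean_latency_ms=150.0),
                             proto, ZERO_NOISE)
        widths = [
            measure_cell(cell, level=level).inac_width
            for level in (0.9, 0.7, 0.5, 0.3)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(widths, widths[1:]))

    def test_width_monotone_in_mean_docking_delay(self):
        proto = make_protocol(step_potentials=[80.0])
        widths = []
        for mean in (20.0, 60.0, 120.0, 240.0):
            cell = simulate_cell(single_component_mixture(k=4, mean_latency_ms=mean),
                                 proto, ZERO_NOISE)
            widths.append(measure_cell(cell).inac_width)
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_measured_width_matches_analytic_open_probability(self):
        # noise-free single-component simulation vs the width computed on a
        # dense analytic P_open curve: sub-sample agreement
        proto = make_protocol(step_potentials=[80.0])
        model = GatingModel(g_max=80.0, k=6, lam=0.05, tau_m=2.0)
        cell = simulate_cell(GlycoformMixture.single(model), proto, ZERO_NOISE)
        measured = measure_cell(cell).inac_width

        t_dense = np.arange(70.0, 599.0005, 0.001)
        step_t = np.clip(t_dense - proto.step_onset, 0.0, None)
        minf = float(model.m_inf(80.0))
        m0 = float(model.m_inf(-90.0))
        m = minf + (m0 - minf) * np.exp(-step_t / model.tau_m)
        m[t_dense < proto.step_onset] = m0
        p = m**model.p * inactivation_survival(step_t, model.k, model.lam)
        analytic = inac_width(t_dense, p / p.max()).inac_width
        assert measured == pytest.approx(analytic, abs=0.2)


class TestCohortMeasurement:
    def test_unanalysable_cells_reported_not_raised(self, tiny_protocol):
        good = simulate_cell(single_component_mixture(), tiny_protocol, ZERO_NOISE,
                             cell_id="good")
        dead = simulate_cell(single_component_mixture(g_max=0.0), tiny_protocol,
                             ZERO_NOISE, cell_id="dead")
        window = (5.0, 59.0)
        table, failures = measure_cohort([good, dead], window=window)
        assert list(table["cell_id"]) == ["good"]
        assert "dead" in failures

    def test_overlay_matrix_shape_and_normalization(self, plus80_protocol):
        cells = [
            simulate_cell(single_component_mixture(mean_latency_ms=m), plus80_protocol,
                          ZERO_NOISE, cell_id=f"c{m:.0f}")
            for m in (30.0, 90.0)
        ]
        overlay = overlay_matrix(cells)
        assert list(overlay.columns) == ["c30", "c90"]
        assert overlay.index[0] == pytest.approx(70.0)
        assert overlay.index[-1] == pytest.approx(599.0)
        np.testing.assert_allclose(overlay.max(axis=0), 1.0)
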