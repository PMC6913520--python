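"""Monodomain cable physics, pseudo-ECG sign rules and mechanism scenarios."""

import numpy as np
import pytest

from hcmecg.simulation import (CableState, CellScaling, SimulationError,
                               Stimulus, TissueConfig, V_REST_MV,
                               apply_ionic_remodeling, conduction_velocity,
                               pseudo_ecg, run_scenario, simulate_cable,
                               single_cell_apd90)


def test_resting_equilibrium_without_stimulus():
    cfg = TissueConfig(stim_sites=[])
    st = simulate_cable(cfg, duration_ms=100.0)
    assert np.max(np.abs(st.vm - V_REST_MV)) < 1.0


def test_planar_propagation_and_cv_constancy(baseline_cable):
    st = baseline_cable
    at = st.activation_time_ms
    assert not np.isnan(at).any()
    # strictly increasing along the propagation path (nodes under the
    # stimulus electrode itself fire simultaneously)
    beyond = st.x_mm > 2.0
    assert np.all(np.diff(at[beyond]) > 0)
    # CV constant within 5% over the middle half
    x = st.x_mm
    mid = (x >= 0.25 * x.max()) & (x <= 0.75 * x.max())
    local_cv = np.diff(x[mid]) / np.diff(at[mid])
    cv = conduction_velocity(st)
    assert np.max(np.abs(local_cv - cv) / cv) < 0.05


def test_cv_scales_as_sqrt_d(baseline_cable):
    cv1 = conduction_velocity(baseline_cable)
    cfg = TissueConfig(diffusion_mm2_per_ms=0.3 / 4.0)
    cv2 = conduction_velocity(simulate_cable(cfg, duration_ms=400.0))
    assert cv2 / cv1 == pytest.approx(0.5, rel=0.10)


def test_numerical_convergence_under_refinement(baseline_cable):
    cv1 = conduction_velocity(baseline_cable)
    fine = TissueConfig(diffusion_mm2_per_ms=0.3, dx_mm=0.125)
    cv2 = conduction_velocity(simulate_cable(fine, duration_ms=250.0,
                                             dt_ms=0.005))
    assert abs(cv2 - cv1) / cv1 < 0.02


def test_stability_bound_error_names_limit():
    cfg = TissueConfig(diffusion_mm2_per_ms=0.3)
    with pytest.raises(SimulationError, match="stability bound"):
        simulate_cable(cfg, duration_ms=10.0, dt_ms=0.2)


def test_remodeling_identity_and_validation():
    cfg = TissueConfig()
    same = apply_ionic_remodeling(cfg, (10.0, 20.0), CellScaling())
    assert same.remodeling == []
    with pytest.raises(ValueError):
        CellScaling(s_K=0.0)
    with pytest.raises(ValueError):
        apply_ionic_remodeling(cfg, (40.0, 60.0), CellScaling(s_K=0.5))


def test_regional_remodeling_prolongs_apd():
    """APD90 inside the remodeled region exceeds APD90 away from it.

    Nodes within a few space constants of the region border are excluded:
    electrotonic load there blurs the cellular APD step."""
    cfg = TissueConfig(diffusion_mm2_per_ms=0.3, apd_gradient=(1.25, 0.75))
    cfg = apply_ionic_remodeling(cfg, (30.0, 50.0),
                                 CellScaling(s_NaL=2.0, s_CaL=1.1, s_K=0.5))
    st = simulate_cable(cfg, duration_ms=900.0)
    inside = (st.x_mm >= 35.0) & (st.x_mm <= 50.0)
    outside = st.x_mm <= 25.0
    assert np.nanmin(st.apd90_ms[inside]) > np.nanmax(st.apd90_ms[outside])


def test_single_cell_apd_monotone_in_potassium():
    apds = [single_cell_apd90(CellScaling(s_K=sk))
            for sk in (1.4, 1.2, 1.0, 0.8, 0.6)]
    assert all(b > a for a, b in zip(apds, apds[1:]))


def test_single_cell_apd_monotone_in_inward_currents():
    base = single_cell_apd90(CellScaling())
    assert single_cell_apd90(CellScaling(s_NaL=2.0)) > base
    assert single_cell_apd90(CellScaling(s_CaL=1.5)) > base


def test_pseudo_ecg_zero_for_uniform_vm():
    x = np.arange(0, 50.25, 0.25)
    vm = np.tile(np.linspace(-84.0, 20.0, 40), (x.size, 1))
    st = CableState(x, np.arange(40.0), vm,
                    np.zeros(x.size), np.full(x.size, 200.0))
    ecg = pseudo_ecg(st, 70.0)
    np.testing.assert_allclose(ecg.trace, 0.0, atol=1e-12)


def test_pseudo_ecg_electrode_must_be_outside():
    x = np.arange(0, 50.25, 0.25)
    st = CableState(x, np.arange(3.0), np.zeros((x.size, 3)),
                    np.zeros(x.size), np.zeros(x.size))
    with pytest.raises(ValueError, match="outside"):
        pseudo_ecg(st, 25.0)


def _step_front_state(position_mm, x):
    """Idealized step front: depolarized behind `position_mm`."""
    vm = np.where(x[:, None] < position_mm, 20.0, -84.0)
    return CableState(x, np.arange(1.0), vm, np.zeros(x.size),
                      np.zeros(x.size))


def test_front_direction_sign_rule_matches_analytic_oracle():
    """phi = -K sum Vm' d(1/r)/dx dx: for a step front at x0 the integral
    collapses to +A/r(x0)^2 toward the electrode, -A/r(x0)^2 away."""
    x = np.arange(0, 50.25, 0.25)
    st = _step_front_state(25.0, x)
    toward = pseudo_ecg(st, 70.0).trace[0]      # front moving toward +x side
    away = pseudo_ecg(st, -20.0).trace[0]       # same field, electrode behind
    amp = 104.0
    assert toward == pytest.approx(amp / 45.0 ** 2, rel=0.05)
    assert away == pytest.approx(-amp / 45.0 ** 2, rel=0.05)


def test_pseudo_ecg_superposition_of_disjoint_episodes():
    rng = np.random.default_rng(0)
    x = np.arange(0, 50.25, 0.25)
    base = np.full((x.size, 40), V_REST_MV)
    a = base.copy()
    a[:, 5:15] += rng.random((x.size, 10)) * 50
    b = base.copy()
    b[:, 25:35] += rng.random((x.size, 10)) * 50
    combined = a + b - base
    st = lambda vm: CableState(x, np.arange(40.0), vm, np.zeros(x.size),
                               np.zeros(x.size))
    tr = pseudo_ecg(st(combined), 70.0).trace
    np.testing.assert_allclose(
        tr, pseudo_ecg(st(a), 70.0).trace + pseudo_ecg(st(b), 70.0).trace
        - pseudo_ecg(st(base), 70.0).trace, atol=1e-9)


def test_unknown_scenario_lists_names():
    with pytest.raises(KeyError, match="baseline"):
        run_scenario("nope")


def test_baseline_scenario_shape(scenario_results):
    state, ecg, s = scenario_results["baseline"]
    assert s["t_like_sign"] == +1          # concordant upright T
    assert ecg.trace.max() > 0             # main deflection positive
    assert s["terminal_deflection_depth"] > 0  # followed by a negative phase


def test_purkinje_decoupling_late_activation_and_deep_s(scenario_results):
    base = scenario_results["baseline"][2]
    purk = scenario_results["purkinje_decoupled"][2]
    assert purk["latest_activation_ms"] > base["latest_activation_ms"]
    depths = {n: r[2]["terminal_deflection_depth"]
              for n, r in scenario_results.items()}
    assert max(depths, key=depths.get) == "purkinje_decoupled"
    assert purk["t_like_sign"] == base["t_like_sign"]  # no T inversion


def test_slow_conduction_broadens_but_no_deep_s(scenario_results):
    base = scenario_results["baseline"][2]
    slow = scenario_results["slow_conduction"][2]
    purk = scenario_results["purkinje_decoupled"][2]
    assert slow["qrs_like_duration_ms"] > base["qrs_like_duration_ms"]
    assert slow["terminal_deflection_depth"] < purk["terminal_deflection_depth"]


def test_ionic_remodeling_flips_t_with_preserved_qrs(scenario_results):
    base = scenario_results["baseline"][2]
    ion = scenario_results["ionic_remodeling"][2]
    assert ion["t_like_sign"] == -base["t_like_sign"]
    rel = abs(ion["qrs_like_duration_ms"] - base["qrs_like_duration_ms"]) \
        / base["qrs_like_duration_ms"]
    assert rel < 0.10
    # the dissociation: only the remodeling scenario inverts the T
    flips = [n for n, r in scenario_results.items()
             if r[2]["t_like_sign"] != base["t_like_sign"]]
    assert flips == ["ionic_remodeling"]
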