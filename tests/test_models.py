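"""Signaling models: steady states, dose-response, potency extraction."""

import numpy as np
import pytest

from tethersim.fixtures import generate_fixture
from tethersim.models import (
    PD1Model,
    PushPullModel,
    dose_response,
    extract_half_max,
    fit_hill,
    relaxation_time,
    steady_state_fraction,
)


def test_table_defaults_molecule_counts():
    fx = generate_fixture("pushpull-micro")
    m = fx.objects["model"]
    w_species = m.species()
    dom = m.domain()
    counts = {s.name: round(s.initial_concentration * dom.measure) for s in w_species}
    assert counts["S"] == fx.expected["S_total"]
    assert counts["F"] == fx.expected["F"]
    assert counts["E"] == fx.expected["E"]


def test_relaxation_time_regimes():
    fast = PushPullModel(D_S=0.1, D_E=0.1, L_e=1.0)
    slow = PushPullModel(D_S=1.25e-6, D_E=1.25e-6, L_e=1.0)
    rf, rb = fast.forward_backward_rates()
    assert relaxation_time(fast) == pytest.approx(1 / (rf + rb), rel=0.5)
    # at slow diffusion the quenched correction dominates
    assert relaxation_time(slow) > 5 * relaxation_time(fast)


def test_no_inhibitor_gives_full_phosphorylation():
    m = PD1Model(D=0.05, pd1_concentration=0.0, L=8.5, voxels_per_axis=32)
    r = steady_state_fraction(m, 40, 3, t_end=80.0)
    assert r.fraction > 0.999


def test_no_phosphorylation_rate_gives_zero():
    m = PD1Model(D=0.05, lam=0.0, pd1_concentration=2e-4, L=8.5, voxels_per_axis=32)
    r = steady_state_fraction(m, 20, 3, t_end=20.0)
    assert r.fraction == 0.0


def test_well_mixed_mean_field_balance():
    """At fast diffusion the fraction matches lam/(lam + k_RL [PD-1])."""
    m = PD1Model(D=0.1, pd1_concentration=7.4e-5, L=8.5, voxels_per_axis=32)
    _, rb = m.forward_backward_rates()
    expected = m.lam / (m.lam + rb)
    r = steady_state_fraction(m, 300, 17)
    assert abs(r.fraction - expected) < 0.03 + 3 * r.sem


def test_pushpull_boundary_cases():
    zero_e = PushPullModel(kinase_concentration=0.0, D_S=0.05, D_E=0.05,
                           voxels_per_axis=32)
    r = steady_state_fraction(zero_e, 20, 5, t_end=30.0)
    assert r.fraction == 0.0
    zero_f = PushPullModel(phosphatase_concentration=0.0, D_S=0.05, D_E=0.05,
                           voxels_per_axis=32)
    r = steady_state_fraction(zero_f, 20, 5, t_end=200.0)
    assert r.fraction > 0.99


def test_half_max_exact_on_clean_hill_curve():
    c = np.geomspace(0.5, 200, 16)
    f = 1.0 / (1.0 + c / 10.0)
    c50, iso, bracket = extract_half_max(c, f, "decreasing", 1.0)
    assert c50 == pytest.approx(10.0, rel=0.02)
    assert bracket[0] <= 10.0 <= bracket[1]


def test_half_max_activator_mirror():
    c = np.geomspace(0.5, 200, 16)
    f = (c / 10.0) / (1.0 + c / 10.0)
    c50, _, _ = extract_half_max(c, f, "increasing", 1.0)
    assert c50 == pytest.approx(10.0, rel=0.02)


def test_half_max_out_of_range_reports_bracket():
    c = np.geomspace(1, 10, 6)
    f = 0.9 - 0.01 * np.log(c)  # never crosses 0.5
    c50, _, bracket = extract_half_max(c, f, "decreasing", 1.0)
    assert c50 is None
    assert bracket == (1.0, 10.0)


def test_half_max_recovery_under_noise():
    """1% additive noise: interpolation recovers c50 to ~2.5% on average and
    the Hill-fit cross-check to <5% in every replicate."""
    fx = generate_fixture("hill-curve", seed=0)
    rng = np.random.default_rng(123)
    interp_errs, hill_errs = [], []
    c = fx.objects["concentrations"]
    c0 = fx.expected["c50"]
    for _ in range(60):
        noisy = fx.objects["clean"] + rng.normal(0, 0.01, size=len(c))
        c50, _, _ = extract_half_max(c, noisy)
        interp_errs.append(abs(c50 - c0) / c0)
        c50h, _ = fit_hill(c, noisy)
        hill_errs.append(abs(c50h - c0) / c0)
    assert np.mean(interp_errs) < 0.05
    assert max(hill_errs) < 0.05


def test_hill_fit_cross_check():
    c = np.geomspace(0.5, 200, 16)
    f = 1.0 / (1.0 + c / 10.0)
    c50, h = fit_hill(c, f)
    assert c50 == pytest.approx(10.0, rel=1e-4)
    assert h == pytest.approx(1.0, rel=1e-4)


def test_dose_response_on_simulated_inhibitor():
    """A coarse PD-1 sweep at moderate diffusion brackets the mean-field c50."""
    m = PD1Model(D=0.1, L=8.5, voxels_per_axis=32)
    ker_rate = m.kernel().well_mixed_rate_2d()
    c_mf = m.lam / ker_rate  # mean-field 50% point: k_RL * c = lam
    sweep = c_mf * np.geomspace(0.15, 8.0, 6)
    res = dose_response(m, sweep, n_trajectories=60, base_seed=2)
    assert res.monotone_within_error
    assert res.ic50 is not None
    assert 0.3 * c_mf < res.ic50 < 3.0 * c_mf


def test_steady_state_window_diagnostic_runs():
    m = PushPullModel(voxels_per_axis=32, D_S=0.05, D_E=0.05, L_e=15.0)
    r = steady_state_fraction(m, 60, 8)
    assert np.isfinite(r.window_means[0]) and np.isfinite(r.window_means[1])
    assert r.converged
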