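"""Two-particle Doi mean-reaction-time theory: closed forms, oracle, asymptotics."""

import math

import numpy as np
import pytest

from tethersim.constants import convert_catalytic_2d, convert_catalytic_3d
from tethersim.kernels import ALPHA, MU, GaussianReachKernel, calibrate_doi
from tethersim.mrt import (
    DoiProblem,
    asymptotic_mrt,
    decompose_mrt,
    equal_measure_radius,
    exact_mrt_2d_disc,
    mrt_3d_sphere,
    problem_for_model,
    solve_mrt_numeric,
    well_mixed_mrt,
)

KCAT = convert_catalytic_3d(0.1)
KCAT2D = convert_catalytic_2d((1 / 3) * 1e6)
R2 = equal_measure_radius(300.0, 2)
R3 = equal_measure_radius(300.0, 3)


def doi(d, R, D_um, L):
    cal = calibrate_doi(GaussianReachKernel(L, KCAT, 3))
    return DoiProblem(d=d, R=R, D=D_um * 1e6, epsilon=cal.epsilon, lam=cal.lam)


def test_equal_measure_radius():
    assert R2 == pytest.approx(300 / math.sqrt(math.pi))
    assert R2 == pytest.approx(169.26, abs=0.01)
    assert R3 == pytest.approx(300 * (3 / (4 * math.pi)) ** (1 / 3))
    assert R3 == pytest.approx(186.11, abs=0.01)
    assert equal_measure_radius(600.0, 2) == pytest.approx(2 * R2)


def test_uniform_reaction_zone_branch():
    """When the interaction radius covers the domain, <T> = 1/lambda."""
    p = DoiProblem(d=2, R=100.0, D=1e4, epsilon=150.0, lam=0.5)
    assert exact_mrt_2d_disc(p).T == pytest.approx(2.0)
    assert solve_mrt_numeric(p).T == pytest.approx(2.0)
    p3 = DoiProblem(d=3, R=100.0, D=1e4, epsilon=150.0, lam=0.5)
    assert mrt_3d_sphere(p3).T == pytest.approx(2.0)


def test_large_reach_branch_value():
    """For eps > R the MRT equals (4/3) pi (alpha L)^3 / kcat."""
    L = 200.0  # alpha*L = 245.7 > R
    cal = calibrate_doi(GaussianReachKernel(L, KCAT, 3))
    p = DoiProblem(2, R2, 1e4, cal.epsilon, cal.lam)
    assert cal.epsilon > R2
    expected = (4 / 3) * math.pi * (ALPHA * L) ** 3 / KCAT
    assert exact_mrt_2d_disc(p).T == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("D_um", [1.25e-6, 1.25e-4, 0.1])
@pytest.mark.parametrize("L", [1.0, 8.5, 70.0])
def test_exact_disc_matches_fv_oracle(D_um, L):
    p = doi(2, R2, D_um, L)
    exact = exact_mrt_2d_disc(p).T
    numeric = solve_mrt_numeric(p).T
    assert abs(numeric - exact) / exact < 1e-6


@pytest.mark.parametrize("D_um", [1.25e-5, 1.25e-3, 0.1])
@pytest.mark.parametrize("L", [1.0, 12.0, 70.0])
def test_exact_sphere_matches_fv_oracle(D_um, L):
    p = doi(3, R3, D_um, L)
    exact = mrt_3d_sphere(p).T
    numeric = solve_mrt_numeric(p).T
    assert abs(numeric - exact) / exact < 1e-6


def test_fv_second_order_convergence():
    """Halving the mesh spacing reduces the error about fourfold."""
    p = doi(2, R2, 1.25e-2, 8.5)
    exact = exact_mrt_2d_disc(p).T
    e1 = abs(solve_mrt_numeric(p, grid_size=4000).T - exact)
    e2 = abs(solve_mrt_numeric(p, grid_size=8000).T - exact)
    order = math.log2(e1 / e2)
    assert 1.6 < order < 2.6


def test_profile_matches_between_exact_and_numeric():
    p = doi(2, R2, 1.25e-3, 25.0)
    ex = exact_mrt_2d_disc(p, profile=True)
    nu = solve_mrt_numeric(p)
    w_interp = np.interp(nu.r, ex.r, ex.w)
    assert np.max(np.abs(w_interp - nu.w)) / np.max(ex.w) < 1e-3
    # no-flux outer boundary
    assert abs(nu.w[-1] - nu.w[-2]) / nu.w[-1] < 1e-5
    assert np.all(nu.w >= 0)


def test_monotone_in_diffusivity_and_rate():
    Ts = [exact_mrt_2d_disc(doi(2, R2, D, 8.5)).T for D in (1e-5, 1e-4, 1e-3, 1e-2)]
    assert all(a > b for a, b in zip(Ts, Ts[1:]))
    base = doi(2, R2, 1e-4, 8.5)
    Ts = [
        exact_mrt_2d_disc(DoiProblem(2, R2, base.D, base.epsilon, lam)).T
        for lam in (0.1, 1.0, 10.0, 100.0)
    ]
    assert all(a > b for a, b in zip(Ts, Ts[1:]))


def test_diffusion_limited_log_form():
    """At huge lambda the 2D MRT approaches the absorbing-trap log form."""
    p = DoiProblem(2, R2, 1.25e4, 10.0, 1e6)
    T = solve_mrt_numeric(p).T
    lead = (R2**2 / (2 * p.D)) * math.log(R2 / p.epsilon)
    assert abs(T - lead) < 0.5 * lead  # log term dominates; O(1) remainder


def test_reaction_limited_limit():
    """At large D the 2.5D MRT approaches (4/3) pi R^2 alpha L / kcat."""
    L = 8.5
    p = doi(2, R2, 1e3, L)  # D = 1e9 nm^2/s
    expected = 1.0 / (p.lam * p.rho**2)
    assert exact_mrt_2d_disc(p).T == pytest.approx(expected, rel=1e-3)
    assert expected == pytest.approx((4 / 3) * math.pi * R2**2 * ALPHA * L / KCAT, rel=1e-12)


def test_3d_large_D_limit_independent_of_reach():
    for L in (5.0, 40.0):
        p = doi(3, R3, 1e3, L)
        assert mrt_3d_sphere(p).T == pytest.approx(
            (4 / 3) * math.pi * R3**3 / KCAT, rel=1e-3
        )


def test_decomposition_identities():
    """The decomposition coefficients reproduce the asymptotic terms exactly."""
    L, D = 8.5, 1.25e4
    T_RL, T_DL, k_RL = decompose_mrt("2.5D", KCAT, L, D)
    assert (32 / (9 * math.pi)) * T_RL == pytest.approx(
        (4 / 3) * math.pi * R2**2 * ALPHA * L / KCAT, rel=1e-10
    )
    assert k_RL == pytest.approx(KCAT * math.sqrt(3 / (2 * math.pi)) / L, rel=1e-12)
    T_RL3, T_DL3, _ = decompose_mrt("3D", KCAT, L, D)
    assert 1.2 * T_DL3 == pytest.approx(2 * R3**3 / (5 * D * ALPHA * L), rel=1e-10)
    assert T_DL3 == pytest.approx(R3**3 / (3 * D * ALPHA * L), rel=1e-10)
    _, _, k2 = decompose_mrt("2D", KCAT2D, L, D)
    assert k2 == KCAT2D  # in-plane kernel integrates to one over the plane


def test_reaction_limited_term_proportional_to_reach():
    T1, _, _ = decompose_mrt("2.5D", KCAT, 10.0, 1e4)
    T2, _, _ = decompose_mrt("2.5D", KCAT, 30.0, 1e4)
    assert T2 / T1 == pytest.approx(3.0, rel=1e-12)
    # 2D and 3D reaction-limited terms are independent of the reach
    for model, k in (("2D", KCAT2D), ("3D", KCAT)):
        a, _, _ = decompose_mrt(model, k, 10.0, 1e4)
        b, _, _ = decompose_mrt(model, k, 30.0, 1e4)
        assert a == pytest.approx(b, rel=1e-12)


def test_asymptotic_validity_flag():
    good = asymptotic_mrt("2.5D", KCAT, 2.0, 0.1e6)
    assert good.valid
    with pytest.warns(UserWarning):
        bad = asymptotic_mrt("2.5D", KCAT, 70.0, 0.1e6)
    assert not bad.valid
    slow = asymptotic_mrt("2.5D", KCAT, 2.0, 1.25e-6 * 1e6)
    assert not slow.valid  # strong-absorption regime: eps*sqrt(lam/D) >> 1


def test_asymptotic_agreement_in_joint_validity_region():
    """Where both rho and eps*sqrt(lam/D) are small the expansions hold to ~1%."""
    for model, k, exactf, R in (
        ("2.5D", KCAT, lambda p: exact_mrt_2d_disc(p).T, R2),
        ("3D", KCAT, lambda p: mrt_3d_sphere(p).T, R3),
    ):
        for L in (1.0, 2.5, 5.0):
            D = 0.1e6
            prob = problem_for_model(model, k, L, D)
            sol = asymptotic_mrt(model, k, L, D)
            assert sol.valid
            assert abs(sol.T - exactf(prob)) / exactf(prob) < 0.01


def test_analytic_switch_signature():
    """2.5D MRT ordering in L inverts between slow and fast diffusion;
    the 2D and 3D models are non-increasing in L at every tabulated D."""
    slow, fast = 1.25e-6, 0.1
    T = {
        (L, D): well_mixed_mrt(problem_for_model("2.5D", KCAT, L, D * 1e6))
        for L in (1.0, 70.0)
        for D in (slow, fast)
    }
    assert T[(70.0, slow)] < T[(1.0, slow)]
    assert T[(70.0, fast)] > T[(1.0, fast)]
    Ds = [1.25e-6, 1.25e-5, 1.25e-4, 1.25e-3, 1.25e-2, 0.1]
    Ls = np.geomspace(1, 70, 6)
    for model, k in (("2D", KCAT2D), ("3D", KCAT)):
        for D in Ds:
            Ts = [well_mixed_mrt(problem_for_model(model, k, L, D * 1e6)) for L in Ls]
            assert all(a >= b * (1 - 1e-12) for a, b in zip(Ts, Ts[1:]))


def test_problem_invariants():
    p = doi(2, R2, 1e-3, 8.5)
    assert p.rho == pytest.approx(p.epsilon / p.R)
    assert p.R_hat == pytest.approx(p.R * math.sqrt(p.lam / p.D))
    with pytest.raises(ValueError):
        DoiProblem(d=4, R=1.0, D=1.0, epsilon=0.1, lam=1.0)
    with pytest.raises(ValueError):
        DoiProblem(d=2, R=-1.0, D=1.0, epsilon=0.1, lam=1.0)
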